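"""Training and application of the two-branch network ensemble and baselines.

The classifier is an ensemble of pseudo-Siamese neural networks.  Each
member is trained on its own random subset of the positive/negative pool
with negatives up-weighted (default 50x) in the loss, so that a high score
demands strong evidence rather than mere plausibility.  Early stopping
monitors unweighted AUROC on a chromosome-disjoint validation set with a
patience of three epochs, keeping the weights from the best epoch.  The
ensemble prediction is the arithmetic mean of member outputs.

Baselines with the same predict contract: a logistic-regression ensemble
and a random-forest ensemble on concatenated (A, B) feature vectors, and a
single-species fully connected network that predicts whether a region
aligns to the other genome at all.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .features import PairDataset, FeatureSchema
from .network import Adam, FeedForwardNetwork, PseudoSiameseNetwork

__all__ = [
    "Hyperparameters",
    "TrainingConfig",
    "NetworkModel",
    "Ensemble",
    "EnsemblePair",
    "weighted_loss",
    "train_single_network",
    "random_hyperparameter_search",
    "train_ensemble",
    "predict_ensemble",
    "train_baseline",
    "BaselineEnsemble",
    "HumanOnlyModel",
    "DEFAULT_SEARCH_SPACE",
    "save_ensemble",
    "load_ensemble",
]

_EPS = 1e-12


@dataclass(frozen=True)
class Hyperparameters:
    """Architecture and optimization hyper-parameters for one network.

    ``branch_widths`` applies to both species branches (distinct weights),
    ``final_widths`` to the combining subnetwork (excluding the 1-unit
    output layer).
    """

    branch_widths: tuple[int, ...] = (32,)
    final_widths: tuple[int, ...] = (32,)
    batch_size: int = 64
    learning_rate: float = 3e-3
    dropout: float = 0.1

    def __post_init__(self) -> None:
        if any(w < 1 for w in self.branch_widths) or any(
            w < 1 for w in self.final_widths
        ):
            raise ValueError("layer widths must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


@dataclass
class TrainingConfig:
    """Ensemble-level training configuration.

    ``profile='paper'`` restores the full-scale settings (100 members, one
    million examples per class per member); the default desk profile keeps
    the same protocol at a scale that trains in minutes on one CPU.
    """

    w_neg: float = 50.0
    patience: int = 3
    max_epochs: int = 100
    max_seconds: float = 24 * 3600.0
    ensemble_size: int = 10
    n_pos: int = 20_000
    n_neg: int = 20_000
    n_candidates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.w_neg <= 0:
            raise ValueError("w_neg must be > 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.ensemble_size < 1:
            raise ValueError("ensemble size must be >= 1")

    @classmethod
    def paper_profile(cls, seed: int = 0) -> "TrainingConfig":
        return cls(
            ensemble_size=100,
            n_pos=1_000_000,
            n_neg=1_000_000,
            n_candidates=100,
            seed=seed,
        )


def weighted_loss(prediction: float, label: int, w_neg: float) -> float:
    """Per-example weighted binary cross-entropy.

    Positives carry weight 1, negatives weight ``w_neg``.  Predictions of
    exactly 0 or 1 are clamped by a small epsilon (1e-12) so the loss stays
    finite.
    """
    p = min(max(float(prediction), _EPS), 1.0 - _EPS)
    w = 1.0 if label == 1 else float(w_neg)
    if label == 1:
        return -w * np.log(p)
    return -w * np.log(1.0 - p)


class EarlyStopping:
    """Keep the best validation AUROC; stop after ``patience`` stale epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = -np.inf
        self.best_epoch = 0
        self.epoch = 0

    def update(self, auroc: float) -> bool:
        """Record one epoch's validation AUROC; return True to stop."""
        self.epoch += 1
        if auroc > self.best:
            self.best = auroc
            self.best_epoch = self.epoch
        return (self.epoch - self.best_epoch) >= self.patience


@dataclass
class NetworkModel:
    """One trained member: weights, hyper-parameters, validation summary."""

    network: PseudoSiameseNetwork
    hp: Hyperparameters
    best_val_auroc: float
    best_epoch: int
    n_epochs_run: int
    seed: int
    metadata: dict = field(default_factory=lambda: {
        "optimizer": "adam",
        "activation": "relu",
        "init": "he-uniform",
    })

    def predict(self, Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(Xa, Xb)


def _check_val(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("validation set must contain both classes (AUROC undefined)")


def train_single_network(
    train: PairDataset,
    val: PairDataset,
    hp: Hyperparameters,
    cfg: TrainingConfig,
    seed: int,
) -> NetworkModel:
    """Train one pseudo-Siamese network with early stopping.

    Stops on patience exhaustion (no validation-AUROC improvement over
    ``cfg.patience`` epochs), on ``cfg.max_epochs``, or on the wall-time
    cap; returns the weights from the best-validation-AUROC epoch.
    Validation AUROC is computed unweighted on the validation set.
    """
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    _check_val(val.y)
    rng = np.random.default_rng(seed)
    net = PseudoSiameseNetwork(
        n_a=train.Xa.shape[1],
        n_b=train.Xb.shape[1],
        branch_widths=hp.branch_widths,
        final_widths=hp.final_widths,
        dropout=hp.dropout,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    opt = Adam(net.all_layers(), lr=hp.learning_rate)
    w = np.where(train.y == 1, 1.0, cfg.w_neg)
    stopper = EarlyStopping(cfg.patience)
    best_weights = net.get_weights()
    t0 = time.monotonic()
    n = len(train)
    epochs_run = 0
    for _ in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            net.train_step(train.Xa[idx], train.Xb[idx], train.y[idx], w[idx], opt)
        epochs_run += 1
        val_auroc = float(roc_auc_score(val.y, net.predict_proba(val.Xa, val.Xb)))
        improved = val_auroc > stopper.best
        stop = stopper.update(val_auroc)
        if improved:
            best_weights = net.get_weights()
        if stop or (time.monotonic() - t0) > cfg.max_seconds:
            break
    net.set_weights(best_weights)
    return NetworkModel(
        network=net,
        hp=hp,
        best_val_auroc=stopper.best,
        best_epoch=stopper.best_epoch,
        n_epochs_run=epochs_run,
        seed=seed,
    )


DEFAULT_SEARCH_SPACE: dict = {
    "n_branch_layers": [1, 2],
    "n_final_layers": [1, 2],
    "width": [16, 32, 64, 128],
    "batch_size": [64, 128, 256],
    "learning_rate": [3e-4, 1e-3, 3e-3],
    "dropout": [0.0, 0.1, 0.2],
}


def sample_hyperparameters(
    space: dict, rng: np.random.Generator
) -> Hyperparameters:
    def pick(key):
        options = space[key]
        return options[int(rng.integers(0, len(options)))]

    branch = tuple(pick("width") for _ in range(pick("n_branch_layers")))
    final = tuple(pick("width") for _ in range(pick("n_final_layers")))
    return Hyperparameters(
        branch_widths=branch,
        final_widths=final,
        batch_size=pick("batch_size"),
        learning_rate=pick("learning_rate"),
        dropout=pick("dropout"),
    )


def random_hyperparameter_search(
    train: PairDataset,
    val: PairDataset,
    cfg: TrainingConfig,
    space: dict | None = None,
    n_candidates: int | None = None,
    seed: int | None = None,
) -> tuple[Hyperparameters, list[tuple[Hyperparameters, float]]]:
    """Random search over hyper-parameters on one fixed training subset.

    Every candidate trains on the SAME subset; the candidate maximizing
    validation AUROC wins.  Returns (best, all (candidate, AUROC) results).
    """
    space = DEFAULT_SEARCH_SPACE if space is None else space
    if not space:
        raise ValueError("empty hyper-parameter space")
    n_candidates = cfg.n_candidates if n_candidates is None else n_candidates
    if n_candidates < 1:
        raise ValueError("need at least one candidate")
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    results: list[tuple[Hyperparameters, float]] = []
    for k in range(n_candidates):
        hp = sample_hyperparameters(space, rng)
        model = train_single_network(train, val, hp, cfg, seed=seed + 1000 + k)
        results.append((hp, model.best_val_auroc))
    best_hp = max(results, key=lambda r: r[1])[0]
    return best_hp, results


@dataclass
class Ensemble:
    """A trained set of two-branch networks; prediction is the member mean."""

    members: list[NetworkModel]
    hp: Hyperparameters
    config: TrainingConfig
    a_schema: FeatureSchema | None = None
    b_schema: FeatureSchema | None = None
    train_chroms_a: frozenset = frozenset()
    train_chroms_b: frozenset = frozenset()

    def predict(self, Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
        preds = np.stack([m.predict(Xa, Xb) for m in self.members])
        return preds.mean(axis=0)

    def covers(self, a_chrom: str, b_chrom: str) -> bool:
        """Whether this ensemble may score a pair without leakage
        (neither chromosome was seen in its training/validation)."""
        return a_chrom not in self.train_chroms_a and b_chrom not in self.train_chroms_b


def _sample_class_subset(
    ds: PairDataset, n_pos: int, n_neg: int, rng: np.random.Generator
) -> np.ndarray:
    pos_idx = np.flatnonzero(ds.y == 1)
    neg_idx = np.flatnonzero(ds.y == 0)
    if len(pos_idx) < n_pos or len(neg_idx) < n_neg:
        raise ValueError(
            f"insufficient pool ({len(pos_idx)} pos / {len(neg_idx)} neg) for "
            f"per-member sample sizes {n_pos}/{n_neg}; reduce n_pos/n_neg"
        )
    take = np.concatenate(
        [
            rng.choice(pos_idx, size=n_pos, replace=False),
            rng.choice(neg_idx, size=n_neg, replace=False),
        ]
    )
    rng.shuffle(take)
    return take


def train_ensemble(
    pool: PairDataset,
    val: PairDataset,
    hp: Hyperparameters,
    cfg: TrainingConfig,
    train_chroms: tuple[frozenset, frozenset] = (frozenset(), frozenset()),
    a_schema: FeatureSchema | None = None,
    b_schema: FeatureSchema | None = None,
) -> Ensemble:
    """Train ``cfg.ensemble_size`` members on distinct random pool subsets.

    Member seeds derive from ``cfg.seed`` plus the member index, so members
    differ in both their subset and their initialization.
    """
    members: list[NetworkModel] = []
    for k in range(cfg.ensemble_size):
        member_seed = cfg.seed + k
        rng = np.random.default_rng(member_seed)
        idx = _sample_class_subset(pool, cfg.n_pos, cfg.n_neg, rng)
        members.append(
            train_single_network(pool.subset(idx), val, hp, cfg, seed=member_seed)
        )
    return Ensemble(
        members=members,
        hp=hp,
        config=cfg,
        a_schema=a_schema,
        b_schema=b_schema,
        train_chroms_a=train_chroms[0],
        train_chroms_b=train_chroms[1],
    )


@dataclass
class EnsemblePair:
    """Two complementary ensembles trained on disjoint chromosome parities.

    Each pair of regions is scored by the ensemble NOT trained on its
    chromosomes, so every genome-wide prediction is out-of-sample.
    """

    first: Ensemble
    second: Ensemble


def predict_ensemble(
    model: Ensemble | EnsemblePair,
    ds: PairDataset,
) -> np.ndarray:
    """Score featurized pairs in [0, 1].

    With an :class:`EnsemblePair`, pairs are routed to whichever ensemble
    did not train on their chromosomes; a pair covered by neither ensemble
    is an error.
    """
    if isinstance(model, Ensemble):
        return model.predict(ds.Xa, ds.Xb)
    scores = np.full(len(ds), np.nan)
    route_first = np.asarray(
        [model.first.covers(a, b) for a, b in zip(ds.a_chrom, ds.b_chrom)]
    )
    route_second = np.asarray(
        [model.second.covers(a, b) for a, b in zip(ds.a_chrom, ds.b_chrom)]
    )
    uncovered = ~(route_first | route_second)
    if uncovered.any():
        bad = int(np.flatnonzero(uncovered)[0])
        raise ValueError(
            f"pair {ds.pair_ids[bad]} ({ds.a_chrom[bad]}, {ds.b_chrom[bad]}) is "
            "covered by neither ensemble"
        )
    use_first = route_first  # pairs covered by both default to the first
    if use_first.any():
        scores[use_first] = model.first.predict(ds.Xa[use_first], ds.Xb[use_first])
    rest = ~use_first
    if rest.any():
        scores[rest] = model.second.predict(ds.Xa[rest], ds.Xb[rest])
    return scores


# ---------------------------------------------------------------------------
# baselines


@dataclass
class BaselineEnsemble:
    """Ensemble of scikit-learn classifiers on concatenated (A, B) vectors."""

    kind: str
    members: list
    best_params: dict

    def predict(self, Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
        X = np.hstack([Xa, Xb])
        preds = np.stack([m.predict_proba(X)[:, 1] for m in self.members])
        return preds.mean(axis=0)


@dataclass
class HumanOnlyModel:
    """Single-species network scoring whether a region aligns at all."""

    members: list[FeedForwardNetwork]

    def predict(self, X: np.ndarray) -> np.ndarray:
        preds = np.stack([m.predict_proba(X) for m in self.members])
        return preds.mean(axis=0)


_LOGISTIC_GRID = [0.01, 0.1, 1.0, 10.0]
_FOREST_SPACE = {
    "n_estimators": [25, 50, 100],
    "max_depth": [4, 8, 16, None],
    "min_samples_leaf": [1, 5, 20],
}


def train_baseline(
    kind: str,
    pool: PairDataset,
    val: PairDataset,
    cfg: TrainingConfig,
    hp_space: dict | None = None,
):
    """Train a baseline with the same ensemble and weighting protocol.

    ``logistic`` grid-searches the regularization strength; ``tree_ensemble``
    random-searches forest hyper-parameters; ``human_only`` trains fully
    connected networks on species-A features with its own alignment-derived
    labels (its dataset must not carry pair features for species B).
    """
    if kind == "logistic":
        return _train_sklearn_baseline(kind, pool, val, cfg, grid=_LOGISTIC_GRID)
    if kind == "tree_ensemble":
        return _train_sklearn_baseline(
            kind, pool, val, cfg, space=hp_space or _FOREST_SPACE
        )
    if kind == "human_only":
        return _train_human_only(pool, val, cfg)
    raise ValueError(f"unknown baseline kind {kind!r}")


def _fit_one_sklearn(kind: str, params: dict, X, y, w, seed: int):
    if kind == "logistic":
        clf = LogisticRegression(C=params["C"], max_iter=2000, random_state=seed)
    else:
        clf = RandomForestClassifier(
            n_estimators=params["n_estimators"],
            max_depth=params["max_depth"],
            min_samples_leaf=params["min_samples_leaf"],
            random_state=seed,
            n_jobs=1,
        )
    clf.fit(X, y, sample_weight=w)
    return clf


def _train_sklearn_baseline(
    kind: str,
    pool: PairDataset,
    val: PairDataset,
    cfg: TrainingConfig,
    grid: list | None = None,
    space: dict | None = None,
) -> BaselineEnsemble:
    _check_val(val.y)
    rng = np.random.default_rng(cfg.seed)
    search_idx = _sample_class_subset(pool, cfg.n_pos, cfg.n_neg, rng)
    sub = pool.subset(search_idx)
    X_search = np.hstack([sub.Xa, sub.Xb])
    w_search = np.where(sub.y == 1, 1.0, cfg.w_neg)
    X_val = np.hstack([val.Xa, val.Xb])

    if kind == "logistic":
        candidates = [{"C": c} for c in (grid or _LOGISTIC_GRID)]
    else:
        sp = space or _FOREST_SPACE
        candidates = []
        for _ in range(cfg.n_candidates):
            candidates.append(
                {k: v[int(rng.integers(0, len(v)))] for k, v in sp.items()}
            )
    best_params, best_auc = None, -np.inf
    for i, params in enumerate(candidates):
        clf = _fit_one_sklearn(kind, params, X_search, sub.y, w_search, cfg.seed + i)
        auc = roc_auc_score(val.y, clf.predict_proba(X_val)[:, 1])
        if auc > best_auc:
            best_params, best_auc = params, auc

    members = []
    for k in range(cfg.ensemble_size):
        mrng = np.random.default_rng(cfg.seed + k)
        idx = _sample_class_subset(pool, cfg.n_pos, cfg.n_neg, mrng)
        msub = pool.subset(idx)
        members.append(
            _fit_one_sklearn(
                kind,
                best_params,
                np.hstack([msub.Xa, msub.Xb]),
                msub.y,
                np.where(msub.y == 1, 1.0, cfg.w_neg),
                cfg.seed + k,
            )
        )
    return BaselineEnsemble(kind=kind, members=members, best_params=best_params)


def _train_human_only(
    pool: PairDataset, val: PairDataset, cfg: TrainingConfig
) -> HumanOnlyModel:
    if pool.Xb is not None and pool.Xb.size > 0:
        raise ValueError(
            "human_only baseline takes single-species data with alignment-derived "
            "labels, not pair features"
        )
    _check_val(val.y)
    members: list[FeedForwardNetwork] = []
    hp = Hyperparameters()
    for k in range(cfg.ensemble_size):
        seed = cfg.seed + k
        rng = np.random.default_rng(seed)
        idx = _sample_class_subset(pool, cfg.n_pos, cfg.n_neg, rng)
        sub = pool.subset(idx)
        net = FeedForwardNetwork(
            n_in=sub.Xa.shape[1],
            widths=hp.branch_widths + hp.final_widths,
            dropout=hp.dropout,
            seed=seed,
        )
        opt = Adam(net.all_layers(), lr=hp.learning_rate)
        w = np.where(sub.y == 1, 1.0, cfg.w_neg)
        stopper = EarlyStopping(cfg.patience)
        best_weights = net.get_weights()
        n = len(sub)
        for _ in range(cfg.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, hp.batch_size):
                bidx = order[start : start + hp.batch_size]
                net.train_step(sub.Xa[bidx], sub.y[bidx], w[bidx], opt)
            auroc = float(roc_auc_score(val.y, net.predict_proba(val.Xa)))
            improved = auroc > stopper.best
            stop = stopper.update(auroc)
            if improved:
                best_weights = net.get_weights()
            if stop:
                break
        net.set_weights(best_weights)
        members.append(net)
    return HumanOnlyModel(members=members)


# ---------------------------------------------------------------------------
# model artifact


def save_ensemble(ensemble: Ensemble, out_dir: str | Path) -> None:
    """Serialize an ensemble: per-member weights (npz) + JSON metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": 1,
        "hp": asdict(ensemble.hp),
        "config": asdict(ensemble.config),
        "n_members": len(ensemble.members),
        "train_chroms_a": sorted(ensemble.train_chroms_a),
        "train_chroms_b": sorted(ensemble.train_chroms_b),
        "a_schema": ensemble.a_schema.to_dict() if ensemble.a_schema else None,
        "b_schema": ensemble.b_schema.to_dict() if ensemble.b_schema else None,
        "members": [
            {
                "best_val_auroc": m.best_val_auroc,
                "best_epoch": m.best_epoch,
                "n_epochs_run": m.n_epochs_run,
                "seed": m.seed,
                "metadata": m.metadata,
            }
            for m in ensemble.members
        ],
        "n_a": ensemble.members[0].network.n_a,
        "n_b": ensemble.members[0].network.n_b,
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))
    for k, m in enumerate(ensemble.members):
        arrays = {}
        for i, (W, b) in enumerate(m.network.get_weights()):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez(out / f"member_{k:03d}.npz", **arrays)


def load_ensemble(model_dir: str | Path) -> Ensemble:
    model_dir = Path(model_dir)
    meta = json.loads((model_dir / "metadata.json").read_text())
    hp_d = meta["hp"]
    hp = Hyperparameters(
        branch_widths=tuple(hp_d["branch_widths"]),
        final_widths=tuple(hp_d["final_widths"]),
        batch_size=hp_d["batch_size"],
        learning_rate=hp_d["learning_rate"],
        dropout=hp_d["dropout"],
    )
    cfg = TrainingConfig(**meta["config"])
    members = []
    for k, mmeta in enumerate(meta["members"]):
        net = PseudoSiameseNetwork(
            n_a=meta["n_a"],
            n_b=meta["n_b"],
            branch_widths=hp.branch_widths,
            final_widths=hp.final_widths,
            dropout=hp.dropout,
            seed=0,
        )
        with np.load(model_dir / f"member_{k:03d}.npz") as data:
            n_layers = len(net.all_layers())
            net.set_weights(
                [(data[f"W{i}"], data[f"b{i}"]) for i in range(n_layers)]
            )
        members.append(
            NetworkModel(
                network=net,
                hp=hp,
                best_val_auroc=mmeta["best_val_auroc"],
                best_epoch=mmeta["best_epoch"],
                n_epochs_run=mmeta["n_epochs_run"],
                seed=mmeta["seed"],
                metadata=mmeta["metadata"],
            )
        )
    return Ensemble(
        members=members,
        hp=hp,
        config=cfg,
        a_schema=FeatureSchema.from_dict(meta["a_schema"]) if meta["a_schema"] else None,
        b_schema=FeatureSchema.from_dict(meta["b_schema"]) if meta["b_schema"] else None,
        train_chroms_a=frozenset(meta["train_chroms_a"]),
        train_chroms_b=frozenset(meta["train_chroms_b"]),
    )
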