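"""Statistics used to characterize and validate the conservation score.

Covers class-weighted AUROC/AUPRC (negatives up-weighted, default 50x, to
match the training objective), bootstrap resampling summaries, agreement
between independently trained scores, the weighted Jaccard similarity of
tissue-grouped peak activity, chromatin-state frequency correlation across
score bins, variant enrichment with one-sided binomial tests, score
distributions within annotations with Mann-Whitney U comparisons, and
windowed track statistics (half-coverage filter; sliding-window two-track
correlation).

Under uniform per-class weights the weighted AUROC equals the unweighted
one (the weight cancels from both axes); the weighted AUPRC does depend on
the weight: a label-independent scorer with equal class counts and negative
weight w has expected AUPRC 1/(1+w) -- 1/51 ~= 0.0196 at the default 50.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .features import AnnotationTrack

__all__ = [
    "AucResult",
    "weighted_auc",
    "resampled_auc_summary",
    "score_agreement",
    "TissueActivityVector",
    "tissue_activity_vectors",
    "weighted_jaccard",
    "UndefinedSimilarityError",
    "state_frequency_correlation",
    "ScoreBinning",
    "bin_by_score",
    "variant_enrichment",
    "score_by_annotation",
    "mean_score_per_state",
    "windowed_mean_score",
    "windowed_track_correlation",
]


@dataclass(frozen=True)
class AucResult:
    auroc: float
    auprc: float


def weighted_auc(
    pos_scores: np.ndarray, neg_scores: np.ndarray, w_neg: float = 50.0
) -> AucResult:
    """Class-weighted AUROC and AUPRC.

    AUROC is the weighted probability that a positive outscores a negative
    (ties count one half); with one uniform weight per negative the weight
    cancels.  AUPRC is the area under the weighted precision-recall curve
    (average precision), where each negative contributes ``w_neg`` to the
    denominator of precision.
    """
    pos_scores = np.asarray(pos_scores, dtype=float)
    neg_scores = np.asarray(neg_scores, dtype=float)
    if len(pos_scores) == 0 or len(neg_scores) == 0:
        raise ValueError("both score sets must be non-empty")
    y = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
    s = np.concatenate([pos_scores, neg_scores])
    w = np.where(y == 1, 1.0, float(w_neg))
    return AucResult(
        auroc=float(roc_auc_score(y, s, sample_weight=w)),
        auprc=float(average_precision_score(y, s, sample_weight=w)),
    )


def resampled_auc_summary(
    pos_scores: np.ndarray,
    neg_scores: np.ndarray,
    n_reps: int = 100,
    n_pos: int = 100_000,
    n_neg: int = 100_000,
    w_neg: float = 50.0,
    seed: int = 0,
) -> dict:
    """Bootstrap mean and SD of the weighted AUROC/AUPRC.

    Each repetition samples ``n_pos`` positives and ``n_neg`` negatives with
    replacement from the test scores.
    """
    if n_reps < 2:
        raise ValueError("need n_reps >= 2 for a standard deviation")
    pos_scores = np.asarray(pos_scores, dtype=float)
    neg_scores = np.asarray(neg_scores, dtype=float)
    rng = np.random.default_rng(seed)
    aurocs, auprcs = [], []
    for _ in range(n_reps):
        p = rng.choice(pos_scores, size=n_pos, replace=True)
        n = rng.choice(neg_scores, size=n_neg, replace=True)
        res = weighted_auc(p, n, w_neg)
        aurocs.append(res.auroc)
        auprcs.append(res.auprc)
    return {
        "auroc_mean": float(np.mean(aurocs)),
        "auroc_sd": float(np.std(aurocs, ddof=1)),
        "auprc_mean": float(np.mean(auprcs)),
        "auprc_sd": float(np.std(auprcs, ddof=1)),
        "n_reps": n_reps,
    }


def score_agreement(scores_x: np.ndarray, scores_y: np.ndarray) -> tuple[float, float]:
    """Pearson and Spearman correlation between two scorings of shared pairs."""
    x = np.asarray(scores_x, dtype=float)
    y = np.asarray(scores_y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 shared pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant scores")
    pcc = float(stats.pearsonr(x, y).statistic)
    scc = float(stats.spearmanr(x, y).statistic)
    return pcc, scc


# ---------------------------------------------------------------------------
# weighted Jaccard similarity of tissue-grouped peak activity


class UndefinedSimilarityError(ValueError):
    """Both activity vectors are zero everywhere; the coefficient is 0/0.

    Pairs raising this are excluded from the similarity analysis upstream.
    """


@dataclass(frozen=True)
class TissueActivityVector:
    """Per-tissue-group peak-overlap fractions for one region pair."""

    h: np.ndarray  # species A fractions, one per group
    m: np.ndarray  # species B fractions
    groups: tuple[str, ...]


def weighted_jaccard(v: TissueActivityVector) -> float:
    """Weighted Jaccard similarity: sum_i min(h_i, m_i) / sum_i max(h_i, m_i)."""
    denom = float(np.maximum(v.h, v.m).sum())
    if denom == 0.0:
        raise UndefinedSimilarityError(
            "all activity fractions are zero; similarity undefined"
        )
    return float(np.minimum(v.h, v.m).sum() / denom)


def tissue_activity_vectors(
    pairs,
    a_tracks: Sequence[AnnotationTrack],
    b_tracks: Sequence[AnnotationTrack],
) -> list[TissueActivityVector]:
    """Per-pair activity fractions over tissue groups shared by both species.

    Only peak tracks with a ``group`` assignment participate; ungrouped
    experiments are discarded.  Every group must be represented in both
    species.  Overlap is whole-region (any base of the region inside a
    peak).  Group metadata is evaluation-only and never enters training
    features.
    """
    def grouped(tracks):
        out: dict[str, list[AnnotationTrack]] = {}
        for t in tracks:
            if t.kind == "peak" and t.group is not None:
                out.setdefault(t.group, []).append(t)
        return out

    ga, gb = grouped(a_tracks), grouped(b_tracks)
    only = set(ga) ^ set(gb)
    if only:
        raise ValueError(
            f"tissue groups present in only one species: {sorted(only)}"
        )
    groups = tuple(sorted(ga))
    if not groups:
        raise ValueError("no grouped peak tracks")

    vectors = []
    for p in pairs:
        h = np.zeros(len(groups))
        m = np.zeros(len(groups))
        for gi, g in enumerate(groups):
            a_hits = sum(
                t.overlaps_region(p.a_region.chrom, p.a_region.start, p.a_region.end)
                for t in ga[g]
            )
            b_hits = sum(
                t.overlaps_region(p.b_region.chrom, p.b_region.start, p.b_region.end)
                for t in gb[g]
            )
            h[gi] = a_hits / len(ga[g])
            m[gi] = b_hits / len(gb[g])
        vectors.append(TissueActivityVector(h=h, m=m, groups=groups))
    return vectors


# ---------------------------------------------------------------------------
# chromatin-state frequency correlation


def state_frequency_correlation(
    pairs,
    a_segmentations: Sequence[AnnotationTrack],
    b_segmentations: Sequence[AnnotationTrack],
) -> dict[str, float | None]:
    """Cross-species Pearson correlation of per-state epigenome fractions.

    For each chromatin state ``s`` of a jointly learned model, build one
    vector per species over the given pairs: the fraction of that species'
    epigenomes annotating the region with ``s`` (any overlap).  Returns the
    per-state PCC; states where either vector is constant are reported as
    None (undefined), not 0.
    """
    states = sorted(
        {s for t in a_segmentations for s in t.states}
        | {s for t in b_segmentations for s in t.states},
        key=lambda s: (len(s), s),
    )
    if not pairs:
        raise ValueError("empty pair set")

    def fractions(tracks, regions, state) -> np.ndarray:
        out = np.zeros(len(regions))
        for t in tracks:
            for i, iv in enumerate(regions):
                ci = t.index.get(iv.chrom)
                if ci is None:
                    continue
                lo = np.searchsorted(ci.starts, iv.end, side="left")
                hit = False
                j = lo - 1
                while j >= 0 and ci.ends[j] > iv.start:
                    if ci.values[j] == state:
                        hit = True
                        break
                    j -= 1
                out[i] += hit
        return out / len(tracks)

    a_regions = [p.a_region for p in pairs]
    b_regions = [p.b_region for p in pairs]
    result: dict[str, float | None] = {}
    for s in states:
        va = fractions(a_segmentations, a_regions, s)
        vb = fractions(b_segmentations, b_regions, s)
        if np.ptp(va) == 0 or np.ptp(vb) == 0:
            result[s] = None
        else:
            result[s] = float(stats.pearsonr(va, vb).statistic)
    return result


# ---------------------------------------------------------------------------
# score binning and enrichment


@dataclass
class ScoreBinning:
    mode: str  # equal_width | percentile_rank
    k: int
    edges: np.ndarray  # for equal_width: k+1 edges; percentile: score quantile cuts
    bin_index: np.ndarray  # per-score bin in [0, k)

    def counts(self) -> np.ndarray:
        return np.bincount(self.bin_index, minlength=self.k)


def bin_by_score(scores: np.ndarray, mode: str = "equal_width", k: int = 10) -> ScoreBinning:
    """Assign each score to one of ``k`` bins.

    ``equal_width`` uses uniform edges over the observed range (top edge
    inclusive); ``percentile_rank`` forms near-equal-count bins by stable
    rank, and requires at least ``k`` distinct scores.
    """
    scores = np.asarray(scores, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if mode == "equal_width":
        lo, hi = float(scores.min()), float(scores.max())
        if lo == hi:
            raise ValueError("cannot bin constant scores")
        edges = np.linspace(lo, hi, k + 1)
        idx = np.clip(np.searchsorted(edges, scores, side="right") - 1, 0, k - 1)
        return ScoreBinning(mode=mode, k=k, edges=edges, bin_index=idx)
    if mode == "percentile_rank":
        if len(np.unique(scores)) < k:
            raise ValueError("k exceeds the number of distinct scores")
        order = np.argsort(scores, kind="stable")
        idx = np.empty(len(scores), dtype=int)
        # near-equal chunk sizes; ties resolved by stable rank
        bounds = np.linspace(0, len(scores), k + 1).astype(int)
        for b in range(k):
            idx[order[bounds[b] : bounds[b + 1]]] = b
        edges = np.quantile(scores, np.linspace(0, 1, k + 1))
        return ScoreBinning(mode=mode, k=k, edges=edges, bin_index=idx)
    raise ValueError(f"unknown binning mode {mode!r}")


def variant_enrichment(
    regions,
    scores: np.ndarray,
    variants: pd.DataFrame,
    k: int = 10,
) -> pd.DataFrame:
    """Variant enrichment across equal-width score bins.

    ``regions`` are the scored species-A intervals; the background is the
    uniform rate over all of them.  Per bin: region count, variant-overlap
    count, log2 fold enrichment versus background, and a one-sided binomial
    p-value for the overlap count given the background rate.  Empty bins
    report missing values.
    """
    scores = np.asarray(scores, dtype=float)
    var_index = _bed_to_index(variants)
    overlap = np.asarray(
        [
            _index_overlaps(var_index, iv.chrom, iv.start, iv.end)
            for iv in regions
        ],
        dtype=bool,
    )
    binning = bin_by_score(scores, "equal_width", k)
    bg_rate = overlap.mean()
    rows = []
    for b in range(k):
        mask = binning.bin_index == b
        n = int(mask.sum())
        if n == 0:
            rows.append((b, 0, 0, np.nan, np.nan, np.nan))
            continue
        x = int(overlap[mask].sum())
        rate = x / n
        fold = rate / bg_rate if bg_rate > 0 else np.nan
        log2_fold = np.log2(fold) if fold and fold > 0 else -np.inf if fold == 0 else np.nan
        pval = float(stats.binom.sf(x - 1, n, bg_rate)) if bg_rate > 0 else np.nan
        rows.append((b, n, x, fold, log2_fold, pval))
    return pd.DataFrame(
        rows,
        columns=["bin", "n_regions", "n_overlap", "fold", "log2_fold", "p_value"],
    )


def _bed_to_index(bed: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    index = {}
    for chrom, sub in bed.groupby(bed.columns[0]):
        sub = sub.sort_values(sub.columns[1])
        starts = sub.iloc[:, 1].to_numpy(dtype=np.int64)
        ends = sub.iloc[:, 2].to_numpy(dtype=np.int64)
        # merge overlaps so bisection is valid
        ms, me = [], []
        for s, e in zip(starts, ends):
            if me and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        index[str(chrom)] = (np.asarray(ms), np.asarray(me))
    return index


def _index_overlaps(index, chrom: str, start: int, end: int) -> bool:
    if chrom not in index:
        return False
    starts, ends = index[chrom]
    i = np.searchsorted(starts, end, side="left") - 1
    return i >= 0 and ends[i] > start


# ---------------------------------------------------------------------------
# score distributions within annotations


def _summary(values: np.ndarray) -> dict:
    q = np.percentile(values, [5, 25, 50, 75, 95])
    return {
        "n": int(len(values)),
        "mean": float(values.mean()),
        "median": float(q[2]),
        "q25": float(q[1]),
        "q75": float(q[3]),
        "p5": float(q[0]),
        "p95": float(q[4]),
    }


def score_by_annotation(
    track,
    annotation: pd.DataFrame,
    side: str = "A",
) -> dict:
    """Compare score distributions between annotation-overlapping regions
    and the rest.

    ``side`` selects which species' coordinates the annotation refers to
    ('A', 'B', or 'both' requiring overlap on both sides).  Returns summary
    statistics per group plus a two-sided Mann-Whitney U test (exact for
    small groups, normal approximation with tie correction otherwise).
    """
    index = _bed_to_index(annotation)
    records = track.records
    if side == "A":
        hit = [
            _index_overlaps(index, r.a_chrom, r.a_start, r.a_end)
            for r in records.itertuples()
        ]
    elif side == "B":
        hit = [
            _index_overlaps(index, r.b_chrom, r.b_start, r.b_end)
            for r in records.itertuples()
        ]
    elif side == "both":
        hit = [
            _index_overlaps(index, r.a_chrom, r.a_start, r.a_end)
            and _index_overlaps(index, r.b_chrom, r.b_start, r.b_end)
            for r in records.itertuples()
        ]
    else:
        raise ValueError("side must be 'A', 'B', or 'both'")
    hit = np.asarray(hit, dtype=bool)
    scores = records["score"].to_numpy(dtype=float)
    inside, outside = scores[hit], scores[~hit]
    if len(inside) == 0 or len(outside) == 0:
        raise ValueError("one comparison group is empty")
    method = "exact" if max(len(inside), len(outside)) <= 25 else "asymptotic"
    u = stats.mannwhitneyu(inside, outside, alternative="two-sided", method=method)
    return {
        "overlap": _summary(inside),
        "background": _summary(outside),
        "u_statistic": float(u.statistic),
        "p_value": float(u.pvalue),
    }


def mean_score_per_state(
    track,
    segmentations: Sequence[AnnotationTrack],
) -> dict[str, float]:
    """Two-level mean score per chromatin state.

    First average the score over all regions annotated with the state in
    each epigenome (any overlap), then average those per-epigenome means
    across epigenomes.  States absent from every epigenome are omitted.
    """
    if not segmentations:
        raise ValueError("need at least one epigenome segmentation")
    records = track.records
    scores = records["score"].to_numpy(dtype=float)
    regions = list(records.itertuples())
    per_state: dict[str, list[float]] = {}
    for seg in segmentations:
        state_hits: dict[str, list[float]] = {}
        for i, r in enumerate(regions):
            ci = seg.index.get(r.a_chrom)
            if ci is None:
                continue
            lo = np.searchsorted(ci.starts, r.a_end, side="left")
            j = lo - 1
            seen = set()
            while j >= 0 and ci.ends[j] > r.a_start:
                seen.add(ci.values[j])
                j -= 1
            for s in seen:
                state_hits.setdefault(s, []).append(scores[i])
        for s, vals in state_hits.items():
            per_state.setdefault(s, []).append(float(np.mean(vals)))
    return {s: float(np.mean(means)) for s, means in sorted(per_state.items())}


# ---------------------------------------------------------------------------
# windowed track statistics


def windowed_mean_score(
    track,
    windows: pd.DataFrame,
    min_coverage: float | None = None,
) -> pd.DataFrame:
    """Mean score per window over score-annotated bases, with coverage filter.

    The score track is expanded per base; each window's mean is taken over
    its annotated bases only.  Windows with strictly less than half their
    bases annotated (or ``min_coverage`` bases if given) are excluded, so
    exactly-half coverage is retained.
    """
    cov_index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    rec = track.records.sort_values(["a_chrom", "a_start"])
    for chrom, sub in rec.groupby("a_chrom"):
        cov_index[str(chrom)] = (
            sub["a_start"].to_numpy(np.int64),
            sub["a_end"].to_numpy(np.int64),
            sub["score"].to_numpy(float),
        )
    rows = []
    for w in windows.itertuples():
        chrom, start, end = str(w[1]), int(w[2]), int(w[3])
        width = end - start
        threshold = width / 2 if min_coverage is None else min_coverage
        covered = 0
        total = 0.0
        if chrom in cov_index:
            starts, ends, scores = cov_index[chrom]
            lo = np.searchsorted(ends, start, side="right")
            hi = np.searchsorted(starts, end, side="left")
            for i in range(lo, hi):
                ov = min(ends[i], end) - max(starts[i], start)
                if ov > 0:
                    covered += ov
                    total += ov * scores[i]
        if covered < threshold:
            continue
        rows.append((chrom, start, end, covered, total / covered))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_annotated", "mean_score"]
    )


def windowed_track_correlation(
    track_x: pd.DataFrame,
    track_y: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    window: int = 50,
    step: int = 10,
    min_annotated: int | Sequence[int] = 1,
) -> dict[int, tuple[float, float]]:
    """Sliding-window correlation between two per-base score tracks.

    Both tracks are bedGraph-like frames (chrom, start, end, value).  A
    window of ``window`` bases slides in ``step`` increments; per window the
    mean of each track over its annotated bases is computed.  For each
    requested ``n`` in ``min_annotated``, the PCC and SCC are taken across
    windows with at least ``n`` bases annotated by BOTH tracks (the tracks
    need not annotate the same bases).
    """
    ns = [min_annotated] if isinstance(min_annotated, int) else list(min_annotated)
    means_x, means_y, cov_x, cov_y = [], [], [], []
    for chrom, size in sorted(chrom_sizes.items()):
        vx, cx = _per_base(track_x, chrom, size)
        vy, cy = _per_base(track_y, chrom, size)
        csum_vx = np.concatenate([[0.0], np.cumsum(vx)])
        csum_cx = np.concatenate([[0], np.cumsum(cx)])
        csum_vy = np.concatenate([[0.0], np.cumsum(vy)])
        csum_cy = np.concatenate([[0], np.cumsum(cy)])
        for start in range(0, size - window + 1, step):
            end = start + window
            nx = csum_cx[end] - csum_cx[start]
            ny = csum_cy[end] - csum_cy[start]
            cov_x.append(nx)
            cov_y.append(ny)
            means_x.append((csum_vx[end] - csum_vx[start]) / nx if nx else np.nan)
            means_y.append((csum_vy[end] - csum_vy[start]) / ny if ny else np.nan)
    means_x = np.asarray(means_x)
    means_y = np.asarray(means_y)
    cov_x = np.asarray(cov_x)
    cov_y = np.asarray(cov_y)
    out: dict[int, tuple[float, float]] = {}
    for n in ns:
        keep = (cov_x >= n) & (cov_y >= n)
        if keep.sum() < 3:
            raise ValueError(f"fewer than 3 qualifying windows at n={n}")
        pcc = float(stats.pearsonr(means_x[keep], means_y[keep]).statistic)
        scc = float(stats.spearmanr(means_x[keep], means_y[keep]).statistic)
        out[n] = (pcc, scc)
    return out


def _per_base(track: pd.DataFrame, chrom: str, size: int) -> tuple[np.ndarray, np.ndarray]:
    values = np.zeros(size)
    covered = np.zeros(size, dtype=np.int64)
    sub = track[track.iloc[:, 0] == chrom]
    for r in sub.itertuples():
        s, e, v = int(r[2]), int(r[3]), float(r[4])
        s, e = max(s, 0), min(e, size)
        if e > s:
            values[s:e] = v
            covered[s:e] = 1
    return values, covered
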