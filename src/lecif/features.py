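"""Feature representations for paired genomic regions.

Each species contributes an ordered set of functional-genomics features:

* one binary feature per peak track (DNase/ChIP/CAGE-style peak calls),
* one binary feature per (chromatin state, epigenome) combination of a
  ChromHMM-style dense segmentation (one-hot encoding), and
* one continuous feature per signal track (RNA-seq-style bedGraph),
  min-max normalized to [0, 1] with a single min/max computed jointly over
  all signal tracks of the species.

Annotations are read at the first base of each region by default
(``first_base`` resolution) and represent the whole region, which is at most
50 bp; ``per_base`` resolution emits one vector pair per aligned base and
supports a base-resolution score variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignments import RegionPair

__all__ = [
    "AnnotationTrack",
    "FeatureDescriptor",
    "FeatureSchema",
    "FeatureVectorPair",
    "PairDataset",
    "load_annotations",
    "build_feature_schema",
    "normalize_signal",
    "featurize_pairs",
    "featurize_regions",
]

TRACK_KINDS = ("peak", "segmentation", "signal")


class TrackError(ValueError):
    """Raised for malformed annotation tracks or manifests."""


@dataclass
class _ChromIndex:
    """Sorted non-overlapping intervals on one chromosome for point lookup."""

    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray | None = None  # state labels or signal values

    def locate(self, pos: np.ndarray) -> np.ndarray:
        """Index of the interval covering each position, or -1."""
        idx = np.searchsorted(self.starts, pos, side="right") - 1
        idx = np.asarray(idx)
        hit = (idx >= 0) & (pos < self.ends[np.clip(idx, 0, None)])
        return np.where(hit, idx, -1)

    def overlaps_interval(self, start: int, end: int) -> bool:
        """Whether any interval intersects [start, end)."""
        i = np.searchsorted(self.starts, end, side="left") - 1
        return i >= 0 and self.ends[i] > start


@dataclass
class AnnotationTrack:
    """One functional-genomics track with fast positional lookup.

    ``kind`` is one of peak / segmentation / signal.  Segmentation tracks
    carry a state label per interval and an epigenome id; signal tracks
    carry a numeric value per interval.  Peak intervals are merged for
    lookup (only membership matters).
    """

    track_id: str
    species: str
    kind: str
    index: dict[str, _ChromIndex]
    epigenome: str | None = None
    states: tuple[str, ...] = ()
    group: str | None = None
    n_intervals: int = 0

    def peak_at(self, chroms: Sequence[str], pos: np.ndarray) -> np.ndarray:
        out = np.zeros(len(pos), dtype=np.float64)
        for chrom in set(chroms):
            ci = self.index.get(chrom)
            if ci is None:
                continue
            mask = np.asarray([c == chrom for c in chroms])
            out[mask] = ci.locate(pos[mask]) >= 0
        return out

    def state_at(self, chroms: Sequence[str], pos: np.ndarray) -> np.ndarray:
        """State label per position ('' where unannotated)."""
        out = np.full(len(pos), "", dtype=object)
        for chrom in set(chroms):
            ci = self.index.get(chrom)
            if ci is None:
                continue
            mask = np.asarray([c == chrom for c in chroms])
            loc = ci.locate(pos[mask])
            vals = np.where(loc >= 0, ci.values[np.clip(loc, 0, None)], "")
            out[mask] = vals
        return out

    def value_at(self, chroms: Sequence[str], pos: np.ndarray) -> np.ndarray:
        """Raw signal value per position (0 where unannotated)."""
        out = np.zeros(len(pos), dtype=np.float64)
        for chrom in set(chroms):
            ci = self.index.get(chrom)
            if ci is None:
                continue
            mask = np.asarray([c == chrom for c in chroms])
            loc = ci.locate(pos[mask])
            vals = np.where(loc >= 0, ci.values[np.clip(loc, 0, None)].astype(float), 0.0)
            out[mask] = vals
        return out

    def overlaps_region(self, chrom: str, start: int, end: int) -> bool:
        ci = self.index.get(chrom)
        return ci is not None and ci.overlaps_interval(start, end)

    def value_range(self) -> tuple[float, float]:
        vmin, vmax = np.inf, -np.inf
        for ci in self.index.values():
            if ci.values is not None and len(ci.values):
                v = ci.values.astype(float)
                vmin = min(vmin, float(v.min()))
                vmax = max(vmax, float(v.max()))
        return vmin, vmax


def _merge_intervals(df: pd.DataFrame) -> dict[str, _ChromIndex]:
    index = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        starts, ends = [], []
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        index[str(chrom)] = _ChromIndex(
            starts=np.asarray(starts, dtype=np.int64),
            ends=np.asarray(ends, dtype=np.int64),
        )
    return index


def _indexed_intervals(
    df: pd.DataFrame, value_col: str, track_id: str, numeric: bool
) -> dict[str, _ChromIndex]:
    index = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        if np.any(starts[1:] < ends[:-1]):
            raise TrackError(
                f"track {track_id!r}: overlapping intervals on {chrom}"
            )
        values = sub[value_col].to_numpy()
        if numeric:
            values = values.astype(np.float64)
            if not np.all(np.isfinite(values)):
                raise TrackError(f"track {track_id!r}: non-finite signal values")
        else:
            values = values.astype(object)
        index[str(chrom)] = _ChromIndex(starts=starts, ends=ends, values=values)
    return index


def _read_bed3(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            rows.append((fields[0], int(fields[1]), int(fields[2])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _read_bed4(path: Path, value_name: str, numeric: bool, track_id: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise TrackError(
                    f"track {track_id!r}: line {lineno}: expected >= 4 columns"
                )
            chrom, start, end, value = fields[0], fields[1], fields[2], fields[3]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise TrackError(
                    f"track {track_id!r}: line {lineno}: bad coordinates"
                ) from exc
            if numeric:
                try:
                    value = float(value)
                except ValueError as exc:
                    raise TrackError(
                        f"track {track_id!r}: line {lineno}: "
                        f"non-numeric value {value!r}"
                    ) from exc
            rows.append((chrom, start_i, end_i, value))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", value_name])


def load_annotations(
    manifest: str | Path | pd.DataFrame, base_dir: str | Path | None = None
) -> list[AnnotationTrack]:
    """Load a manifest of annotation tracks.

    The manifest is a TSV (or DataFrame) with columns ``path``, ``species``,
    ``kind`` and optionally ``epigenome`` (required for segmentations) and
    ``group`` (used only by downstream evaluation, never as a feature).
    Relative paths resolve against the manifest's directory.
    """
    if isinstance(manifest, (str, Path)):
        mpath = Path(manifest)
        df = pd.read_csv(mpath, sep="\t", dtype=str)
        base = Path(base_dir) if base_dir is not None else mpath.parent
    else:
        df = manifest
        base = Path(base_dir) if base_dir is not None else Path(".")
    required = {"path", "species", "kind"}
    if not required <= set(df.columns):
        raise TrackError(f"manifest must have columns {sorted(required)}")

    tracks: list[AnnotationTrack] = []
    for row in df.itertuples():
        kind = row.kind
        if kind not in TRACK_KINDS:
            raise TrackError(f"unknown track kind {kind!r} for {row.path}")
        path = Path(row.path)
        if not path.is_absolute():
            path = base / path
        track_id = str(getattr(row, "track_id", "") or path.stem)
        epigenome = getattr(row, "epigenome", None)
        epigenome = None if (epigenome is None or pd.isna(epigenome)) else str(epigenome)
        group = getattr(row, "group", None)
        group = None if (group is None or pd.isna(group)) else str(group)

        if kind == "peak":
            bed = _read_bed3(path)
            index = _merge_intervals(bed)
            n = len(bed)
            states: tuple[str, ...] = ()
        elif kind == "segmentation":
            if epigenome is None:
                raise TrackError(f"segmentation track {track_id!r} needs an epigenome id")
            bed = _read_bed4(path, "state", numeric=False, track_id=track_id)
            index = _indexed_intervals(bed, "state", track_id, numeric=False)
            states = tuple(sorted(set(map(str, bed["state"])), key=_state_key))
            n = len(bed)
        else:  # signal
            bed = _read_bed4(path, "value", numeric=True, track_id=track_id)
            index = _indexed_intervals(bed, "value", track_id, numeric=True)
            states = ()
            n = len(bed)

        tracks.append(
            AnnotationTrack(
                track_id=track_id,
                species=str(row.species),
                kind=kind,
                index=index,
                epigenome=epigenome,
                states=states,
                group=group,
                n_intervals=n,
            )
        )
    return tracks


def _state_key(state: str) -> tuple:
    try:
        return (0, int(state), state)
    except ValueError:
        return (1, 0, state)


# ---------------------------------------------------------------------------
# schema


@dataclass(frozen=True)
class FeatureDescriptor:
    track_id: str
    kind: str
    state: str | None = None  # segmentation one-hot only

    @property
    def name(self) -> str:
        return self.track_id if self.state is None else f"{self.track_id}|{self.state}"


@dataclass
class FeatureSchema:
    """Ordered feature descriptors for one species, frozen at build time.

    The signal min/max of the training universe is persisted with the schema
    so prediction-time normalization is identical (out-of-range values clip).
    """

    species: str
    descriptors: tuple[FeatureDescriptor, ...]
    signal_min: float | None = None
    signal_max: float | None = None

    def __len__(self) -> int:
        return len(self.descriptors)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "descriptors": [
                {"track_id": d.track_id, "kind": d.kind, "state": d.state}
                for d in self.descriptors
            ],
            "signal_min": self.signal_min,
            "signal_max": self.signal_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(
            species=d["species"],
            descriptors=tuple(
                FeatureDescriptor(x["track_id"], x["kind"], x["state"])
                for x in d["descriptors"]
            ),
            signal_min=d["signal_min"],
            signal_max=d["signal_max"],
        )


def build_feature_schema(tracks: Sequence[AnnotationTrack]) -> FeatureSchema:
    """Build the ordered feature schema for one species' tracks.

    Feature order is deterministic: manifest order, with segmentation tracks
    expanded into one binary feature per state (state alphabet order).  The
    species-wide signal min/max is computed jointly over all signal tracks.
    """
    if not tracks:
        raise TrackError("no tracks given")
    species = {t.species for t in tracks}
    if len(species) != 1:
        raise TrackError(f"tracks span multiple species: {sorted(species)}")
    ids = [t.track_id for t in tracks]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise TrackError(f"duplicate track ids: {dup}")

    descriptors: list[FeatureDescriptor] = []
    vmin, vmax = np.inf, -np.inf
    has_signal = False
    for t in tracks:
        if t.kind == "peak":
            descriptors.append(FeatureDescriptor(t.track_id, "peak"))
        elif t.kind == "segmentation":
            descriptors.extend(
                FeatureDescriptor(t.track_id, "segmentation", s) for s in t.states
            )
        else:
            has_signal = True
            lo, hi = t.value_range()
            vmin, vmax = min(vmin, lo), max(vmax, hi)
            descriptors.append(FeatureDescriptor(t.track_id, "signal"))
    if has_signal:
        if not (vmin < vmax):
            raise TrackError(
                "degenerate signal normalization: global min equals global max"
            )
        signal_min, signal_max = float(vmin), float(vmax)
    else:
        signal_min = signal_max = None
    return FeatureSchema(
        species=species.pop(),
        descriptors=tuple(descriptors),
        signal_min=signal_min,
        signal_max=signal_max,
    )


def normalize_signal(value, global_min: float, global_max: float):
    """Min-max normalize a signal value to [0, 1], clipping out-of-range input.

    The min/max are species-wide constants computed once over all signal
    tracks; prediction-time values outside the training range clip rather
    than error.
    """
    if not (global_min < global_max):
        raise ValueError("degenerate normalization: global_min must be < global_max")
    return np.clip((np.asarray(value) - global_min) / (global_max - global_min), 0.0, 1.0)


# ---------------------------------------------------------------------------
# featurization


@dataclass(frozen=True)
class FeatureVectorPair:
    pair_id: str
    a_vector: np.ndarray
    b_vector: np.ndarray


@dataclass
class PairDataset:
    """Featurized region pairs as dense matrices plus labels and provenance."""

    pair_ids: list[str]
    Xa: np.ndarray
    Xb: np.ndarray
    y: np.ndarray  # 1 positive, 0 negative
    a_chrom: np.ndarray
    b_chrom: np.ndarray

    def __len__(self) -> int:
        return len(self.pair_ids)

    @property
    def n_pos(self) -> int:
        return int(self.y.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.y) - self.y.sum())

    def subset(self, idx) -> "PairDataset":
        idx = np.asarray(idx)
        return PairDataset(
            pair_ids=[self.pair_ids[i] for i in idx],
            Xa=self.Xa[idx],
            Xb=self.Xb[idx],
            y=self.y[idx],
            a_chrom=self.a_chrom[idx],
            b_chrom=self.b_chrom[idx],
        )


def _representative_positions(
    pairs: Sequence[RegionPair], side: str, resolution: str
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """(chroms, positions, owner-pair-index) of lookup bases for one side."""
    chroms: list[str] = []
    positions: list[int] = []
    owner: list[int] = []
    for i, p in enumerate(pairs):
        iv = p.a_region if side == "a" else p.b_region
        if resolution == "first_base":
            # "first base" follows the alignment: for a minus-strand B region
            # the alignment's first base is the forward-coordinate last base
            pos = iv.end - 1 if iv.strand == "-" else iv.start
            chroms.append(iv.chrom)
            positions.append(pos)
            owner.append(i)
        else:  # per_base
            rng = range(iv.end - 1, iv.start - 1, -1) if iv.strand == "-" else range(iv.start, iv.end)
            for pos in rng:
                chroms.append(iv.chrom)
                positions.append(pos)
                owner.append(i)
    return chroms, np.asarray(positions, dtype=np.int64), np.asarray(owner)


def featurize_regions(
    chroms: Sequence[str],
    positions: np.ndarray,
    schema: FeatureSchema,
    tracks: Sequence[AnnotationTrack],
) -> np.ndarray:
    """Feature matrix (n_positions x len(schema)) for single-base lookups."""
    by_id = {t.track_id: t for t in tracks}
    n = len(positions)
    X = np.zeros((n, len(schema)), dtype=np.float64)
    col = 0
    state_cache: dict[str, np.ndarray] = {}
    for d in schema.descriptors:
        track = by_id.get(d.track_id)
        if track is None:
            raise TrackError(f"schema references unknown track {d.track_id!r}")
        if d.kind == "peak":
            X[:, col] = track.peak_at(chroms, positions)
        elif d.kind == "segmentation":
            if d.track_id not in state_cache:
                state_cache[d.track_id] = track.state_at(chroms, positions)
            X[:, col] = state_cache[d.track_id] == d.state
        else:
            raw = track.value_at(chroms, positions)
            X[:, col] = normalize_signal(raw, schema.signal_min, schema.signal_max)
        col += 1
    return X


def featurize_pairs(
    pairs: Sequence[RegionPair],
    a_schema: FeatureSchema,
    b_schema: FeatureSchema,
    a_tracks: Sequence[AnnotationTrack],
    b_tracks: Sequence[AnnotationTrack],
    resolution: str = "first_base",
) -> list[FeatureVectorPair]:
    """Featurize region pairs at first-base (default) or per-base resolution."""
    Xa, Xb, ids, _, _, _ = _featurize_matrices(
        pairs, a_schema, b_schema, a_tracks, b_tracks, resolution
    )
    return [FeatureVectorPair(pid, Xa[i], Xb[i]) for i, pid in enumerate(ids)]


def _featurize_matrices(
    pairs: Sequence[RegionPair],
    a_schema: FeatureSchema,
    b_schema: FeatureSchema,
    a_tracks: Sequence[AnnotationTrack],
    b_tracks: Sequence[AnnotationTrack],
    resolution: str = "first_base",
):
    if resolution not in ("first_base", "per_base"):
        raise ValueError(f"unknown resolution {resolution!r}")
    a_chr, a_pos, owner_a = _representative_positions(pairs, "a", resolution)
    b_chr, b_pos, owner_b = _representative_positions(pairs, "b", resolution)
    if resolution == "per_base" and not np.array_equal(owner_a, owner_b):
        raise ValueError("per_base featurization requires equal-length region pairs")
    Xa = featurize_regions(a_chr, a_pos, a_schema, a_tracks)
    Xb = featurize_regions(b_chr, b_pos, b_schema, b_tracks)
    if resolution == "first_base":
        ids = [p.pair_id for p in pairs]
    else:
        ids = [f"{pairs[i].pair_id}:b{k}" for k, i in enumerate(owner_a)]
    labels = np.asarray(
        [1.0 if pairs[i].label == "positive" else 0.0 for i in owner_a]
    )
    a_chroms = np.asarray([pairs[i].a_region.chrom for i in owner_a], dtype=object)
    b_chroms = np.asarray([pairs[i].b_region.chrom for i in owner_a], dtype=object)
    return Xa, Xb, ids, labels, a_chroms, b_chroms


def build_pair_dataset(
    pairs: Sequence[RegionPair],
    a_schema: FeatureSchema,
    b_schema: FeatureSchema,
    a_tracks: Sequence[AnnotationTrack],
    b_tracks: Sequence[AnnotationTrack],
    resolution: str = "first_base",
) -> PairDataset:
    """Featurize labeled pairs into a :class:`PairDataset` for model training."""
    Xa, Xb, ids, y, a_chroms, b_chroms = _featurize_matrices(
        pairs, a_schema, b_schema, a_tracks, b_tracks, resolution
    )
    return PairDataset(pair_ids=ids, Xa=Xa, Xb=Xb, y=y, a_chrom=a_chroms, b_chrom=b_chroms)
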