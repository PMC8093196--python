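"""Genome-wide score track production and output writers.

Every 50-bp (or truncated) window of every ungapped alignment block gets
one score from the ensemble pair, with each window scored by the ensemble
not trained on its chromosomes; the window's score annotates all its
bases.  A neighborhood-max variant rescans the query side: the species-A
region is re-paired with 50-bp species-B windows stepped outwards from the
aligning region within a symmetric neighborhood of W bases, and the
maximum score is taken (W = 0 reproduces the plain score bit-for-bit).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignments import (
    AlignmentBlock,
    GenomicInterval,
    RegionPair,
    SplitScheme,
    tile_blocks,
)
from .features import (
    AnnotationTrack,
    FeatureSchema,
    build_pair_dataset,
)
from .model import Ensemble, EnsemblePair, predict_ensemble

__all__ = [
    "ScoreTrack",
    "NeighborhoodConfig",
    "score_aligning_genome",
    "neighborhood_max_score",
    "write_score_outputs",
]

_COLUMNS = [
    "a_chrom",
    "a_start",
    "a_end",
    "b_chrom",
    "b_start",
    "b_end",
    "score",
    "block_id",
]


@dataclass
class ScoreTrack:
    """Per-window conservation scores with coordinates in both genomes."""

    records: pd.DataFrame  # columns _COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"score track missing columns {missing}")
        if not np.all(np.isfinite(self.records["score"].to_numpy(dtype=float))):
            raise ValueError("score track contains non-finite scores")
        rec = self.records.sort_values(["a_chrom", "a_start"])
        same = rec["a_chrom"].to_numpy()[1:] == rec["a_chrom"].to_numpy()[:-1]
        if np.any(same & (rec["a_start"].to_numpy()[1:] < rec["a_end"].to_numpy()[:-1])):
            raise ValueError("A intervals overlap within a chromosome")

    def __len__(self) -> int:
        return len(self.records)

    def scores(self) -> np.ndarray:
        return self.records["score"].to_numpy(dtype=float)

    def a_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.a_chrom, int(r.a_start), int(r.a_end))
            for r in self.records.itertuples()
        ]


@dataclass(frozen=True)
class NeighborhoodConfig:
    """Symmetric query-side neighborhood width W in bases (0 = plain score).

    Windows are placed at 50-bp steps outward from the aligning region's
    first base; a W that is not a multiple of the step truncates the
    outermost window (i.e. only whole windows fully inside the neighborhood
    are scored).
    """

    W: int = 0
    step: int = 50

    def __post_init__(self) -> None:
        if self.W < 0:
            raise ValueError("W must be >= 0")


def score_aligning_genome(
    model: Ensemble | EnsemblePair,
    blocks: Sequence[AlignmentBlock],
    a_schema: FeatureSchema,
    b_schema: FeatureSchema,
    a_tracks: Sequence[AnnotationTrack],
    b_tracks: Sequence[AnnotationTrack],
    width: int = 50,
) -> ScoreTrack:
    """Score every window of every alignment block.

    Each window of ``width`` bases (the last one possibly truncated)
    receives one score; the score annotates all bases of the window.
    """
    pairs = tile_blocks(blocks, width)
    ds = build_pair_dataset(pairs, a_schema, b_schema, a_tracks, b_tracks)
    scores = predict_ensemble(model, ds)
    rows = [
        (
            p.a_region.chrom,
            p.a_region.start,
            p.a_region.end,
            p.b_region.chrom,
            p.b_region.start,
            p.b_region.end,
            s,
            p.block_id,
        )
        for p, s in zip(pairs, scores)
    ]
    return ScoreTrack(records=pd.DataFrame(rows, columns=_COLUMNS))


def neighborhood_max_score(
    pair: RegionPair,
    model: Ensemble | EnsemblePair,
    cfg: NeighborhoodConfig,
    a_schema: FeatureSchema,
    b_schema: FeatureSchema,
    a_tracks: Sequence[AnnotationTrack],
    b_tracks: Sequence[AnnotationTrack],
    b_chrom_sizes: Mapping[str, int] | None = None,
) -> float:
    """Maximum score over the A region paired with nearby B windows.

    Candidate B windows step by ``cfg.step`` from the aligning B region's
    first base in both directions, out to offset W; the aligning region
    itself is always included.  Windows extending past the chromosome end
    are dropped (truncation, not an error).
    """
    b = pair.b_region
    size = None if b_chrom_sizes is None else b_chrom_sizes.get(b.chrom)
    candidates: list[RegionPair] = []
    n_steps = cfg.W // cfg.step
    for k in range(-n_steps, n_steps + 1):
        offset = k * cfg.step
        start = b.start + offset
        end = start + len(b)
        if start < 0 or (size is not None and end > size):
            continue
        candidates.append(
            RegionPair(
                a_region=pair.a_region,
                b_region=GenomicInterval(b.chrom, start, end, b.strand),
                block_id=pair.block_id,
                label="unlabeled",
                pair_id=f"{pair.pair_id}@{offset:+d}",
            )
        )
    ds = build_pair_dataset(candidates, a_schema, b_schema, a_tracks, b_tracks)
    scores = predict_ensemble(model, ds)
    return float(scores.max())


def write_score_outputs(track: ScoreTrack, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write the track as (i) a species-A bedGraph and (ii) a paired TSV.

    Both outputs are sorted by A coordinate and keep one row per window
    (adjacent equal-score windows are NOT merged, preserving resolution).
    Scores print with 6 decimal places.
    """
    scores = track.records["score"].to_numpy(dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("cannot write non-finite scores")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    rec = track.records.sort_values(["a_chrom", "a_start"])
    bedgraph = out_prefix.with_suffix(".bedGraph")
    with open(bedgraph, "w") as fh:
        for r in rec.itertuples():
            fh.write(f"{r.a_chrom}\t{r.a_start}\t{r.a_end}\t{r.score:.6f}\n")
    tsv = out_prefix.with_suffix(".pairs.tsv")
    rec_out = rec.copy()
    rec_out["score"] = rec_out["score"].map(lambda s: f"{s:.6f}")
    rec_out.to_csv(tsv, sep="\t", index=False)
    return bedgraph, tsv
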