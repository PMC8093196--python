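"""End-to-end orchestration: fixture files -> featurized datasets -> models.

Thin convenience layer used by the command-line interface, the test suite
and the reproduction script.  Negatives are generated within each
chromosome-split role separately, so the mismatch-derangement marginal
matching holds exactly inside every role (train, validation, test), not
just globally.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .alignments import (
    AlignmentBlock,
    RegionPair,
    SplitScheme,
    assign_splits,
    generate_training_pairs,
    load_alignment_blocks,
    select_best_partner,
    tile_blocks,
)
from .features import (
    AnnotationTrack,
    FeatureSchema,
    PairDataset,
    build_feature_schema,
    build_pair_dataset,
    load_annotations,
)

__all__ = ["PairedData", "read_chrom_sizes", "prepare_paired_data"]


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={0: str})
    return dict(zip(df["chrom"], df["size"].astype(int)))


@dataclass
class PairedData:
    """Everything the modeling layer needs, derived from one fixture."""

    blocks: list[AlignmentBlock]
    positives: list[RegionPair]
    scheme: SplitScheme
    pairs_by_role: dict[str, list[RegionPair]]
    datasets: dict[str, PairDataset]
    a_schema: FeatureSchema
    b_schema: FeatureSchema
    a_tracks: list[AnnotationTrack]
    b_tracks: list[AnnotationTrack]


def prepare_paired_data(
    axt_path: str | Path,
    b_chrom_sizes: Mapping[str, int],
    manifest_a: str | Path,
    manifest_b: str | Path,
    seed: int,
    width: int = 50,
    scheme: SplitScheme | None = None,
    neg_mode: str = "mismatch",
    genome_sizes: tuple[Mapping[str, int], Mapping[str, int]] | None = None,
) -> PairedData:
    """Run the data pipeline: blocks -> windows -> negatives -> features.

    Positive pairs are assigned to roles first; each evaluation role then
    receives its own derangement negatives drawn from its own positives.
    """
    blocks = select_best_partner(load_alignment_blocks(axt_path, b_chrom_sizes))
    positives = tile_blocks(blocks, width)
    if scheme is None:
        scheme = SplitScheme.from_parity(
            {b.a_interval.chrom for b in blocks},
            {b.b_interval.chrom for b in blocks},
        )
    pos_by_role = assign_splits(positives, scheme)

    a_tracks = load_annotations(manifest_a)
    b_tracks = load_annotations(manifest_b)
    a_schema = build_feature_schema(a_tracks)
    b_schema = build_feature_schema(b_tracks)

    pairs_by_role: dict[str, list[RegionPair]] = {}
    datasets: dict[str, PairDataset] = {}
    for offset, role in enumerate(SplitScheme.EVAL_ROLES):
        role_pos = pos_by_role.get(role, [])
        if len(role_pos) < 2:
            continue
        labeled = generate_training_pairs(
            role_pos,
            mode=neg_mode,
            seed=seed + 1 + offset,
            genome_sizes=genome_sizes,
        )
        pairs_by_role[role] = labeled
        datasets[role] = build_pair_dataset(
            labeled, a_schema, b_schema, a_tracks, b_tracks
        )
    pairs_by_role["predict"] = pos_by_role.get("predict", [])

    return PairedData(
        blocks=blocks,
        positives=positives,
        scheme=scheme,
        pairs_by_role=pairs_by_role,
        datasets=datasets,
        a_schema=a_schema,
        b_schema=b_schema,
        a_tracks=a_tracks,
        b_tracks=b_tracks,
    )
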