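"""Pairwise-alignment handling: axt parsing, ungapped blocks, paired windows.

The supervised signal for cross-species conservation scoring comes entirely
from a chained/netted pairwise genome alignment.  This module turns an axt
file into maximal ungapped :class:`AlignmentBlock` objects, tiles each block
into non-overlapping paired windows of at most 50 bp (:class:`RegionPair`),
builds mismatch or genome-background negatives, and partitions pairs into
chromosome-disjoint train/validation/test/predict roles.

Coordinates are 0-based half-open internally (BED convention).  axt headers
are 1-based inclusive and, for minus-strand query records, expressed in
reverse-complement coordinates; both conventions are converted on read.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "AlignmentRecord",
    "AlignmentBlock",
    "RegionPair",
    "SplitScheme",
    "AxtParseError",
    "load_alignment_records",
    "load_alignment_blocks",
    "records_to_blocks",
    "select_best_partner",
    "tile_block_windows",
    "generate_training_pairs",
    "assign_splits",
    "write_pairs_tsv",
    "read_pairs_tsv",
]

DEFAULT_WINDOW = 50


class AxtParseError(ValueError):
    """Raised when an axt record is structurally invalid."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def reverse_complement_interval(
    interval: GenomicInterval, chrom_size: int
) -> GenomicInterval:
    """Map an interval between forward and reverse-complement coordinates.

    Applying the conversion twice is the identity.
    """
    return GenomicInterval(
        chrom=interval.chrom,
        start=chrom_size - interval.end,
        end=chrom_size - interval.start,
        strand="-" if interval.strand == "+" else "+",
    )


@dataclass(frozen=True)
class AlignmentRecord:
    """One gapped axt alignment between a reference (A) and query (B) segment.

    ``b_interval`` is stored in forward-strand coordinates; ``strand`` records
    the original orientation of the query.  The gapped sequences retain axt
    orientation (B reverse-complemented for minus-strand records), so column
    offsets into ``b_gapped`` run along the reverse strand in that case.
    """

    a_interval: GenomicInterval
    b_interval: GenomicInterval
    a_gapped: str
    b_gapped: str
    score: int
    index: int = 0

    def __post_init__(self) -> None:
        if len(self.a_gapped) != len(self.b_gapped):
            raise AxtParseError(
                f"record {self.index}: gapped sequences differ in length "
                f"({len(self.a_gapped)} vs {len(self.b_gapped)})"
            )
        a_len = sum(1 for c in self.a_gapped if c != "-")
        b_len = sum(1 for c in self.b_gapped if c != "-")
        if a_len != len(self.a_interval):
            raise AxtParseError(
                f"record {self.index}: ungapped A length {a_len} does not match "
                f"interval length {len(self.a_interval)}"
            )
        if b_len != len(self.b_interval):
            raise AxtParseError(
                f"record {self.index}: ungapped B length {b_len} does not match "
                f"interval length {len(self.b_interval)}"
            )


@dataclass(frozen=True)
class AlignmentBlock:
    """A maximal gap-free stretch of an alignment record.

    Both sides have equal length, so base offsets correspond 1:1.  For
    minus-strand queries, A offset ``o`` maps to forward B position
    ``b.end - 1 - o``; for plus strand, ``b.start + o``.
    """

    a_interval: GenomicInterval
    b_interval: GenomicInterval
    score: int
    block_id: str = ""

    def __post_init__(self) -> None:
        if len(self.a_interval) != len(self.b_interval):
            raise ValueError(
                f"block {self.block_id}: side lengths differ "
                f"({len(self.a_interval)} vs {len(self.b_interval)})"
            )

    def __len__(self) -> int:
        return len(self.a_interval)

    def b_subinterval(self, offset: int, length: int) -> GenomicInterval:
        """Forward-strand B interval paired with A offsets [offset, offset+length)."""
        b = self.b_interval
        if b.strand == "+":
            return GenomicInterval(b.chrom, b.start + offset, b.start + offset + length, "+")
        return GenomicInterval(
            b.chrom, b.end - offset - length, b.end - offset, "-"
        )


@dataclass(frozen=True)
class RegionPair:
    """A species-A region (<= 50 bp) paired with a species-B region."""

    a_region: GenomicInterval
    b_region: GenomicInterval
    block_id: str
    label: str = "unlabeled"  # positive | negative | unlabeled
    pair_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative", "unlabeled"):
            raise ValueError(f"unknown label {self.label!r}")


# ---------------------------------------------------------------------------
# axt parsing


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_alignment_records(
    axt_path: str | Path,
    b_chrom_sizes: Mapping[str, int] | None = None,
) -> list[AlignmentRecord]:
    """Parse an axt file (optionally gzipped) into alignment records.

    axt query coordinates for minus-strand records follow the
    reverse-complement convention; converting them to forward-strand
    coordinates requires the query chromosome sizes, so ``b_chrom_sizes``
    is mandatory whenever such a record is present.
    """
    records: list[AlignmentRecord] = []
    with _open_text(axt_path) as fh:
        lines = (ln.rstrip("\n") for ln in fh)
        content = [ln for ln in lines if not ln.startswith("#")]
    i = 0
    rec_idx = 0
    n = len(content)
    while i < n:
        if not content[i].strip():
            i += 1
            continue
        header = content[i].split()
        if len(header) != 9:
            raise AxtParseError(
                f"record {rec_idx}: expected 9 header fields, got {len(header)}"
            )
        if i + 2 >= n:
            raise AxtParseError(f"record {rec_idx}: truncated record body")
        try:
            a_chrom, a_start, a_end = header[1], int(header[2]), int(header[3])
            b_chrom, b_start, b_end = header[4], int(header[5]), int(header[6])
            strand = header[7]
            score = int(header[8])
        except ValueError as exc:
            raise AxtParseError(f"record {rec_idx}: malformed header: {exc}") from exc
        if strand not in ("+", "-"):
            raise AxtParseError(f"record {rec_idx}: bad strand {strand!r}")
        a_seq = content[i + 1].strip()
        b_seq = content[i + 2].strip()
        a_iv = GenomicInterval(a_chrom, a_start - 1, a_end, "+")
        b_iv = GenomicInterval(b_chrom, b_start - 1, b_end, "+")
        if strand == "-":
            if b_chrom_sizes is None or b_chrom not in b_chrom_sizes:
                raise AxtParseError(
                    f"record {rec_idx}: minus-strand query on {b_chrom} requires "
                    "b_chrom_sizes for coordinate conversion"
                )
            b_iv = reverse_complement_interval(b_iv, b_chrom_sizes[b_chrom])
        try:
            records.append(
                AlignmentRecord(
                    a_interval=a_iv,
                    b_interval=b_iv,
                    a_gapped=a_seq,
                    b_gapped=b_seq,
                    score=score,
                    index=rec_idx,
                )
            )
        except AxtParseError:
            raise
        rec_idx += 1
        i += 3
    return records


def record_to_blocks(record: AlignmentRecord) -> list[AlignmentBlock]:
    """Split one gapped record at every gap column into maximal ungapped blocks."""
    blocks: list[AlignmentBlock] = []
    a_off = 0  # ungapped offset into A
    b_off = 0  # ungapped offset into B, along axt (possibly reverse) orientation
    run_start: tuple[int, int] | None = None
    minus = record.b_interval.strand == "-"

    def close_run(a_end_off: int, b_end_off: int) -> None:
        if run_start is None:
            return
        a0, b0 = run_start
        length = a_end_off - a0
        a_iv = GenomicInterval(
            record.a_interval.chrom,
            record.a_interval.start + a0,
            record.a_interval.start + a_end_off,
            "+",
        )
        if minus:
            # offsets run along the reverse strand: offset 0 is b_interval.end
            b_iv = GenomicInterval(
                record.b_interval.chrom,
                record.b_interval.end - b_end_off,
                record.b_interval.end - b0,
                "-",
            )
        else:
            b_iv = GenomicInterval(
                record.b_interval.chrom,
                record.b_interval.start + b0,
                record.b_interval.start + b_end_off,
                "+",
            )
        assert len(a_iv) == len(b_iv) == length
        blocks.append(
            AlignmentBlock(
                a_interval=a_iv,
                b_interval=b_iv,
                score=record.score,
                block_id=f"{record.index}.{len(blocks)}",
            )
        )

    for a_char, b_char in zip(record.a_gapped, record.b_gapped):
        a_gap = a_char == "-"
        b_gap = b_char == "-"
        if not a_gap and not b_gap:
            if run_start is None:
                run_start = (a_off, b_off)
        else:
            close_run(a_off, b_off)
            run_start = None
        if not a_gap:
            a_off += 1
        if not b_gap:
            b_off += 1
    close_run(a_off, b_off)
    return blocks


def records_to_blocks(records: Iterable[AlignmentRecord]) -> list[AlignmentBlock]:
    return [blk for rec in records for blk in record_to_blocks(rec)]


def load_alignment_blocks(
    axt_path: str | Path,
    b_chrom_sizes: Mapping[str, int] | None = None,
) -> list[AlignmentBlock]:
    """Parse an axt file and return its maximal ungapped alignment blocks."""
    return records_to_blocks(load_alignment_records(axt_path, b_chrom_sizes))


# ---------------------------------------------------------------------------
# best-partner selection


def _partner_key(block: AlignmentBlock) -> tuple:
    # higher score wins; ties broken by lower B chromosome name then lower B start
    return (-block.score, block.b_interval.chrom, block.b_interval.start)


def select_best_partner(blocks: Sequence[AlignmentBlock]) -> list[AlignmentBlock]:
    """Resolve A-segments with multiple candidate B-partners.

    Where blocks overlap on the A genome, only the highest-scoring candidate
    is kept; ties break deterministically by (score, B chromosome, B start).
    Output is sorted by A coordinate.
    """
    by_chrom: dict[str, list[AlignmentBlock]] = {}
    for blk in blocks:
        by_chrom.setdefault(blk.a_interval.chrom, []).append(blk)
    kept: list[AlignmentBlock] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda b: (b.a_interval.start, _partner_key(b)))
        chosen: list[AlignmentBlock] = []
        for blk in group:
            if chosen and chosen[-1].a_interval.overlaps(blk.a_interval):
                if _partner_key(blk) < _partner_key(chosen[-1]):
                    chosen[-1] = blk
            else:
                chosen.append(blk)
        kept.extend(chosen)
    return kept


# ---------------------------------------------------------------------------
# windowing


def tile_block_windows(
    block: AlignmentBlock, width: int = DEFAULT_WINDOW
) -> list[RegionPair]:
    """Tile a block into non-overlapping paired windows of at most ``width`` bp.

    Windows start from the first base of the block; the final window is
    truncated at the block end, so it may be shorter than ``width``.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    pairs: list[RegionPair] = []
    n = len(block)
    for w_idx, offset in enumerate(range(0, n, width)):
        length = min(width, n - offset)
        a_iv = GenomicInterval(
            block.a_interval.chrom,
            block.a_interval.start + offset,
            block.a_interval.start + offset + length,
            "+",
        )
        b_iv = block.b_subinterval(offset, length)
        pairs.append(
            RegionPair(
                a_region=a_iv,
                b_region=b_iv,
                block_id=block.block_id,
                label="positive",
                pair_id=f"{block.block_id}:{w_idx}",
            )
        )
    return pairs


def tile_blocks(
    blocks: Iterable[AlignmentBlock], width: int = DEFAULT_WINDOW
) -> list[RegionPair]:
    return [p for blk in blocks for p in tile_block_windows(blk, width)]


# ---------------------------------------------------------------------------
# negatives


def generate_training_pairs(
    positives: Sequence[RegionPair],
    mode: str = "mismatch",
    seed: int | None = None,
    genome_sizes: tuple[Mapping[str, int], Mapping[str, int]] | None = None,
    max_shuffles: int = 50,
) -> list[RegionPair]:
    """Label positives and construct one negative per positive.

    In ``mismatch`` mode B-regions are permuted over A-regions such that no
    A-region keeps any B-region it truly aligns to (a derangement with
    respect to the alignment relation); every region appearing in a negative
    therefore also appears in some positive, which matches each feature's
    marginal distribution exactly between the two classes.  In
    ``genome_background`` mode both members are drawn uniformly from their
    genomes (requires ``genome_sizes``).

    Returns the concatenated labeled list (positives first, then negatives).
    """
    if seed is None:
        raise ValueError("seed is required for reproducible negative sampling")
    if mode not in ("mismatch", "genome_background"):
        raise ValueError(f"unknown negative mode {mode!r}")
    rng = np.random.default_rng(seed)
    n = len(positives)
    labeled = [replace(p, label="positive") for p in positives]

    if mode == "genome_background":
        if genome_sizes is None:
            raise ValueError("genome_background mode requires genome_sizes")
        a_sizes, b_sizes = genome_sizes
        negatives = []
        for i, pos in enumerate(positives):
            length = len(pos.a_region)
            a_chrom = str(rng.choice(sorted(a_sizes)))
            b_chrom = str(rng.choice(sorted(b_sizes)))
            a_start = int(rng.integers(0, a_sizes[a_chrom] - length))
            b_start = int(rng.integers(0, b_sizes[b_chrom] - length))
            negatives.append(
                RegionPair(
                    a_region=GenomicInterval(a_chrom, a_start, a_start + length),
                    b_region=GenomicInterval(b_chrom, b_start, b_start + length),
                    block_id="",
                    label="negative",
                    pair_id=f"neg_gb:{i}",
                )
            )
        return labeled + negatives

    if n < 2:
        raise ValueError("mismatch negatives need >= 2 positives (no derangement exists)")

    # forbidden pairs: the true alignment relation over these positives
    relation = {(p.a_region.key, p.b_region.key) for p in positives}
    a_keys = [p.a_region.key for p in positives]
    perm = np.arange(n)

    def collisions(p: np.ndarray) -> np.ndarray:
        bad = [
            i
            for i in range(n)
            if (a_keys[i], positives[p[i]].b_region.key) in relation
        ]
        return np.asarray(bad, dtype=int)

    for _ in range(max_shuffles):
        rng.shuffle(perm)
        if collisions(perm).size == 0:
            break
    # fix residual collisions by pairwise swaps with random partners
    bad = collisions(perm)
    guard = 0
    while bad.size > 0:
        guard += 1
        if guard > 1000:
            raise RuntimeError("could not derange negatives; too many forbidden pairs")
        for i in bad:
            j = int(rng.integers(0, n))
            perm[i], perm[j] = perm[j], perm[i]
        bad = collisions(perm)

    negatives = [
        RegionPair(
            a_region=positives[i].a_region,
            b_region=positives[perm[i]].b_region,
            block_id="",
            label="negative",
            pair_id=f"neg:{positives[i].pair_id}",
        )
        for i in range(n)
    ]
    return labeled + negatives


# ---------------------------------------------------------------------------
# chromosome splits


@dataclass(frozen=True)
class SplitScheme:
    """Per-role, per-species chromosome sets.

    ``roles`` maps role name (train/validation/test/predict) to a pair of
    chromosome sets (species A, species B).  Train, validation and test sets
    must be pairwise disjoint within each species so no genomic region can
    leak between fitting and evaluation.
    """

    roles: Mapping[str, tuple[frozenset, frozenset]]

    EVAL_ROLES = ("train", "validation", "test")

    def __post_init__(self) -> None:
        for side in (0, 1):
            for r1, r2 in itertools.combinations(
                [r for r in self.EVAL_ROLES if r in self.roles], 2
            ):
                common = self.roles[r1][side] & self.roles[r2][side]
                if common:
                    raise ValueError(
                        f"chromosome sets overlap between {r1} and {r2}: {sorted(common)}"
                    )

    @classmethod
    def from_parity(
        cls,
        chroms_a: Iterable[str],
        chroms_b: Iterable[str],
        train_on: str = "odd",
        exclude: Iterable[str] = ("chrX", "chrY", "chrM"),
    ) -> "SplitScheme":
        """Build the default parity scheme.

        Chromosomes of the training parity are themselves split: alternating
        members go to train and validation, so the validation chromosomes are
        training-parity chromosomes not used in training.  The opposite
        parity forms the test set; prediction covers everything (including
        any excluded-from-training chromosomes such as chrX).
        """

        def parity_sets(chroms: Iterable[str]) -> tuple[list, list]:
            odd, even = [], []
            for c in sorted(set(chroms), key=_chrom_sort_key):
                num = _chrom_number(c)
                if num is None:
                    continue
                (odd if num % 2 == 1 else even).append(c)
            return odd, even

        excl = set(exclude)
        roles = {}
        a_all = sorted(set(chroms_a), key=_chrom_sort_key)
        b_all = sorted(set(chroms_b), key=_chrom_sort_key)
        a_odd, a_even = parity_sets(c for c in chroms_a if c not in excl)
        b_odd, b_even = parity_sets(c for c in chroms_b if c not in excl)
        if train_on == "odd":
            a_fit, b_fit, a_test, b_test = a_odd, b_odd, a_even, b_even
        elif train_on == "even":
            a_fit, b_fit, a_test, b_test = a_even, b_even, a_odd, b_odd
        else:
            raise ValueError("train_on must be 'odd' or 'even'")
        roles["train"] = (frozenset(a_fit[0::2]), frozenset(b_fit[0::2]))
        roles["validation"] = (frozenset(a_fit[1::2]), frozenset(b_fit[1::2]))
        roles["test"] = (frozenset(a_test), frozenset(b_test))
        roles["predict"] = (frozenset(a_all), frozenset(b_all))
        for role in ("train", "validation"):
            if not roles[role][0] or not roles[role][1]:
                raise ValueError(
                    f"not enough chromosomes to populate the {role} role"
                )
        return cls(roles=roles)

    def complement(self) -> "SplitScheme":
        """Swap the fitting parity (train/validation <-> test)."""
        roles = dict(self.roles)
        test_a = sorted(roles["test"][0], key=_chrom_sort_key)
        test_b = sorted(roles["test"][1], key=_chrom_sort_key)
        fit_a = sorted(roles["train"][0] | roles["validation"][0], key=_chrom_sort_key)
        fit_b = sorted(roles["train"][1] | roles["validation"][1], key=_chrom_sort_key)
        new = {
            "train": (frozenset(test_a[0::2]), frozenset(test_b[0::2])),
            "validation": (frozenset(test_a[1::2]), frozenset(test_b[1::2])),
            "test": (frozenset(fit_a), frozenset(fit_b)),
            "predict": roles.get("predict", (frozenset(), frozenset())),
        }
        return SplitScheme(roles=new)

    def role_of_pair(self, pair: RegionPair) -> str | None:
        """The evaluation role of a pair, or None if it matches none.

        A pair enters a role only if BOTH its A and B chromosomes belong to
        that role's sets.
        """
        for role in self.EVAL_ROLES:
            if role not in self.roles:
                continue
            a_set, b_set = self.roles[role]
            if pair.a_region.chrom in a_set and pair.b_region.chrom in b_set:
                return role
        return None


def _chrom_number(chrom: str) -> int | None:
    tail = chrom[3:] if chrom.startswith("chr") else chrom
    try:
        return int(tail)
    except ValueError:
        return None


def _chrom_sort_key(chrom: str) -> tuple:
    num = _chrom_number(chrom)
    return (0, num, chrom) if num is not None else (1, 0, chrom)


def assign_splits(
    pairs: Sequence[RegionPair], scheme: SplitScheme
) -> dict[str, list[RegionPair]]:
    """Partition pairs into train/validation/test plus a predict catch-all.

    Pairs matching no evaluation role are dropped from train/validation/test
    but retained under ``predict`` when that role covers them.
    """
    out: dict[str, list[RegionPair]] = {r: [] for r in scheme.roles}
    predict_sets = scheme.roles.get("predict")
    for pair in pairs:
        role = scheme.role_of_pair(pair)
        if role is not None:
            out[role].append(pair)
        if predict_sets is not None:
            a_set, b_set = predict_sets
            if pair.a_region.chrom in a_set and pair.b_region.chrom in b_set:
                out["predict"].append(pair)
    return out


# ---------------------------------------------------------------------------
# I/O

_PAIR_COLUMNS = [
    "pair_id",
    "a_chrom",
    "a_start",
    "a_end",
    "b_chrom",
    "b_start",
    "b_end",
    "label",
    "block_id",
]


def write_pairs_tsv(pairs: Sequence[RegionPair], path: str | Path) -> None:
    import pandas as pd

    rows = [
        (
            p.pair_id,
            p.a_region.chrom,
            p.a_region.start,
            p.a_region.end,
            p.b_region.chrom,
            p.b_region.start,
            p.b_region.end,
            p.label,
            p.block_id,
        )
        for p in pairs
    ]
    pd.DataFrame(rows, columns=_PAIR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path: str | Path) -> list[RegionPair]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"a_chrom": str, "b_chrom": str})
    return [
        RegionPair(
            a_region=GenomicInterval(r.a_chrom, int(r.a_start), int(r.a_end)),
            b_region=GenomicInterval(r.b_chrom, int(r.b_start), int(r.b_end)),
            block_id="" if pd.isna(r.block_id) else str(r.block_id),
            label=str(r.label),
            pair_id=str(r.pair_id),
        )
        for r in df.itertuples()
    ]


def write_pairs_bed(
    pairs: Sequence[RegionPair], path: str | Path, side: str = "a"
) -> None:
    """Export one side of each pair as BED6 (score column carries the label)."""
    with open(path, "w") as fh:
        for p in pairs:
            iv = p.a_region if side == "a" else p.b_region
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.pair_id}\t0\t{iv.strand}\n"
            )
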