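"""Synthetic two-species datasets with planted cross-species concordance.

The generator emulates the structure of a real cross-species functional
genomics compendium without modeling real biology.  Each genome carries a
latent regulatory activity per segment: a categorical state (quiescent /
enhancer-like / promoter-like) plus a continuous intensity in [0, 1].
Within sequence-aligning intervals, species B inherits species A's latent
activity with probability rho (the planted concordance); elsewhere, and
with probability 1 - rho, its activity is drawn independently.  Observed
tracks -- peak calls, chromatin-state segmentations across epigenomes, and
continuous signal -- are noisy emissions of the latent activity, so aligned
pairs carry statistically dependent annotations exactly when concordance
was planted.

At rho = 0 aligned pairs are feature-independent across species; at rho = 1
with zero assay noise their latent-derived features agree exactly.  All
randomness flows from the config seed and files are written in a fixed
order, so the same config yields a byte-identical fixture.

Emitted files parse with the package's own loaders: an axt alignment
(including minus-strand records), chrom.sizes tables, per-species track
manifests with BED / dense-BED / bedGraph tracks, and a variant BED with an
optionally planted enrichment in active aligned segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .alignments import (
    AlignmentBlock,
    AlignmentRecord,
    GenomicInterval,
    records_to_blocks,
    reverse_complement_interval,
)

__all__ = ["SyntheticConfig", "SyntheticDataset", "simulate_dataset", "concordance_audit"]

_STATES = ("quiescent", "enhancer", "promoter")
_STATE_LABEL = {0: "3", 1: "2", 2: "1"}  # segmentation labels per latent state
_N_SEG_STATES = 5
_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the desk-scale study conditions."""

    n_chroms_a: int = 4
    n_chroms_b: int = 4
    chrom_length: int = 1_000_000
    segment: int = 200              # latent-activity resolution in bases
    n_records: int = 2000           # gapped alignment records
    record_min: int = 200           # matched columns per record
    record_max: int = 800
    gap_rate: float = 0.01          # expected gap columns per matched column
    rho: float = 0.9                # planted cross-species concordance
    state_probs: tuple[float, float, float] = (0.55, 0.25, 0.20)
    aligned_activity_boost: float = 1.5   # active-state bias inside aligned A segments
    n_peak_tracks: int = 6          # per species; round-robin over tissue groups
    tissue_groups: tuple[str, ...] = ("liver", "brain", "heart")
    n_epigenomes: int = 2           # segmentation tracks per species
    n_signal_tracks: int = 1
    assay_noise: float = 0.1
    variant_rate: float = 2e-4      # per base, background
    variant_effect: float = 4.0     # rate multiplier in active aligned segments
    plant_variant_effect: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [0, 1]")
        if self.record_max + 1000 > self.chrom_length:
            raise ValueError("records longer than chromosomes")
        if min(self.n_chroms_a, self.n_chroms_b, self.n_records) < 1:
            raise ValueError("counts must be >= 1")

    @property
    def chroms_a(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms_a)]

    @property
    def chroms_b(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms_b)]


@dataclass
class _LatentTrack:
    """Piecewise-constant latent activity on one chromosome."""

    starts: np.ndarray
    ends: np.ndarray
    state: np.ndarray      # int in {0, 1, 2}
    intensity: np.ndarray  # float in [0, 1]
    coupled: np.ndarray    # -1 background, 0 aligned-uncoupled, 1 aligned-coupled

    def at(self, pos: np.ndarray) -> np.ndarray:
        """Index of the latent interval covering each position."""
        idx = np.searchsorted(self.starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < self.ends[np.clip(idx, 0, None)])
        if not np.all(ok):
            raise IndexError("position outside latent coverage")
        return idx


@dataclass
class SyntheticDataset:
    """Paths plus in-memory latent truth for generator self-validation."""

    cfg: SyntheticConfig
    root: Path
    axt: Path
    manifest_a: Path
    manifest_b: Path
    chrom_sizes_a: dict[str, int]
    chrom_sizes_b: dict[str, int]
    variants: Path
    latent_a: dict[str, _LatentTrack]
    latent_b: dict[str, _LatentTrack]
    records: list[AlignmentRecord]

    @property
    def blocks(self) -> list[AlignmentBlock]:
        return records_to_blocks(self.records)


def _draw_intensity(rng: np.random.Generator, states: np.ndarray) -> np.ndarray:
    """Latent intensity given state: higher and tighter for active states."""
    a = np.choose(states, [1.5, 4.0, 6.0])
    b = np.choose(states, [8.0, 4.0, 2.0])
    return rng.beta(a, b)


def _aligned_mask_a(cfg: SyntheticConfig, layout_a, chrom: str, n_seg: int) -> np.ndarray:
    mask = np.zeros(n_seg, dtype=bool)
    for (c, start, end) in layout_a:
        if c != chrom:
            continue
        mask[start // cfg.segment : (end - 1) // cfg.segment + 1] = True
    return mask


def simulate_dataset(cfg: SyntheticConfig, out_dir: str | Path) -> SyntheticDataset:
    """Generate a complete on-disk fixture and return its handle."""
    rng = np.random.default_rng(cfg.seed)
    root = Path(out_dir)
    (root / "tracks").mkdir(parents=True, exist_ok=True)

    sizes_a = {c: cfg.chrom_length for c in cfg.chroms_a}
    sizes_b = {c: cfg.chrom_length for c in cfg.chroms_b}

    records, layout_a, layout_b = _make_alignment(cfg, rng, sizes_a, sizes_b)
    latent_a = _latent_for_a(cfg, rng, sizes_a, layout_a)
    latent_b = _latent_for_b(cfg, rng, sizes_b, records, latent_a)

    axt_path = root / "alignment.axt"
    _write_axt(axt_path, records, sizes_b)
    _write_sizes(root / "a.chrom.sizes", sizes_a)
    _write_sizes(root / "b.chrom.sizes", sizes_b)

    manifest_a = _emit_tracks(cfg, rng, root, "speciesA", "a", latent_a)
    manifest_b = _emit_tracks(cfg, rng, root, "speciesB", "b", latent_b)

    variants = root / "variants.bed"
    _emit_variants(cfg, rng, variants, latent_a)

    return SyntheticDataset(
        cfg=cfg,
        root=root,
        axt=axt_path,
        manifest_a=manifest_a,
        manifest_b=manifest_b,
        chrom_sizes_a=sizes_a,
        chrom_sizes_b=sizes_b,
        variants=variants,
        latent_a=latent_a,
        latent_b=latent_b,
        records=records,
    )


# ---------------------------------------------------------------------------
# alignment geometry


def _make_alignment(cfg, rng, sizes_a, sizes_b):
    """Place non-overlapping alignment records on both genomes."""
    margin = 500
    cursors_a = {c: margin for c in cfg.chroms_a}
    cursors_b = {c: margin for c in cfg.chroms_b}
    records: list[AlignmentRecord] = []
    layout_a: list[tuple[str, int, int]] = []
    layout_b: list[tuple[str, int, int]] = []
    chroms_a = cfg.chroms_a
    chroms_b = cfg.chroms_b
    for i in range(cfg.n_records):
        matched = int(rng.integers(cfg.record_min, cfg.record_max + 1))
        n_gap_a = int(rng.poisson(cfg.gap_rate * matched / 2))
        n_gap_b = int(rng.poisson(cfg.gap_rate * matched / 2))
        len_a = matched + n_gap_b  # B-gap columns carry an A base
        len_b = matched + n_gap_a
        # syntenic layout: chromosome i of A aligns to chromosome i of B,
        # mirroring the strong large-scale synteny of mammalian genomes and
        # leaving every chromosome-parity split well populated
        a_chrom = chroms_a[i % len(chroms_a)]
        b_chrom = chroms_b[i % len(chroms_b)]
        spacing_a = int(rng.integers(100, 400))
        spacing_b = int(rng.integers(100, 400))
        a_start = cursors_a[a_chrom] + spacing_a
        b_start = cursors_b[b_chrom] + spacing_b
        if (
            a_start + len_a > sizes_a[a_chrom] - margin
            or b_start + len_b > sizes_b[b_chrom] - margin
        ):
            continue  # chromosome full
        cursors_a[a_chrom] = a_start + len_a
        cursors_b[b_chrom] = b_start + len_b
        strand = "+" if rng.random() < 0.5 else "-"

        # column structure: shuffle gap columns among matched columns
        n_cols = matched + n_gap_a + n_gap_b
        kinds = np.concatenate(
            [
                np.zeros(matched, dtype=int),       # 0 = match
                np.ones(n_gap_a, dtype=int),        # 1 = gap in A
                np.full(n_gap_b, 2, dtype=int),     # 2 = gap in B
            ]
        )
        rng.shuffle(kinds)
        a_seq = np.where(kinds == 1, "-", _BASES[rng.integers(0, 4, n_cols)])
        b_seq = np.where(kinds == 2, "-", _BASES[rng.integers(0, 4, n_cols)])

        records.append(
            AlignmentRecord(
                a_interval=GenomicInterval(a_chrom, a_start, a_start + len_a, "+"),
                b_interval=GenomicInterval(
                    b_chrom, b_start, b_start + len_b, strand
                ),
                a_gapped="".join(a_seq),
                b_gapped="".join(b_seq),
                score=matched * 10 + int(rng.integers(0, 100)),
                index=len(records),
            )
        )
        layout_a.append((a_chrom, a_start, a_start + len_a))
        layout_b.append((b_chrom, b_start, b_start + len_b))
    return records, layout_a, layout_b


def _write_axt(path: Path, records, sizes_b) -> None:
    with open(path, "w") as fh:
        fh.write("# synthetic pairwise alignment\n")
        for rec in records:
            b = rec.b_interval
            if b.strand == "-":
                b_out = reverse_complement_interval(b, sizes_b[b.chrom])
            else:
                b_out = b
            a = rec.a_interval
            fh.write(
                f"{rec.index} {a.chrom} {a.start + 1} {a.end} "
                f"{b.chrom} {b_out.start + 1} {b_out.end} {b.strand} {rec.score}\n"
            )
            fh.write(rec.a_gapped + "\n")
            fh.write(rec.b_gapped + "\n")
            fh.write("\n")


def _write_sizes(path: Path, sizes: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


# ---------------------------------------------------------------------------
# latent activity


def _latent_for_a(cfg, rng, sizes, layout_a) -> dict[str, _LatentTrack]:
    out: dict[str, _LatentTrack] = {}
    probs = np.asarray(cfg.state_probs)
    boosted = probs * np.array([1.0, cfg.aligned_activity_boost, cfg.aligned_activity_boost])
    boosted = boosted / boosted.sum()
    for chrom in sorted(sizes):
        size = sizes[chrom]
        n_seg = (size + cfg.segment - 1) // cfg.segment
        starts = np.arange(n_seg, dtype=np.int64) * cfg.segment
        ends = np.minimum(starts + cfg.segment, size)
        aligned = _aligned_mask_a(cfg, layout_a, chrom, n_seg)
        # aligned segments get a mild bias toward active states
        u = rng.random(n_seg)
        cum_bg = np.cumsum(probs)
        cum_al = np.cumsum(boosted)
        state = np.where(
            aligned,
            np.searchsorted(cum_al, u, side="right"),
            np.searchsorted(cum_bg, u, side="right"),
        ).astype(int)
        state = np.clip(state, 0, 2)
        intensity = _draw_intensity(rng, state)
        out[chrom] = _LatentTrack(
            starts=starts,
            ends=ends,
            state=state,
            intensity=intensity,
            coupled=np.where(aligned, 0, -1).astype(int),
        )
    return out


def _latent_for_b(cfg, rng, sizes, records, latent_a) -> dict[str, _LatentTrack]:
    """Background grid latent, overridden inside aligned intervals.

    Within each ungapped block, runs of B bases mapping into one A latent
    segment inherit that segment's activity with probability rho (with a
    small intensity perturbation); otherwise the run draws independently.
    """
    probs = np.asarray(cfg.state_probs)
    # collect aligned runs per B chromosome
    runs: dict[str, list[tuple[int, int, int, float, int]]] = {c: [] for c in sizes}
    for block in records_to_blocks(records):
        a_iv = block.a_interval
        la = latent_a[a_iv.chrom]
        off = 0
        n = len(block)
        while off < n:
            a_pos = a_iv.start + off
            seg_end = (a_pos // cfg.segment + 1) * cfg.segment
            run_len = min(seg_end - a_pos, n - off)
            seg_idx = int(la.at(np.asarray([a_pos]))[0])
            if rng.random() < cfg.rho:
                state = int(la.state[seg_idx])
                intensity = float(
                    np.clip(la.intensity[seg_idx] + rng.normal(0, 0.05), 0, 1)
                )
                coupled = 1
            else:
                state = int(np.searchsorted(np.cumsum(probs), rng.random(), "right"))
                state = min(state, 2)
                intensity = float(_draw_intensity(rng, np.asarray([state]))[0])
                coupled = 0
            b_iv = block.b_subinterval(off, run_len)
            runs[b_iv.chrom].append((b_iv.start, b_iv.end, state, intensity, coupled))
            off += run_len

    out: dict[str, _LatentTrack] = {}
    for chrom in sorted(sizes):
        size = sizes[chrom]
        chrom_runs = sorted(runs[chrom])
        pieces: list[tuple[int, int, int, float, int]] = []
        cursor = 0
        for (rs, re, state, v, coupled) in chrom_runs:
            if rs > cursor:
                pieces.extend(_background_pieces(cfg, rng, cursor, rs, probs))
            pieces.append((rs, re, state, v, coupled))
            cursor = re
        if cursor < size:
            pieces.extend(_background_pieces(cfg, rng, cursor, size, probs))
        arr = np.asarray([(p[0], p[1]) for p in pieces], dtype=np.int64)
        out[chrom] = _LatentTrack(
            starts=arr[:, 0],
            ends=arr[:, 1],
            state=np.asarray([p[2] for p in pieces], dtype=int),
            intensity=np.asarray([p[3] for p in pieces]),
            coupled=np.asarray([p[4] for p in pieces], dtype=int),
        )
    return out


def _background_pieces(cfg, rng, start: int, end: int, probs) -> list:
    """Grid-aligned background latent pieces covering [start, end)."""
    pieces = []
    pos = start
    cum = np.cumsum(probs)
    while pos < end:
        nxt = min((pos // cfg.segment + 1) * cfg.segment, end)
        state = min(int(np.searchsorted(cum, rng.random(), "right")), 2)
        v = float(_draw_intensity(rng, np.asarray([state]))[0])
        pieces.append((pos, nxt, state, v, -1))
        pos = nxt
    return pieces


# ---------------------------------------------------------------------------
# emissions


_AFFINITY = {
    # latent state -> (promoter-class affinity, enhancer-class affinity)
    0: (0.05, 0.05),
    1: (0.25, 1.00),
    2: (1.00, 0.25),
}


def _emit_tracks(cfg, rng, root: Path, species: str, tag: str, latent) -> Path:
    rows = []
    track_dir = root / "tracks"

    # peak tracks: class alternates promoter/enhancer; groups round-robin
    for t in range(cfg.n_peak_tracks):
        cls = t % 2  # 0 promoter-class, 1 enhancer-class
        group = cfg.tissue_groups[t % len(cfg.tissue_groups)]
        name = f"{tag}_peak_{group}_{t}"
        path = track_dir / f"{name}.bed"
        with open(path, "w") as fh:
            for chrom in sorted(latent):
                lt = latent[chrom]
                aff = np.asarray([_AFFINITY[s][cls] for s in lt.state])
                # deterministic latent->peak rule plus assay-noise flips, so
                # zero noise means peaks are a pure function of the latent
                active = lt.intensity * aff >= 0.3
                flips = rng.random(len(active)) < cfg.assay_noise
                hits = active ^ flips
                for s, e in zip(lt.starts[hits], lt.ends[hits]):
                    fh.write(f"{chrom}\t{s}\t{e}\n")
        rows.append((name, f"tracks/{name}.bed", species, "peak", "", group))

    # segmentations: one per epigenome, shared 5-state alphabet
    for e in range(cfg.n_epigenomes):
        name = f"{tag}_seg_e{e + 1}"
        path = track_dir / f"{name}.bed"
        with open(path, "w") as fh:
            for chrom in sorted(latent):
                lt = latent[chrom]
                labels = np.asarray([_STATE_LABEL[s] for s in lt.state], dtype=object)
                noisy = rng.random(len(labels)) < cfg.assay_noise
                rand_states = rng.integers(1, _N_SEG_STATES + 1, size=len(labels))
                labels = np.where(noisy, rand_states.astype(str).astype(object), labels)
                for s, e2, lab in zip(lt.starts, lt.ends, labels):
                    fh.write(f"{chrom}\t{s}\t{e2}\t{lab}\n")
        rows.append((name, f"tracks/{name}.bed", species, "segmentation", f"E{e + 1}", ""))

    # signal tracks: intensity plus Gaussian noise
    for t in range(cfg.n_signal_tracks):
        name = f"{tag}_signal_{t + 1}"
        path = track_dir / f"{name}.bedGraph"
        with open(path, "w") as fh:
            for chrom in sorted(latent):
                lt = latent[chrom]
                vals = np.clip(10.0 * lt.intensity + rng.normal(0, 0.3, len(lt.starts)), 0, None)
                for s, e2, v in zip(lt.starts, lt.ends, vals):
                    fh.write(f"{chrom}\t{s}\t{e2}\t{v:.3f}\n")
        rows.append((name, f"tracks/{name}.bedGraph", species, "signal", "", ""))

    manifest = root / f"manifest_{tag}.tsv"
    with open(manifest, "w") as fh:
        fh.write("track_id\tpath\tspecies\tkind\tepigenome\tgroup\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")
    return manifest


def _emit_variants(cfg, rng, path: Path, latent_a) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(latent_a):
            lt = latent_a[chrom]
            lengths = lt.ends - lt.starts
            active_aligned = (lt.state > 0) & (lt.coupled >= 0)
            rate = cfg.variant_rate * np.where(
                active_aligned & cfg.plant_variant_effect, cfg.variant_effect, 1.0
            )
            counts = rng.poisson(rate * lengths)
            for s, e, k in zip(lt.starts, lt.ends, counts):
                if k == 0:
                    continue
                pos = np.sort(rng.integers(s, e, size=k))
                for p in pos:
                    fh.write(f"{chrom}\t{p}\t{p + 1}\n")


# ---------------------------------------------------------------------------
# generator self-validation


def concordance_audit(ds: SyntheticDataset, stride: int = 50) -> dict:
    """Estimate the planted concordance from the latent truth.

    Samples aligned positions every ``stride`` bases within each ungapped
    block, compares latent states across species, and corrects the raw
    agreement for chance using the empirical state marginals:
    ``rho_hat = (agree - chance) / (1 - chance)``.
    """
    agree = 0
    total = 0
    states_a: list[int] = []
    states_b: list[int] = []
    for block in ds.blocks:
        la = ds.latent_a[block.a_interval.chrom]
        lb = ds.latent_b[block.b_interval.chrom]
        offs = np.arange(0, len(block), stride)
        a_pos = block.a_interval.start + offs
        if block.b_interval.strand == "+":
            b_pos = block.b_interval.start + offs
        else:
            b_pos = block.b_interval.end - 1 - offs
        sa = la.state[la.at(a_pos)]
        sb = lb.state[lb.at(b_pos)]
        agree += int((sa == sb).sum())
        total += len(offs)
        states_a.extend(sa.tolist())
        states_b.extend(sb.tolist())
    pa = np.bincount(states_a, minlength=3) / total
    pb = np.bincount(states_b, minlength=3) / total
    chance = float((pa * pb).sum())
    raw = agree / total
    rho_hat = (raw - chance) / (1.0 - chance) if chance < 1.0 else np.nan
    return {
        "raw_agreement": float(raw),
        "chance_agreement": chance,
        "rho_hat": float(rho_hat),
        "n_sampled": int(total),
    }
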