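"""Evaluation statistics against independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from lecif.alignments import GenomicInterval, RegionPair
from lecif.evaluation import (
    ScoreBinning,
    TissueActivityVector,
    UndefinedSimilarityError,
    bin_by_score,
    mean_score_per_state,
    resampled_auc_summary,
    score_agreement,
    score_by_annotation,
    state_frequency_correlation,
    tissue_activity_vectors,
    variant_enrichment,
    weighted_auc,
    weighted_jaccard,
    windowed_mean_score,
    windowed_track_correlation,
)
from lecif.scoring import ScoreTrack


# ---------------------------------------------------------------------------
# oracles


def auroc_oracle(pos, neg):
    """Exhaustive pairwise comparison; ties count one half."""
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def auprc_oracle(pos, neg, w_neg):
    """Weighted average precision from the step curve definition."""
    scores = np.concatenate([pos, neg])
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    w = np.where(y == 1, 1.0, w_neg)
    order = np.argsort(-scores, kind="stable")
    y, w = y[order], w[order]
    # group ties: thresholds between distinct score values
    s_sorted = scores[order]
    tp = fp = 0.0
    total_pos = w[y == 1].sum()
    ap = 0.0
    prev_recall = 0.0
    i = 0
    n = len(y)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += w[i:j][y[i:j] == 1].sum()
        fp += w[i:j][y[i:j] == 0].sum()
        recall = tp / total_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


def mwu_oracle(x, y):
    """U statistic by exhaustive rank comparison (ties one half)."""
    return sum((a > b) + 0.5 * (a == b) for a in x for b in y)


# ---------------------------------------------------------------------------
# weighted AUROC / AUPRC


class TestWeightedAuc:
    def test_perfect_separation(self):
        res = weighted_auc([0.9], [0.1], 50)
        assert res.auroc == 1.0 and res.auprc == 1.0

    def test_small_example_matches_pairwise_oracle(self):
        res = weighted_auc([0.8, 0.4], [0.6, 0.2], w_neg=7)
        assert res.auroc == pytest.approx(0.75)
        assert res.auroc == pytest.approx(auroc_oracle([0.8, 0.4], [0.6, 0.2]))

    def test_matches_oracles_on_random_instances_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n_pos = int(rng.integers(1, 100))
            n_neg = int(rng.integers(1, 100))
            # coarse grid forces plenty of ties
            pos = rng.integers(0, 6, n_pos) / 5
            neg = rng.integers(0, 6, n_neg) / 5
            w = float(rng.choice([1.0, 10.0, 50.0]))
            res = weighted_auc(pos, neg, w)
            assert res.auroc == pytest.approx(auroc_oracle(pos, neg), abs=1e-12)
            assert res.auprc == pytest.approx(auprc_oracle(pos, neg, w), abs=1e-9)

    def test_auroc_invariant_to_uniform_class_weight(self):
        rng = np.random.default_rng(1)
        pos, neg = rng.random(200), rng.random(300)
        assert weighted_auc(pos, neg, 1.0).auroc == pytest.approx(
            weighted_auc(pos, neg, 50.0).auroc
        )

    def test_random_scorer_auprc_is_one_over_one_plus_w(self):
        rng = np.random.default_rng(2)
        n = 20_000
        scores = rng.random(2 * n)
        res = weighted_auc(scores[:n], scores[n:], 50)
        assert res.auprc == pytest.approx(1 / 51, abs=0.005)
        assert res.auroc == pytest.approx(0.5, abs=0.01)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            weighted_auc([], [0.5], 50)


class TestResampledSummary:
    def test_perfect_scores_have_zero_spread(self):
        out = resampled_auc_summary(
            np.full(50, 0.9), np.full(50, 0.1), n_reps=5, n_pos=100, n_neg=100
        )
        assert out["auroc_mean"] == 1.0 and out["auroc_sd"] == 0.0

    def test_same_seed_identical(self):
        rng = np.random.default_rng(3)
        pos, neg = rng.random(500) + 0.2, rng.random(500)
        a = resampled_auc_summary(pos, neg, n_reps=5, n_pos=200, n_neg=200, seed=4)
        b = resampled_auc_summary(pos, neg, n_reps=5, n_pos=200, n_neg=200, seed=4)
        assert a == b

    def test_sd_shrinks_with_resample_size(self):
        rng = np.random.default_rng(5)
        pos, neg = rng.random(2000) + 0.2, rng.random(2000)
        small = resampled_auc_summary(pos, neg, n_reps=30, n_pos=50, n_neg=50, seed=0)
        large = resampled_auc_summary(pos, neg, n_reps=30, n_pos=2000, n_neg=2000, seed=0)
        assert large["auroc_sd"] < small["auroc_sd"]

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            resampled_auc_summary([0.9], [0.1], n_reps=1)


class TestScoreAgreement:
    def test_identity_and_reflection(self):
        x = np.array([0.1, 0.4, 0.2, 0.9, 0.5])
        assert score_agreement(x, x) == pytest.approx((1.0, 1.0))
        assert score_agreement(x, -x) == pytest.approx((-1.0, -1.0))

    def test_five_point_hand_computed_covariance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        pcc, _ = score_agreement(x, y)
        assert pcc == pytest.approx(expected)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            score_agreement(np.ones(5), np.arange(5.0))


# ---------------------------------------------------------------------------
# weighted Jaccard


class TestWeightedJaccard:
    def test_identical_nonzero_vectors_give_one(self):
        v = TissueActivityVector(
            h=np.array([0.2, 0.5]), m=np.array([0.2, 0.5]), groups=("a", "b")
        )
        assert weighted_jaccard(v) == 1.0

    def test_disjoint_support_gives_zero(self):
        v = TissueActivityVector(
            h=np.array([0.4, 0.0]), m=np.array([0.0, 0.7]), groups=("a", "b")
        )
        assert weighted_jaccard(v) == 0.0

    def test_worked_example(self):
        v = TissueActivityVector(
            h=np.array([0.5, 0.2, 0.0]),
            m=np.array([0.25, 0.4, 0.1]),
            groups=("a", "b", "c"),
        )
        assert weighted_jaccard(v) == pytest.approx(0.45)

    def test_zero_denominator_flags_exclusion(self):
        v = TissueActivityVector(
            h=np.zeros(3), m=np.zeros(3), groups=("a", "b", "c")
        )
        with pytest.raises(UndefinedSimilarityError):
            weighted_jaccard(v)

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1, allow_nan=False),
                st.floats(0, 1, allow_nan=False),
            ),
            min_size=1,
            max_size=10,
        )
    )
    def test_symmetric_and_bounded(self, hm):
        h = np.array([t[0] for t in hm])
        m = np.array([t[1] for t in hm])
        groups = tuple(str(i) for i in range(len(hm)))
        if np.maximum(h, m).sum() == 0:
            return
        j1 = weighted_jaccard(TissueActivityVector(h=h, m=m, groups=groups))
        j2 = weighted_jaccard(TissueActivityVector(h=m, m=h, groups=groups))
        assert j1 == j2
        assert 0.0 <= j1 <= 1.0
        if np.array_equal(h, m):
            assert j1 == 1.0


# ---------------------------------------------------------------------------
# tissue activity vectors


def _region_pair(a=(100, 150), b=(100, 150)):
    return RegionPair(
        a_region=GenomicInterval("chr1", *a),
        b_region=GenomicInterval("chr1", *b),
        block_id="t",
        label="positive",
        pair_id="p",
    )


def _peak_track(tmp_path, name, intervals, species, group):
    import pandas as pd

    from lecif.features import load_annotations

    path = tmp_path / f"{name}.bed"
    path.write_text("".join(f"chr1\t{s}\t{e}\n" for s, e in intervals))
    manifest = pd.DataFrame(
        {
            "track_id": [name],
            "path": [f"{name}.bed"],
            "species": [species],
            "kind": ["peak"],
            "epigenome": [None],
            "group": [group],
        }
    )
    return load_annotations(manifest, base_dir=tmp_path)[0]


class TestTissueActivity:
    def test_fraction_of_group_experiments(self, tmp_path):
        a_tracks = [
            _peak_track(tmp_path, f"a{i}", [(100, 200)] if i < 2 else [(900, 950)], "A", "liver")
            for i in range(4)
        ]
        b_tracks = [_peak_track(tmp_path, "b0", [(100, 200)], "B", "liver")]
        vec = tissue_activity_vectors([_region_pair()], a_tracks, b_tracks)[0]
        assert vec.h.tolist() == [0.5]  # 2 of 4 liver experiments overlap
        assert vec.m.tolist() == [1.0]

    def test_region_overlapping_nothing_is_zero_vector(self, tmp_path):
        a_tracks = [_peak_track(tmp_path, "a0", [(900, 950)], "A", "liver")]
        b_tracks = [_peak_track(tmp_path, "b0", [(900, 950)], "B", "liver")]
        vec = tissue_activity_vectors([_region_pair()], a_tracks, b_tracks)[0]
        assert vec.h.tolist() == [0.0] and vec.m.tolist() == [0.0]

    def test_one_sided_group_rejected(self, tmp_path):
        a_tracks = [_peak_track(tmp_path, "a0", [(0, 10)], "A", "liver")]
        b_tracks = [_peak_track(tmp_path, "b0", [(0, 10)], "B", "brain")]
        with pytest.raises(ValueError, match="only one species"):
            tissue_activity_vectors([_region_pair()], a_tracks, b_tracks)

    def test_fractions_invariant_to_track_order(self, tmp_path):
        tracks = [
            _peak_track(tmp_path, f"t{i}", [(100, 120)] if i % 2 else [(500, 520)], "A", "liver")
            for i in range(4)
        ]
        v1 = tissue_activity_vectors([_region_pair()], tracks, tracks)[0]
        v2 = tissue_activity_vectors([_region_pair()], tracks[::-1], tracks[::-1])[0]
        assert np.array_equal(v1.h, v2.h)


# ---------------------------------------------------------------------------
# state-frequency correlation


def _seg_track(tmp_path, name, rows, species="A"):
    import pandas as pd

    from lecif.features import load_annotations

    path = tmp_path / f"{name}.bed"
    path.write_text("".join(f"{c}\t{s}\t{e}\t{st_}\n" for c, s, e, st_ in rows))
    manifest = pd.DataFrame(
        {
            "track_id": [name],
            "path": [f"{name}.bed"],
            "species": [species],
            "kind": ["segmentation"],
            "epigenome": [name],
            "group": [None],
        }
    )
    return load_annotations(manifest, base_dir=tmp_path)[0]


class TestStateFrequencyCorrelation:
    def _pairs(self, n):
        return [
            RegionPair(
                a_region=GenomicInterval("chr1", 100 * i, 100 * i + 50),
                b_region=GenomicInterval("chr1", 100 * i, 100 * i + 50),
                block_id="t",
                label="positive",
                pair_id=str(i),
            )
            for i in range(n)
        ]

    def test_identical_annotations_give_unit_correlation(self, tmp_path):
        rows = [("chr1", 100 * i, 100 * i + 50, str(1 + i % 2)) for i in range(6)]
        seg_a = _seg_track(tmp_path, "ea", rows)
        seg_b = _seg_track(tmp_path, "eb", rows)
        result = state_frequency_correlation(self._pairs(6), [seg_a], [seg_b])
        for s, pcc in result.items():
            assert pcc == pytest.approx(1.0)

    def test_shuffled_annotations_are_uncorrelated(self, tmp_path):
        rng = np.random.default_rng(0)
        n = 200
        sa = rng.integers(1, 3, n)
        sb = rng.integers(1, 3, n)
        seg_a = _seg_track(
            tmp_path, "ea", [("chr1", 100 * i, 100 * i + 50, str(sa[i])) for i in range(n)]
        )
        seg_b = _seg_track(
            tmp_path, "eb", [("chr1", 100 * i, 100 * i + 50, str(sb[i])) for i in range(n)]
        )
        result = state_frequency_correlation(self._pairs(n), [seg_a], [seg_b])
        for pcc in result.values():
            assert abs(pcc) < 0.2

    def test_three_pair_hand_example(self, tmp_path):
        # state "1" fractions: A = (1, 0, 1), B = (1, 1, 0) over 3 pairs
        seg_a = _seg_track(
            tmp_path, "ea",
            [("chr1", 0, 50, "1"), ("chr1", 100, 150, "2"), ("chr1", 200, 250, "1")],
        )
        seg_b = _seg_track(
            tmp_path, "eb",
            [("chr1", 0, 50, "1"), ("chr1", 100, 150, "1"), ("chr1", 200, 250, "2")],
        )
        result = state_frequency_correlation(self._pairs(3), [seg_a], [seg_b])
        expected = float(stats.pearsonr([1, 0, 1], [1, 1, 0]).statistic)
        assert result["1"] == pytest.approx(expected)

    def test_constant_state_reported_missing(self, tmp_path):
        rows = [("chr1", 100 * i, 100 * i + 50, "1") for i in range(4)]
        seg_a = _seg_track(tmp_path, "ea", rows)
        seg_b = _seg_track(tmp_path, "eb", rows)
        result = state_frequency_correlation(self._pairs(4), [seg_a], [seg_b])
        assert result["1"] is None


# ---------------------------------------------------------------------------
# binning


class TestBinning:
    def test_equal_width_edges_uniform(self):
        scores = np.linspace(0, 1, 101)
        b = bin_by_score(scores, "equal_width", 10)
        assert np.allclose(b.edges, np.arange(11) / 10)
        assert b.bin_index[-1] == 9  # max score in top bin

    def test_percentile_bins_near_equal_counts(self):
        rng = np.random.default_rng(0)
        b = bin_by_score(rng.random(1000), "percentile_rank", 10)
        assert set(b.counts()) == {100}

    def test_every_score_in_exactly_one_bin(self):
        rng = np.random.default_rng(1)
        scores = rng.random(500)
        for mode in ("equal_width", "percentile_rank"):
            b = bin_by_score(scores, mode, 7)
            assert len(b.bin_index) == 500
            assert b.counts().sum() == 500

    def test_too_few_distinct_scores_for_percentile(self):
        with pytest.raises(ValueError, match="distinct"):
            bin_by_score(np.array([0.1, 0.1, 0.9]), "percentile_rank", 3)


# ---------------------------------------------------------------------------
# variant enrichment


class TestVariantEnrichment:
    def _regions(self, n):
        return [GenomicInterval("chr1", 100 * i, 100 * i + 50) for i in range(n)]

    def test_all_regions_overlap_gives_flat_unit_fold(self):
        n = 100
        regions = self._regions(n)
        variants = pd.DataFrame(
            {"chrom": ["chr1"] * n, "start": [100 * i + 10 for i in range(n)],
             "end": [100 * i + 11 for i in range(n)]}
        )
        scores = np.linspace(0, 1, n)
        out = variant_enrichment(regions, scores, variants, k=10)
        assert np.allclose(out["fold"], 1.0)
        assert np.allclose(out["log2_fold"], 0.0)

    def test_fold_ratio_formula(self):
        # 200 regions; variants only in the top-score half -> fold 2 there
        n = 200
        regions = self._regions(n)
        scores = np.concatenate([np.zeros(100), np.ones(100)])
        variants = pd.DataFrame(
            {"chrom": ["chr1"] * 100,
             "start": [100 * i + 10 for i in range(100, 200)],
             "end": [100 * i + 11 for i in range(100, 200)]}
        )
        out = variant_enrichment(regions, scores, variants, k=2)
        assert out.loc[1, "fold"] == pytest.approx(2.0)
        assert out.loc[1, "log2_fold"] == pytest.approx(1.0)
        assert out.loc[0, "fold"] == pytest.approx(0.0)

    def test_binomial_p_matches_exact_tail_sum(self):
        n = 200
        regions = self._regions(n)
        rng = np.random.default_rng(0)
        scores = rng.random(n)
        hit_idx = rng.choice(n, 30, replace=False)
        variants = pd.DataFrame(
            {"chrom": ["chr1"] * 30,
             "start": [100 * i + 5 for i in hit_idx],
             "end": [100 * i + 6 for i in hit_idx]}
        )
        out = variant_enrichment(regions, scores, variants, k=5)
        p0 = 30 / n
        for row in out.itertuples():
            tail = sum(
                stats.binom.pmf(x, row.n_regions, p0)
                for x in range(int(row.n_overlap), row.n_regions + 1)
            )
            assert row.p_value == pytest.approx(tail, rel=1e-8)

    def test_count_weighted_folds_average_to_one(self):
        n = 500
        regions = self._regions(n)
        rng = np.random.default_rng(1)
        scores = rng.random(n)
        hit_idx = rng.choice(n, 80, replace=False)
        variants = pd.DataFrame(
            {"chrom": ["chr1"] * 80,
             "start": [100 * i + 5 for i in hit_idx],
             "end": [100 * i + 6 for i in hit_idx]}
        )
        out = variant_enrichment(regions, scores, variants, k=10)
        weighted = np.nansum(out["fold"] * out["n_regions"]) / out["n_regions"].sum()
        assert weighted == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# score-by-annotation and windowed statistics


def _track_df(scores, start=0, width=50, chrom="chr1"):
    n = len(scores)
    return ScoreTrack(
        records=pd.DataFrame(
            {
                "a_chrom": [chrom] * n,
                "a_start": [start + width * 2 * i for i in range(n)],
                "a_end": [start + width * 2 * i + width for i in range(n)],
                "b_chrom": [chrom] * n,
                "b_start": [start + width * 2 * i for i in range(n)],
                "b_end": [start + width * 2 * i + width for i in range(n)],
                "score": scores,
                "block_id": ["b"] * n,
            }
        )
    )


class TestScoreByAnnotation:
    def test_u_statistic_matches_exhaustive_rank_oracle(self):
        scores = [0.9, 0.7, 0.5, 0.3, 0.2, 0.15, 0.1]
        track = _track_df(scores)
        # annotation covers the first 4 windows
        ann = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [350]})
        out = score_by_annotation(track, ann, side="A")
        inside = scores[:4]
        outside = scores[4:]
        assert out["u_statistic"] == pytest.approx(mwu_oracle(inside, outside))

    def test_planted_high_score_annotation_is_significant(self):
        rng = np.random.default_rng(0)
        scores = rng.random(200) * 0.3
        scores[:60] += 0.6  # planted effect in annotated windows
        track = _track_df(list(scores))
        ann = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [60 * 100]})
        out = score_by_annotation(track, ann, side="A")
        assert out["p_value"] < 0.05
        assert out["overlap"]["mean"] > out["background"]["mean"]

    def test_annotation_covering_everything_errors(self):
        track = _track_df([0.1, 0.2, 0.3])
        ann = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000]})
        with pytest.raises(ValueError, match="empty"):
            score_by_annotation(track, ann, side="A")


class TestMeanScorePerState:
    def test_single_epigenome_mean(self, tmp_path):
        track = _track_df([0.2, 0.4])
        seg = _seg_track(tmp_path, "e1", [("chr1", 0, 200, "5")])
        out = mean_score_per_state(track, [seg])
        assert out["5"] == pytest.approx(0.3)

    def test_epigenomes_averaged_unweighted(self, tmp_path):
        track = _track_df([0.2, 0.2, 0.6, 0.6, 0.6])
        # epigenome 1 annotates the first two windows, epigenome 2 the rest
        seg1 = _seg_track(tmp_path, "e1", [("chr1", 0, 200, "7")])
        seg2 = _seg_track(tmp_path, "e2", [("chr1", 200, 500, "7")])
        out = mean_score_per_state(track, [seg1, seg2])
        assert out["7"] == pytest.approx(0.4)

    def test_invariant_to_region_order(self, tmp_path):
        seg = _seg_track(tmp_path, "e1", [("chr1", 0, 1000, "2")])
        t1 = _track_df([0.1, 0.5, 0.9])
        rec = t1.records.iloc[::-1].reset_index(drop=True)
        t2 = ScoreTrack(records=rec)
        assert mean_score_per_state(t1, [seg]) == mean_score_per_state(t2, [seg])


class TestWindowedMeanScore:
    def test_under_half_coverage_excluded(self):
        # one 1000-base window, 400 annotated bases -> excluded
        track = ScoreTrack(
            records=pd.DataFrame(
                {
                    "a_chrom": ["chr1"], "a_start": [0], "a_end": [400],
                    "b_chrom": ["chr1"], "b_start": [0], "b_end": [400],
                    "score": [0.5], "block_id": ["b"],
                }
            )
        )
        windows = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        assert len(windowed_mean_score(track, windows)) == 0

    def test_exactly_half_coverage_retained(self):
        track = ScoreTrack(
            records=pd.DataFrame(
                {
                    "a_chrom": ["chr1"], "a_start": [0], "a_end": [500],
                    "b_chrom": ["chr1"], "b_start": [0], "b_end": [500],
                    "score": [0.2], "block_id": ["b"],
                }
            )
        )
        windows = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        out = windowed_mean_score(track, windows)
        assert len(out) == 1
        assert out.iloc[0]["mean_score"] == pytest.approx(0.2)
        assert out.iloc[0]["n_annotated"] == 500

    def test_full_coverage_constant_score(self):
        scores = [0.7, 0.7]
        track = ScoreTrack(
            records=pd.DataFrame(
                {
                    "a_chrom": ["chr1"] * 2, "a_start": [0, 500], "a_end": [500, 1000],
                    "b_chrom": ["chr1"] * 2, "b_start": [0, 500], "b_end": [500, 1000],
                    "score": scores, "block_id": ["b", "b"],
                }
            )
        )
        windows = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        out = windowed_mean_score(track, windows)
        assert out.iloc[0]["mean_score"] == pytest.approx(0.7)


class TestWindowedTrackCorrelation:
    def _bedgraph(self, values, width=10, chrom="chr1"):
        n = len(values)
        return pd.DataFrame(
            {
                "chrom": [chrom] * n,
                "start": [width * i for i in range(n)],
                "end": [width * (i + 1) for i in range(n)],
                "value": values,
            }
        )

    def test_identical_tracks_fully_correlated(self):
        rng = np.random.default_rng(0)
        t = self._bedgraph(rng.random(100))
        out = windowed_track_correlation(t, t, {"chr1": 1000}, min_annotated=[1, 50])
        for pcc, scc in out.values():
            assert pcc == pytest.approx(1.0)
            assert scc == pytest.approx(1.0)

    def test_independent_tracks_uncorrelated(self):
        rng = np.random.default_rng(1)
        tx = self._bedgraph(rng.random(500))
        ty = self._bedgraph(rng.random(500))
        out = windowed_track_correlation(tx, ty, {"chr1": 5000})
        pcc, _ = out[1]
        assert abs(pcc) < 0.1

    def test_min_annotated_50_keeps_fully_covered_windows_only(self):
        rng = np.random.default_rng(2)
        # track y annotates only the first 300 bases
        tx = self._bedgraph(rng.random(100))
        ty = self._bedgraph(rng.random(30))
        out = windowed_track_correlation(tx, ty, {"chr1": 1000}, min_annotated=[50])
        assert 50 in out  # computed from the co-annotated prefix only

    def test_too_few_windows_rejected(self):
        t = self._bedgraph([1.0, 2.0])
        with pytest.raises(ValueError, match="qualifying"):
            windowed_track_correlation(t, t, {"chr1": 60}, min_annotated=[50])
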