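"""Genomics-aware folds: band atomicity, window/TAD matching, CV provenance."""

import numpy as np
import pandas as pd
import pytest

from hypersmurf.crossval import (
    LeakageError,
    assign_cytoband_folds,
    audit_no_leakage,
    build_matched_negative_folds,
    genomic_sort_order,
    progressive_negative_subsample,
    run_cv,
)
from hypersmurf.ensemble import HyperSmurfConfig
from hypersmurf.simdata import SimConfig, simulate


def bands_with_positive_counts(counts):
    """One band per entry, holding that many positives (plus 2 negatives each)."""
    bands, labels = [], []
    for i, c in enumerate(counts):
        name = f"band{i}"
        bands += [name] * (c + 2)
        labels += [1] * c + [0] * 2
    return np.array(bands), np.array(labels)


class TestCytobandFolds:
    def test_greedy_balance_two_folds(self):
        bands, labels = bands_with_positive_counts([3, 2, 2, 1, 1])
        fa = assign_cytoband_folds(bands, labels, 2, seed=0)
        totals = sorted(
            int(labels[(fa.fold == j) & (labels == 1)].sum()) for j in range(2)
        )
        assert totals == [4, 5]

    def test_band_atomicity(self):
        bands, labels = bands_with_positive_counts([5, 0, 0])
        fa = assign_cytoband_folds(bands, labels, 2, seed=1)
        for b in np.unique(bands):
            assert len(np.unique(fa.fold[bands == b])) == 1

    def test_negatives_inherit_band_fold(self):
        bands, labels = bands_with_positive_counts([2, 1])
        fa = assign_cytoband_folds(bands, labels, 2, seed=2)
        for b in np.unique(bands):
            mask = bands == b
            assert len(set(fa.fold[mask])) == 1

    def test_singleton_bands_spread_evenly(self):
        # 20 bands of one positive each over 10 folds -> 2 positives per fold
        bands, labels = bands_with_positive_counts([1] * 20)
        fa = assign_cytoband_folds(bands, labels, 10, seed=3)
        per_fold = [int(labels[fa.fold == j].sum()) for j in range(10)]
        assert per_fold == [2] * 10

    def test_simulated_scaffold_folds_are_band_atomic(self, small_dataset):
        bands = small_dataset.loci["band"].to_numpy()
        fa = assign_cytoband_folds(bands, small_dataset.labels, 10, seed=4)
        for b in np.unique(bands):
            assert len(np.unique(fa.fold[bands == b])) == 1

    def test_missing_band_rejected(self):
        with pytest.raises(ValueError):
            assign_cytoband_folds(np.array(["a", ""]), np.array([1, 0]), 2, seed=0)

    def test_fewer_positive_bands_than_folds_warns(self):
        bands, labels = bands_with_positive_counts([2])
        with pytest.warns(UserWarning, match="positive-bearing"):
            assign_cytoband_folds(bands, labels, 3, seed=0)


class TestMatchedNegatives:
    def test_overlapping_windows_merge_into_one_fold(self):
        pos = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [100_000, 150_000]})
        neg = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [10_000, 200_000, 260_000]})
        kept, fa = build_matched_negative_folds(pos, neg, window_size=100_000)
        assert fa.n_folds == 1
        # windows [1, 200000] and [50000, 250000] merge; 260000 falls outside
        assert kept.tolist() == [0, 1]
        assert set(fa.fold) == {0}

    def test_window_distance_arithmetic(self):
        pos = pd.DataFrame({"chrom": ["chr2"], "pos": [500_000]})
        neg = pd.DataFrame(
            {"chrom": ["chr2"] * 4, "pos": [401_000, 599_999, 601_000, 700_000]}
        )
        kept, _ = build_matched_negative_folds(pos, neg, window_size=100_000)
        # closed window [400000, 600000]: farther-than-100kb negatives excluded
        assert kept.tolist() == [0, 1]

    def test_never_selects_negative_outside_window(self, rng):
        pos = pd.DataFrame({"chrom": ["chr1"] * 5, "pos": rng.integers(1, 10**7, 5)})
        neg = pd.DataFrame({"chrom": ["chr1"] * 200, "pos": rng.integers(1, 10**7, 200)})
        size = 50_000
        kept, _ = build_matched_negative_folds(pos, neg, window_size=size)
        for i in kept:
            assert np.min(np.abs(pos["pos"].to_numpy() - neg["pos"].iloc[i])) <= size

    def test_tad_mode_drops_positive_free_domains(self):
        tads = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [1, 1_000_001, 1],
                "end": [1_000_001, 2_000_001, 1_000_001],
                "name": ["tad1", "tad2", "tad3"],
            }
        )
        pos = pd.DataFrame({"chrom": ["chr1", "chr2"], "pos": [500_000, 500_000]})
        neg = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr2"], "pos": [400_000, 1_500_000, 600_000]}
        )
        kept, fa = build_matched_negative_folds(pos, neg, tad_table=tads)
        assert fa.n_folds == 2  # only positive-bearing TADs become folds
        assert kept.tolist() == [0, 2]  # negative in tad2 dropped
        # each positive shares its fold with its in-TAD negative
        assert fa.fold[0] == fa.fold[2] and fa.fold[1] == fa.fold[3]

    def test_positive_without_negatives_retained_with_warning(self):
        pos = pd.DataFrame({"chrom": ["chr1", "chr3"], "pos": [100_000, 100_000]})
        neg = pd.DataFrame({"chrom": ["chr1"], "pos": [120_000]})
        with pytest.warns(UserWarning, match="no matched negatives"):
            kept, fa = build_matched_negative_folds(pos, neg, window_size=100_000)
        assert len(fa.fold) == 2 + len(kept)


class TestProgressiveSubsample:
    def test_fixed_step_selection(self):
        loci = pd.DataFrame({"chrom": ["chr1"] * 100, "pos": np.arange(1, 101)})
        picked = progressive_negative_subsample(loci, 10)
        assert picked.tolist() == list(range(0, 100, 10))

    def test_full_target_is_identity(self):
        loci = pd.DataFrame({"chrom": ["chr1"] * 25, "pos": np.arange(1, 26)})
        assert progressive_negative_subsample(loci, 25).tolist() == list(range(25))

    def test_coverage_preserved(self, rng):
        n = 500
        loci = pd.DataFrame(
            {"chrom": rng.choice(["chr1", "chr2"], n), "pos": rng.integers(1, 10**6, n)}
        )
        order = genomic_sort_order(loci["chrom"].to_numpy(), loci["pos"].to_numpy())
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        for target in (10, 50, 250):
            picked = progressive_negative_subsample(loci, target)
            assert len(picked) == target
            picked_ranks = ranks[picked]
            assert picked_ranks.min() < n // 10  # first decile reached
            assert picked_ranks.max() >= n - n // 10 - n // target  # last decile reached

    def test_canonical_targets_scale_ratio(self):
        """Targets |P| * {1, 10, 100, 1000} produce 1:1 ... 1:1000 ratios."""
        n_pos = 40
        loci = pd.DataFrame({"chrom": ["chr1"] * 40_000, "pos": np.arange(1, 40_001)})
        for ratio in (1, 10, 100, 1000):
            picked = progressive_negative_subsample(loci, n_pos * ratio)
            assert len(picked) == n_pos * ratio

    def test_target_out_of_range(self):
        loci = pd.DataFrame({"chrom": ["chr1"] * 5, "pos": np.arange(1, 6)})
        with pytest.raises(ValueError):
            progressive_negative_subsample(loci, 6)


def test_genomic_sort_order_natural_chromosomes():
    chrom = ["chr10", "chr2", "chrX", "chr2", "chrMT", "chrY", "chr1"]
    pos = [5, 9, 1, 3, 1, 1, 7]
    order = genomic_sort_order(chrom, pos)
    assert [chrom[i] for i in order] == ["chr1", "chr2", "chr2", "chr10", "chrX", "chrY", "chrMT"]
    assert [pos[i] for i in order] == [7, 3, 9, 5, 1, 1, 1]


class TestRunCV:
    @pytest.fixture(scope="class")
    def tiny(self):
        return simulate(SimConfig(n_pos=16, n_neg=120, d=4, separation=3.0, seed=21))

    def test_out_of_fold_provenance(self, tiny):
        fa = assign_cytoband_folds(tiny.loci["band"].to_numpy(), tiny.labels, 2, seed=0)
        result = run_cv(tiny, fa, HyperSmurfConfig(n=2, f=1, m=1, k=3, seed=0))
        assert not np.isnan(result.scores).any()
        for rec in result.records:
            assert not set(rec.train_indices) & set(rec.test_indices)
            assert np.array_equal(np.sort(rec.test_indices), np.flatnonzero(fa.fold == rec.fold_id))

    def test_rerun_is_identical(self, tiny):
        fa = assign_cytoband_folds(tiny.loci["band"].to_numpy(), tiny.labels, 2, seed=0)
        cfg = HyperSmurfConfig(n=2, f=1, m=1, k=3, seed=7)
        np.testing.assert_array_equal(run_cv(tiny, fa, cfg).scores, run_cv(tiny, fa, cfg).scores)

    def test_planted_leak_is_caught(self, tiny):
        fa = assign_cytoband_folds(tiny.loci["band"].to_numpy(), tiny.labels, 2, seed=0)
        result = run_cv(tiny, fa, HyperSmurfConfig(n=2, f=1, m=1, k=3, seed=0))
        rec = result.records[0]
        leaked_positive = rec.test_indices[tiny.labels[rec.test_indices] == 1][0]
        rec.train_indices = np.append(rec.train_indices, leaked_positive)
        with pytest.raises(LeakageError):
            audit_no_leakage(result, tiny.n_variants)

    def test_fold_without_training_positives_rejected(self):
        data = simulate(SimConfig(n_pos=5, n_neg=40, d=3, seed=5))
        from hypersmurf.crossval import FoldAssignment

        fold = np.zeros(data.n_variants, dtype=int)
        fold[data.positives] = 0  # every positive held out together
        fold[data.negatives[:20]] = 1
        fa = FoldAssignment(fold=fold, n_folds=2)
        with pytest.raises(ValueError, match="no positives"):
            run_cv(data, fa, HyperSmurfConfig(n=1, seed=0))
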