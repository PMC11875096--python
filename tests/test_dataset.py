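"""Outlier filtering and binned splitting / stratified folds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_2samp

from chargeshell.dataset import (
    binned_split,
    chauvenet_filter,
    drop_connectivity_changes,
    stratified_folds,
)


class TestChauvenet:
    def test_planted_ten_sigma_outlier_removed(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 1000)
        x[137] = 10.0
        kept, removed = chauvenet_filter(x)
        assert 137 in removed
        assert len(kept) + len(removed) == 1000

    def test_idempotent_on_kept_values(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 500), [8.0, -9.0]])
        kept, _ = chauvenet_filter(x)
        _, removed_again = chauvenet_filter(x[kept])
        assert removed_again == []

    def test_all_equal_removes_nothing(self):
        kept, removed = chauvenet_filter([5.0] * 10)
        assert removed == [] and len(kept) == 10

    def test_symmetric_mild_extremes_survive(self):
        x = np.array([-1.5, 1.5, 0.0, 0.5, -0.5, 0.2, -0.2])
        _, removed = chauvenet_filter(x)
        assert removed == []

    def test_classical_variant_scales_with_sample_size(self):
        # a 3-sigma point survives the plain 1% rule but fails the
        # classical n*p < 0.5 rule in a small sample
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 30), [4.5]])
        _, removed_plain = chauvenet_filter(x, threshold=1e-6)
        _, removed_classical = chauvenet_filter(x, classical=True)
        assert removed_plain == []
        assert len(removed_classical) >= 1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=50))
    def test_filter_partitions_indices(self, values):
        kept, removed = chauvenet_filter(values)
        assert sorted(kept + removed) == list(range(len(values)))


class TestBinnedSplit:
    def test_global_train_fraction(self):
        rng = np.random.default_rng(4)
        y = rng.normal(250, 60, 10_000)
        a = binned_split(y, n_bins=10, seed=4)
        n_train = int(a.train_mask.sum())
        # within 1 record per bin of 85%
        assert abs(n_train - 8500) <= 10

    def test_per_bin_fraction_on_bimodal_targets(self):
        rng = np.random.default_rng(5)
        y = np.concatenate([rng.normal(0, 1, 5000), rng.normal(10, 1, 5000)])
        a = binned_split(y, n_bins=10, seed=5)
        for b in np.unique(a.bin_id):
            mask = a.bin_id == b
            if mask.sum() >= 100:
                frac = (a.train_mask & mask).sum() / mask.sum()
                assert 0.84 <= frac <= 0.86

    def test_single_bin_reduces_to_plain_split(self):
        y = np.arange(1000.0)
        a = binned_split(y, n_bins=1, seed=6)
        assert len(np.unique(a.bin_id)) == 1
        assert int(a.train_mask.sum()) == 850

    def test_split_conserves_records(self):
        y = np.random.default_rng(7).normal(size=2000)
        a = binned_split(y, seed=7)
        assert int(a.train_mask.sum()) + int(a.test_mask.sum()) == 2000

    def test_train_test_distributions_match(self):
        rng = np.random.default_rng(8)
        y = rng.gamma(4, 30, 10_000)
        a = binned_split(y, n_bins=10, seed=8)
        d = ks_2samp(y[a.train_mask], y[a.test_mask]).statistic
        assert d < 0.03

    def test_reproducible_from_seed(self):
        y = np.random.default_rng(9).normal(size=3000)
        a = binned_split(y, seed=123)
        b = binned_split(y, seed=123)
        assert np.array_equal(a.partition, b.partition)


class TestStratifiedFolds:
    def _assignment(self, n=8500, seed=10):
        y = np.random.default_rng(seed).normal(250, 60, n)
        a = binned_split(y, n_bins=10, seed=seed)
        return a

    def test_folds_partition_training_set(self):
        a = self._assignment()
        folds = stratified_folds(a, k=5, seed=10)
        assert np.all(folds[a.test_mask] == -1)
        assert set(folds[a.train_mask]) == {0, 1, 2, 3, 4}
        sizes = [int((folds == f).sum()) for f in range(5)]
        assert max(sizes) - min(sizes) <= a.n_bins

    def test_per_bin_fold_balance(self):
        a = self._assignment()
        folds = stratified_folds(a, k=5, seed=10)
        for b in np.unique(a.bin_id):
            counts = [
                int(((a.bin_id == b) & (folds == f)).sum()) for f in range(5)
            ]
            assert max(counts) - min(counts) <= 1

    def test_deterministic(self):
        a = self._assignment(n=1000, seed=11)
        f1 = stratified_folds(a, k=5, seed=99)
        a2 = self._assignment(n=1000, seed=11)
        f2 = stratified_folds(a2, k=5, seed=99)
        assert np.array_equal(f1, f2)

    def test_k_exceeding_training_size_rejected(self):
        y = np.arange(6.0)
        a = binned_split(y, n_bins=1, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            stratified_folds(a, k=50, seed=0)


@pytest.mark.parametrize(
    "n, n_flagged",
    [(20, 0), (20, 3), (20, 20)],
)
def test_drop_connectivity_changes(n, n_flagged):
    records = list(range(n))
    flags = [i < n_flagged for i in range(n)]
    kept, removed = drop_connectivity_changes(records, flags)
    assert removed == n_flagged
    assert len(kept) == n - n_flagged
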