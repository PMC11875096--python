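"""Regressor training, hyperparameter search and uncertainty estimators."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from chargeshell.dataset import binned_split, stratified_folds
from chargeshell.fixtures import make_labeled_table
from chargeshell.models import (
    DEFAULT_HYPERPARAMETERS,
    AffinityRegressor,
    EnsembleUncertainty,
    ForestUncertainty,
    KNNUncertainty,
    predict,
    train_regressor,
    train_uncertainty,
    tune_hyperparameters,
)


@pytest.fixture(scope="module")
def small_split():
    tab = make_labeled_table(1500, seed=21, noise_std=5.0)
    a = binned_split(tab.y, n_bins=10, seed=21)
    folds = stratified_folds(a, k=5, seed=21)
    return tab, a, folds


class TestRegressor:
    def test_noiseless_recovery(self, noiseless_fit):
        tab, assignment, reg = noiseless_fit
        te = assignment.test_mask
        pred = reg.predict(tab.X[te])
        r = pearsonr(pred, tab.y[te])[0]
        rmse = float(np.sqrt(np.mean((pred - tab.y[te]) ** 2)))
        target_range = tab.y.max() - tab.y.min()
        assert r >= 0.99
        assert rmse <= 0.02 * target_range

    def test_five_fold_cv_recorded_and_best_retained(self, noiseless_fit):
        _, _, reg = noiseless_fit
        assert len(reg.cv_rmse_) == 5
        assert reg.best_fold_ == int(np.argmin(reg.cv_rmse_))

    def test_constant_target_zero_cv_rmse(self):
        X = make_labeled_table(300, seed=22).X
        y = np.full(300, 42.0)
        reg = AffinityRegressor(n_estimators=20, random_state=0).fit(X, y)
        assert np.allclose(reg.cv_rmse_, 0.0)

    def test_wrong_feature_width_rejected(self, noiseless_fit):
        _, _, reg = noiseless_fit
        with pytest.raises(ValueError, match="width 53"):
            reg.predict(np.zeros((3, 10)))

    def test_empty_input_empty_output(self, noiseless_fit):
        _, _, reg = noiseless_fit
        assert reg.predict(np.empty((0, 53))).size == 0

    def test_sklearn_param_round_trip(self):
        reg = AffinityRegressor(n_estimators=17, random_state=5)
        params = reg.get_params()
        assert params["n_estimators"] == 17
        clone = AffinityRegressor(**params)
        assert clone.get_params() == params


class TestTuning:
    def test_budget_one_returns_single_sample(self, small_split):
        tab, _, folds = small_split
        params, value, trace = tune_hyperparameters(
            tab.X, tab.y, folds, budget=1, seed=3, n_estimators=30
        )
        assert len(trace) == 1
        assert np.isfinite(value)
        assert set(params) == set(DEFAULT_HYPERPARAMETERS)

    def test_best_so_far_trace_non_increasing(self, small_split):
        tab, _, folds = small_split
        _, _, trace = tune_hyperparameters(
            tab.X, tab.y, folds, budget=8, seed=3, n_estimators=30
        )
        assert all(b <= a for a, b in zip(trace, trace[1:]))

    def test_deterministic_for_fixed_seed(self, small_split):
        tab, _, folds = small_split
        p1, v1, _ = tune_hyperparameters(
            tab.X, tab.y, folds, budget=5, seed=17, n_estimators=30
        )
        p2, v2, _ = tune_hyperparameters(
            tab.X, tab.y, folds, budget=5, seed=17, n_estimators=30
        )
        assert p1 == p2 and v1 == v2

    def test_zero_budget_returns_defaults(self, small_split):
        tab, _, folds = small_split
        params, value, trace = tune_hyperparameters(
            tab.X, tab.y, folds, budget=0, seed=1
        )
        assert params == DEFAULT_HYPERPARAMETERS
        assert trace == [] and np.isnan(value)


class TestUncertainty:
    def test_forest_sigma_is_std_over_200_trees(self, small_split):
        tab, _, _ = small_split
        unc = train_uncertainty(tab.X[:500], tab.y[:500], method="forest_std", seed=1)
        tp = unc.tree_predictions(tab.X[:20])
        assert tp.shape[0] == 200
        assert np.allclose(unc.predict_std(tab.X[:20]), tp.std(axis=0, ddof=0))

    def test_sigma_zero_at_duplicated_training_point(self):
        row = make_labeled_table(1, seed=30).X
        X = np.repeat(row, 50, axis=0)
        y = np.full(50, 100.0)
        unc = ForestUncertainty(random_state=0).fit(X, y)
        assert unc.predict_std(row)[0] == 0.0

    def test_knn_distance_zero_at_training_point(self, small_split):
        tab, _, _ = small_split
        unc = KNNUncertainty(k=1, metric="manhattan").fit(tab.X[:200])
        assert unc.predict_std(tab.X[:1])[0] == 0.0

    @pytest.mark.parametrize("k", [1, 10])
    def test_manhattan_dominates_euclidean(self, small_split, k):
        tab, _, _ = small_split
        q = tab.X[500:520]
        man = KNNUncertainty(k=k, metric="manhattan").fit(tab.X[:400])
        euc = KNNUncertainty(k=k, metric="euclidean").fit(tab.X[:400])
        dm, de = man.predict_std(q), euc.predict_std(q)
        assert np.all(dm >= 0) and np.all(de >= 0)
        assert np.all(dm >= de - 1e-12)

    def test_ensemble_std_matches_fold_spread(self, noiseless_fit):
        tab, assignment, reg = noiseless_fit
        unc = EnsembleUncertainty(regressor=reg).fit()
        q = tab.X[:30]
        oracle = np.std(np.vstack([m.predict(q) for m in reg.models_]), axis=0)
        assert np.allclose(unc.predict_std(q), oracle)

    def test_forest_sigma_larger_outside_training_hull(self, small_split):
        tab, _, _ = small_split
        unc = train_uncertainty(tab.X[:800], tab.y[:800], method="forest_std", seed=2)
        inside = unc.predict_std(tab.X[:100]).mean()
        outside = unc.predict_std(tab.X[:100] + 1.0).mean()
        assert outside > inside

    def test_unknown_method_rejected(self, small_split):
        tab, _, _ = small_split
        with pytest.raises(ValueError, match="unknown uncertainty"):
            train_uncertainty(tab.X, tab.y, method="bootstrap")


def test_predict_pairs_point_and_sigma(noiseless_fit):
    tab, assignment, reg = noiseless_fit
    tr = assignment.train_mask
    unc = train_uncertainty(tab.X[tr][:500], tab.y[tr][:500], seed=0)
    y_pred, sigma = predict(reg, unc, tab.X[:10])
    assert y_pred.shape == sigma.shape == (10,)
    assert np.all(sigma >= 0)


def test_noisy_rmse_approaches_noise_level():
    s = 10.0
    tab = make_labeled_table(6000, seed=31, noise_std=s)
    a = binned_split(tab.y, n_bins=10, seed=31)
    folds = stratified_folds(a, k=5, seed=31)
    tr = a.train_mask
    reg = train_regressor(tab.X[tr], tab.y[tr], folds[tr], seed=31)
    te = a.test_mask
    rmse = float(np.sqrt(np.mean((reg.predict(tab.X[te]) - tab.y[te]) ** 2)))
    assert s <= rmse <= 1.3 * s  # cannot beat the noise floor; close above it
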