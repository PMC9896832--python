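"""Predictor-set construction: RFE, model-based importance, PCA transform."""

import numpy as np
import pytest

from oksmap.features import (
    ITEM_NAMES,
    all_predictors,
    build_predictor_sets,
    model_based_importance,
    pca_preprocess,
    rfe_rank,
)
from oksmap.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="module")
def three_informative():
    """12 independent items of which exactly three drive the outcome."""
    rng = np.random.default_rng(11)
    X = rng.integers(0, 5, size=(2000, 12)).astype(float)
    latent = X[:, 1] + X[:, 5] + X[:, 9] + rng.normal(0, 1.5, 2000)
    y = np.digitize(latent, np.quantile(latent, [0.2, 0.45, 0.7, 0.9])) + 1
    return X, y


@pytest.fixture(scope="module")
def calibrated_2000():
    return generate_cohort(CohortSpec(n_patients=2000, seed=3))


class TestAllPredictors:
    def test_contains_exactly_the_twelve_items(self):
        ps = all_predictors()
        assert ps.columns == ITEM_NAMES
        X = np.arange(24, dtype=float).reshape(2, 12)
        assert np.array_equal(ps.apply(X), X)


class TestRFE:
    def test_informative_items_occupy_top_ranks(self, three_informative):
        X, y = three_informative
        ps = rfe_rank(X, y, folds=3, repeats=1, seed=0, n_trees=50)
        assert set(ps.ranking[:3]) == {"oks_q02", "oks_q06", "oks_q10"}

    def test_weak_signal_domain_selects_fewer_items(self, calibrated_2000):
        c = calibrated_2000
        strong = rfe_rank(c.oks_items, c.eq_levels[:, 0], folds=3, repeats=1, seed=0, n_trees=50)
        weak = rfe_rank(c.oks_items, c.eq_levels[:, 4], folds=3, repeats=1, seed=0, n_trees=50)
        assert weak.n_columns <= strong.n_columns

    def test_deterministic_given_seed(self, three_informative):
        X, y = three_informative
        a = rfe_rank(X, y, folds=3, repeats=1, seed=4, n_trees=25)
        b = rfe_rank(X, y, folds=3, repeats=1, seed=4, n_trees=25)
        assert a.ranking == b.ranking
        assert a.columns == b.columns

    def test_degenerate_outcome_rejected(self):
        X = np.zeros((100, 12))
        with pytest.raises(ValueError, match="degenerate"):
            rfe_rank(X, np.ones(100))

    def test_too_few_rows_rejected(self, three_informative):
        X, y = three_informative
        with pytest.raises(ValueError, match="50"):
            rfe_rank(X[:30], y[:30])


class TestModelBasedImportance:
    @pytest.mark.parametrize("family", ["cumulative", "penalized", "ocart", "oforest"])
    def test_informative_items_dominate(self, three_informative, family):
        X, y = three_informative
        ps = model_based_importance(family, X, y, seed=0)
        top3 = set(ps.ranking[:3])
        assert top3 == {"oks_q02", "oks_q06", "oks_q10"}

    def test_empty_lasso_selection_falls_back_to_all(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 5, size=(300, 12)).astype(float)
        y = rng.integers(1, 4, size=300)  # outcome independent of items
        with pytest.warns(UserWarning, match="falling back"):
            ps = model_based_importance("penalized", X, y, seed=0)
        assert ps.columns == ITEM_NAMES

    def test_tree_gives_zero_importance_to_unsplit_items(self, three_informative):
        X, y = three_informative
        ps = model_based_importance("ocart", X, y, seed=0)
        # at least the three informative items retained; every retained
        # item had a positive impurity decrease
        assert {"oks_q02", "oks_q06", "oks_q10"} <= set(ps.columns)


class TestPCA:
    def test_independent_items_need_nearly_all_components(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(2000, 12))
        ps = pca_preprocess(X)
        assert ps.n_columns >= 11

    def test_strong_single_factor_needs_few_components(self):
        rng = np.random.default_rng(5)
        latent = rng.normal(size=2000)
        X = np.outer(latent, np.ones(12)) + 0.25 * rng.normal(size=(2000, 12))
        ps = pca_preprocess(X)
        assert ps.n_columns <= 3

    def test_calibrated_cohort_shows_dominant_first_component(self, calibrated_2000):
        ps = pca_preprocess(calibrated_2000.oks_items)
        assert 0.55 <= ps.explained_variance_ratio[0] <= 0.75
        assert ps.n_columns < 11

    def test_components_orthogonal_in_sample(self, calibrated_2000):
        ps = pca_preprocess(calibrated_2000.oks_items)
        Z = ps.apply(calibrated_2000.oks_items)
        corr = np.corrcoef(Z.T)
        off = corr - np.diag(np.diag(corr))
        assert np.max(np.abs(off)) < 1e-8

    def test_cumulative_variance_reaches_target(self, calibrated_2000):
        ps = pca_preprocess(calibrated_2000.oks_items)
        # the retained components reach 90%; one fewer would not
        X = np.asarray(calibrated_2000.oks_items, dtype=float)
        corr = np.corrcoef(((X - X.mean(0)) / X.std(0)).T)
        evals = np.sort(np.linalg.eigvalsh(corr))[::-1]
        ratio = evals / evals.sum()
        assert np.cumsum(ratio)[ps.n_columns - 1] >= 0.90
        assert np.cumsum(ratio)[ps.n_columns - 2] < 0.90

    def test_constant_column_names_the_item(self):
        X = np.random.default_rng(0).normal(size=(100, 12))
        X[:, 6] = 2.0
        with pytest.raises(ValueError, match="oks_q07"):
            pca_preprocess(X)

    def test_transform_reuses_estimation_centers(self, calibrated_2000):
        # the leakage guard: validation rows are transformed with
        # estimation-sample centers/scales/rotation
        est = calibrated_2000.oks_items[:1500]
        val = calibrated_2000.oks_items[1500:]
        ps = pca_preprocess(est)
        expected = ((val - ps.center) / ps.scale) @ ps.rotation
        assert np.allclose(ps.apply(val), expected)
        ps_val = pca_preprocess(val)
        assert not np.allclose(ps.center, ps_val.center)


def test_build_predictor_sets_returns_all_four(three_informative):
    X, y = three_informative
    sets = build_predictor_sets("cumulative", X, y, seed=0, rfe_folds=3, rfe_repeats=1, rfe_trees=25)
    assert set(sets) == {"all", "rfe", "model_based", "pca"}
    for ps in sets.values():
        assert ps.apply(X).shape[0] == len(X)
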