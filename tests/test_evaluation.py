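"""Accuracy measures, profile assembly, utility errors, conceptual overlap."""

import numpy as np
import pytest
from scipy import stats

from oksmap.evaluation import (
    assemble_profiles,
    baseline_accuracy,
    conceptual_overlap,
    crude_accuracy,
    multi_valueset_summary,
    utility_errors,
)
from oksmap.instruments import DOMAINS, EQProfile, ValueSet

# Published estimation-sample level counts per domain (n = 456), from
# which the study's baseline accuracies derive.
LEVEL_COUNTS = {
    "MO": [121, 111, 103, 94, 27],
    "SC": [271, 61, 62, 38, 24],
    "UA": [112, 116, 113, 68, 47],
    "PD": [38, 140, 140, 77, 61],
    "AD": [118, 114, 138, 48, 38],
}
PUBLISHED_BASELINE_PCT = {"MO": 26.5, "SC": 59.4, "UA": 25.4, "PD": 30.7, "AD": 30.3}


class TestBaselineAccuracy:
    @pytest.mark.parametrize("domain", list(LEVEL_COUNTS))
    def test_reproduces_published_baselines(self, domain):
        y = np.repeat([1, 2, 3, 4, 5], LEVEL_COUNTS[domain])
        assert len(y) == 456
        pct = 100 * baseline_accuracy(y)
        assert pct == pytest.approx(PUBLISHED_BASELINE_PCT[domain], abs=0.05)

    def test_degenerate_and_uniform_vectors(self):
        assert baseline_accuracy(np.ones(30)) == 1.0
        assert baseline_accuracy(np.tile([1, 2, 3, 4, 5], 20)) == pytest.approx(0.2)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            baseline_accuracy([])


class TestCrudeAccuracy:
    def test_perfect_and_disjoint(self):
        y = np.tile([1, 2, 3], 30)
        perfect = crude_accuracy(y, y, boot_B=300)
        assert perfect.crude == 1.0
        assert perfect.ci_low == perfect.ci_high == 1.0
        disjoint = crude_accuracy(y, y + 1, boot_B=300)
        assert disjoint.crude == 0.0

    def test_half_matching_ci_straddles_point(self):
        pred = np.array([1] * 50 + [2] * 50)
        actual = np.array([1] * 50 + [3] * 50)  # exactly half the rows match
        r = crude_accuracy(pred, actual, boot_B=2000, seed=1)
        assert r.crude == pytest.approx(0.5)
        assert r.ci_low < 0.5 < r.ci_high

    def test_ci_orders_around_point(self):
        rng = np.random.default_rng(0)
        pred = rng.integers(1, 4, 200)
        actual = rng.integers(1, 4, 200)
        r = crude_accuracy(pred, actual, boot_B=500, seed=0)
        assert 0 <= r.ci_low <= r.crude <= r.ci_high <= 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            crude_accuracy([1, 2], [1, 2, 3])


class TestProfileAssembly:
    def test_examples(self):
        profiles = assemble_profiles([[1, 5, 1], [1, 5, 2], [1, 5, 3], [1, 5, 4], [1, 5, 5]])
        assert [p.code for p in profiles] == ["11111", "55555", "12345"]

    def test_misaligned_vectors_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            assemble_profiles([[1], [1], [1], [1], [1, 2]])

    def test_wrong_domain_count_rejected(self):
        with pytest.raises(ValueError, match="five"):
            assemble_profiles([[1], [1], [1]])


class TestUtilityErrors:
    def test_perfect_prediction_collapses_to_zero(self, toy_value_sets):
        profiles = [EQProfile.from_code(c) for c in ["11111", "23145", "55555", "31224"]]
        r = utility_errors(profiles, profiles, toy_value_sets[0], boot_B=300)
        assert r.mae == r.mse == 0.0
        assert r.mae_ci == (0.0, 0.0)

    def test_two_patient_arithmetic(self):
        # decrements chosen so the two patients' utility errors are 0.1 and 0.3
        dec = {d: {2: 0.1, 3: 0.2, 4: 0.3, 5: 0.4} for d in DOMAINS}
        vs = ValueSet(country="t", decrements=dec)
        actual = [EQProfile.from_code("11111"), EQProfile.from_code("11111")]
        pred = [EQProfile.from_code("21111"), EQProfile.from_code("41111")]
        r = utility_errors(actual, pred, vs, boot_B=200, seed=0)
        assert r.mae == pytest.approx(0.2)
        assert r.mse == pytest.approx(0.05)

    def test_constant_shift_leaves_errors_unchanged(self, toy_value_sets):
        rng = np.random.default_rng(2)
        actual = [EQProfile(tuple(rng.integers(1, 6, 5))) for _ in range(60)]
        pred = [EQProfile(tuple(rng.integers(1, 6, 5))) for _ in range(60)]
        vs = toy_value_sets[0]
        shifted = ValueSet(country="s", dialect="additive", constant=vs.constant + 0.37,
                           decrements=vs.decrements)
        a = utility_errors(actual, pred, vs, boot_B=200, seed=3)
        b = utility_errors(actual, pred, shifted, boot_B=200, seed=3)
        assert a.mae == pytest.approx(b.mae, abs=1e-12)
        assert a.mse == pytest.approx(b.mse, abs=1e-12)

    def test_bootstrap_ci_contains_point_estimate(self, toy_value_sets):
        rng = np.random.default_rng(4)
        actual = [EQProfile(tuple(rng.integers(1, 6, 5))) for _ in range(80)]
        pred = [EQProfile(tuple(rng.integers(1, 6, 5))) for _ in range(80)]
        r = utility_errors(actual, pred, toy_value_sets[1], boot_B=400, seed=5)
        assert r.mae_ci[0] <= r.mae <= r.mae_ci[1]
        assert r.mse_ci[0] <= r.mse <= r.mse_ci[1]

    def test_median_split_partitions_patients(self, toy_value_sets):
        rng = np.random.default_rng(6)
        actual = [EQProfile(tuple(rng.integers(1, 6, 5))) for _ in range(115)]
        pred = [EQProfile(tuple(rng.integers(1, 6, 5))) for _ in range(115)]
        r = utility_errors(actual, pred, toy_value_sets[0], boot_B=200, seed=7)
        assert r.n_above + r.n_below == 115

    def test_empty_input_rejected(self, toy_value_sets):
        with pytest.raises(ValueError, match="empty"):
            utility_errors([], [], toy_value_sets[0])


class TestSummary:
    def _report(self, mae, mse=0.01):
        from oksmap.evaluation import UtilityErrorReport

        return UtilityErrorReport(
            value_set_id="x", tariff_type="VT", mae=mae, mae_ci=(0, 1),
            mse=mse, mse_ci=(0, 1), mae_above_median=mae / 2, mae_above_ci=(0, 1),
            mae_below_median=mae * 1.5, mae_below_ci=(0, 1), n=10, n_above=5, n_below=5,
        )

    def test_single_report(self):
        s = multi_valueset_summary([self._report(0.1)])
        assert s.loc["mean", "mae"] == s.loc["min", "mae"] == s.loc["max", "mae"] == 0.1
        assert s.loc["sd", "mae"] == 0.0

    def test_two_reports_hand_computation(self):
        s = multi_valueset_summary([self._report(0.1, 0.01), self._report(0.2, 0.03)])
        assert s.loc["mean", "mae"] == pytest.approx(0.15)
        assert s.loc["sd", "mae"] == pytest.approx(np.std([0.1, 0.2], ddof=1))
        assert s.loc["min", "mse"] == pytest.approx(0.01)
        assert s.loc["max", "mse"] == pytest.approx(0.03)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            multi_valueset_summary([])


class TestConceptualOverlap:
    def test_linear_utility_gives_unit_r_squared(self):
        rng = np.random.default_rng(0)
        oks = rng.integers(0, 5, size=(200, 12))
        eq = rng.integers(1, 6, size=(200, 5))
        util = 0.02 * oks.sum(axis=1) - 0.1
        _, ols = conceptual_overlap(oks, eq, util)
        assert ols["r_squared"] == pytest.approx(1.0)
        assert ols["slope"] == pytest.approx(0.02)

    def test_independent_inputs_show_no_correlation(self):
        rng = np.random.default_rng(123)
        oks = rng.integers(0, 5, size=(1000, 12))
        eq = rng.integers(1, 6, size=(1000, 5))
        util = rng.normal(size=1000)
        rho, _ = conceptual_overlap(oks, eq, util)
        assert np.nanmax(np.abs(rho.to_numpy())) < 0.1

    def test_calibrated_cohort_entries_all_negative(self, estimation_cohort, toy_value_sets):
        from oksmap.evaluation import assemble_profiles
        from oksmap.instruments import utilities

        eq = estimation_cohort.eq_levels
        profiles = assemble_profiles([eq[:, d] for d in range(5)])
        util = utilities(profiles, toy_value_sets[0])
        rho, ols = conceptual_overlap(estimation_cohort.oks_items, eq, util)
        assert np.all(rho.to_numpy() < 0)
        assert ols["slope"] > 0  # higher OKS total = better health = higher utility

    def test_constant_column_reported_missing(self):
        oks = np.ones((50, 12), dtype=int)
        eq = np.random.default_rng(0).integers(1, 6, size=(50, 5))
        rho, _ = conceptual_overlap(oks, eq, np.random.default_rng(1).normal(size=50))
        assert rho.isna().all().all()
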