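"""Growth-curve parameterization: loess, steepest slope, sibling delta, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pengrowth import growthcurves as gc
from conftest import make_series


# --- independent oracles -----------------------------------------------------


def loess_oracle(x, y, x0, span, degree):
    """Brute-force locally weighted least squares at one point."""
    import math

    q = math.ceil(span * len(x))
    d = np.abs(x - x0)
    keep = np.argsort(d, kind="stable")[:q]
    dmax = d[keep].max()
    if dmax == 0:
        return float(np.mean(y[keep]))
    w = (1 - (d[keep] / dmax) ** 3) ** 3
    W = np.diag(w)
    X = np.vander(x[keep] - x0, degree + 1, increasing=True)
    beta = np.linalg.pinv(X.T @ W @ X) @ X.T @ W @ y[keep]
    return float(beta[0])


def steepest_oracle(series, min_points=3, min_span_days=5.0):
    """Exhaustive OLS over every admissible contiguous window."""
    x, y = series.ages, series.masses
    cands = []
    for i in range(len(x)):
        for j in range(i + min_points - 1, len(x)):
            if x[j] - x[i] < min_span_days:
                continue
            slope = np.polyfit(x[i : j + 1], y[i : j + 1], 1)[0]
            cands.append((slope, x[j] - x[i], -x[i]))
    slope, dur, negstart = max(cands, key=lambda t: (round(t[0], 9), t[1], t[2]))
    return slope, -negstart, dur


# --- validate_series ---------------------------------------------------------


class TestValidateSeries:
    def _raw(self, rows):
        return pd.DataFrame(rows, columns=["chick_id", "brood_id", "season", "age_days", "mass_g"])

    def test_short_series_excluded_and_reported(self):
        rows = [("a", "b1", 2001, 20 + 3 * i, 500 + 50 * i) for i in range(4)]
        series, report = gc.validate_series(self._raw(rows))
        assert series == []
        assert report.excluded_chicks == [("a", 4)]

    def test_clean_five_point_series_accepted_unchanged(self):
        rows = [("a", "b1", 2001, 20 + 5 * i, 500 + 50 * i) for i in range(5)]
        series, report = gc.validate_series(self._raw(rows))
        assert len(series) == 1
        np.testing.assert_array_equal(series[0].ages, [20, 25, 30, 35, 40])
        np.testing.assert_array_equal(series[0].masses, [500, 550, 600, 650, 700])
        assert report.n_rejected_rows == 0

    def test_duplicate_ages_averaged(self):
        rows = [("a", "b1", 2001, 20 + 5 * i, 500.0) for i in range(5)]
        rows += [("a", "b1", 2001, 20, 520.0)]  # duplicate at age 20: 500 & 520
        series, _ = gc.validate_series(self._raw(rows))
        assert series[0].masses[0] == pytest.approx(510.0)
        assert series[0].n == 5

    def test_bad_rows_rejected_with_reason(self):
        rows = [("a", "b1", 2001, 20 + 3 * i, 500 + 10 * i) for i in range(5)]
        rows += [("a", "b1", 2001, 50, -5.0), ("a", "b1", 2001, -1, 400.0)]
        series, report = gc.validate_series(self._raw(rows))
        assert report.n_rejected_rows == 2
        reasons = {r[2] for r in report.rejected_reasons}
        assert reasons == {"non-positive mass", "negative age"}
        assert len(series) == 1

    def test_fledged_flag_rule(self):
        # leaves after day 45 with peak >= 800 g -> fledged
        good = [("a", "b", 2001, a, m) for a, m in zip(range(24, 54, 6), [500, 700, 850, 820, 800])]
        light = [("b", "b", 2001, a, m) for a, m in zip(range(24, 54, 6), [400, 500, 600, 650, 640])]
        series, _ = gc.validate_series(self._raw(good + light))
        flags = {s.chick_id: s.fledged for s in series}
        assert flags == {"a": True, "b": False}


# --- loess & irregularity ----------------------------------------------------


class TestLoess:
    def test_linear_data_reproduced_exactly(self, linear_series):
        fit = gc.loess_smooth(linear_series, span=0.9, degree=1)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-9)

    def test_constant_data_fit_is_constant(self):
        s = make_series(np.arange(20, 41, 4), np.full(6, 700.0))
        fit = gc.loess_smooth(s, span=0.9, degree=1)
        np.testing.assert_allclose(fit.fitted, 700.0, atol=1e-9)

    def test_fitted_plus_residuals_reproduce_observations(self, linear_series):
        fit = gc.loess_smooth(linear_series, span=0.7, degree=2)
        np.testing.assert_allclose(fit.fitted + fit.residuals, linear_series.masses, atol=1e-12)

    def test_matches_independent_oracle_on_curved_data(self):
        rng = np.random.default_rng(42)
        ages = np.arange(12, 48, 3, dtype=float)
        masses = 1000 / (1 + np.exp(-0.2 * (ages - 25))) + rng.normal(0, 30, len(ages))
        s = make_series(ages, masses)
        for span, degree in [(0.9, 2), (0.75, 1), (0.6, 2)]:
            fit = gc.loess_smooth(s, span=span, degree=degree)
            expect = [loess_oracle(ages, masses, a, span, degree) for a in ages]
            np.testing.assert_allclose(fit.fitted, expect, atol=1e-6)

    def test_window_too_small_raises(self):
        s = make_series([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        with pytest.raises(ValueError, match="at least"):
            gc.loess_smooth(s, span=0.3, degree=2)


class TestIrregularity:
    def test_zero_on_straight_line(self, linear_series):
        assert gc.irregularity_index(linear_series) == pytest.approx(0.0, abs=1e-9)

    def test_scales_linearly_with_mass(self):
        rng = np.random.default_rng(3)
        ages = np.arange(15, 45, 3, dtype=float)
        masses = 600 + 15 * ages + rng.normal(0, 40, len(ages))
        s1 = make_series(ages, masses)
        s2 = make_series(ages, 2.5 * masses)
        assert gc.irregularity_index(s2) == pytest.approx(2.5 * gc.irregularity_index(s1), rel=1e-9)

    def test_sawtooth_matches_direct_recomputation(self):
        ages = np.arange(10, 40, 3, dtype=float)  # n=10
        masses = 500 + 20 * ages + 50 * np.array([1, -1] * 5)
        s = make_series(ages, masses)
        expect = np.mean(
            [abs(m - loess_oracle(ages, masses, a, 0.9, 2)) for a, m in zip(ages, masses)]
        )
        assert gc.irregularity_index(s, span=0.9) == pytest.approx(expect, abs=1e-9)


# --- steepest slope ----------------------------------------------------------


class TestSteepestSlope:
    def test_linear_series_full_span(self, linear_series):
        slope, start, dur = gc.steepest_slope_segment(linear_series)
        assert slope == pytest.approx(25.0, abs=1e-9)
        assert start == linear_series.ages[0]
        assert dur == linear_series.ages[-1] - linear_series.ages[0]

    def test_logistic_recovers_analytic_max_derivative(self):
        A, k = 1200.0, 0.25
        # daily sampling: the shortest admissible OLS window (>=5 days)
        # under-reads the instantaneous derivative by only a few percent
        ages = np.arange(4, 44, 1, dtype=float)
        masses = A / (1 + np.exp(-k * (ages - 24)))
        slope, _, _ = gc.steepest_slope_segment(make_series(ages, masses))
        assert slope == pytest.approx(A * k / 4, rel=0.05)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_equals_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        ages = np.sort(rng.choice(np.arange(8, 60), size=n, replace=False)).astype(float)
        masses = np.maximum(rng.normal(600 + 12 * ages, 80), 1.0)
        s = make_series(ages, masses)
        got = gc.steepest_slope_segment(s)
        want = steepest_oracle(s)
        assert got[0] == pytest.approx(want[0], abs=1e-8)
        assert (got[1], got[2]) == (want[1], want[2])

    def test_no_admissible_window_raises(self):
        s = make_series([10, 11, 12, 13, 14], [1, 2, 3, 4, 5])
        with pytest.raises(ValueError, match="window"):
            gc.steepest_slope_segment(s, min_points=3, min_span_days=10)


# --- sibling delta -----------------------------------------------------------


class TestSiblingDelta:
    def test_identical_siblings_zero(self, linear_series):
        twin = make_series(linear_series.ages, linear_series.masses, chick_id="c2")
        assert gc.sibling_delta(linear_series, twin) == pytest.approx(0.0)

    def test_constant_offset_and_antisymmetry(self):
        ages = np.arange(20, 45, 5, dtype=float)
        a = make_series(ages, np.full(5, 1100.0))
        b = make_series(ages, np.full(5, 900.0), chick_id="c2")
        assert gc.sibling_delta(a, b) == pytest.approx(0.2)
        assert gc.sibling_delta(b, a) == pytest.approx(-0.2)

    def test_two_shared_age_arithmetic(self):
        a = make_series([20, 25, 30, 35, 40], [900, 1000, 1200, 1150, 1100])
        b = make_series([20, 25, 30, 33, 41], [850, 800, 1000, 1000, 1000], chick_id="c2")
        # shared ages 20, 25, 30; the example uses the last two
        d = gc.sibling_delta(a, b)
        expect = np.mean([50 / 875, 200 / 900, 200 / 1100])
        assert d == pytest.approx(expect)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_antisymmetric_exactly(self, seed):
        rng = np.random.default_rng(seed)
        ages = np.sort(rng.choice(np.arange(10, 60), 7, replace=False)).astype(float)
        a = make_series(ages, rng.uniform(300, 1200, 7))
        b = make_series(ages, rng.uniform(300, 1200, 7), chick_id="c2")
        assert gc.sibling_delta(a, b) == -gc.sibling_delta(b, a)

    def test_missing_when_no_shared_age(self):
        a = make_series([20, 22, 24, 26, 28], [1] * 5)
        b = make_series([21, 23, 25, 27, 29], [1] * 5, chick_id="c2")
        assert gc.sibling_delta(a, b) is None
        assert gc.sibling_delta(a, None) is None


# --- full parameter extraction ----------------------------------------------


class TestGrowthParams:
    def test_worked_example(self):
        s = make_series([20, 30, 40, 45, 50], [800, 1000, 1200, 1150, 1100])
        p = gc.compute_growth_params(s)
        assert p.peak_mass == 1200
        assert p.age_at_peak == 40
        assert p.fledge_mass == 1100
        assert p.rel_mass_loss == pytest.approx(0.0833, abs=1e-4)
        assert p.guard_duration == 20
        assert p.age_at_fledge == 50

    def test_monotone_series_no_mass_loss(self):
        s = make_series([20, 25, 30, 35, 40], [500, 600, 700, 800, 900])
        p = gc.compute_growth_params(s)
        assert p.rel_mass_loss == 0
        assert p.age_at_peak == p.age_at_fledge

    def test_mass_scaling_equivariance(self):
        rng = np.random.default_rng(7)
        ages = np.arange(14, 50, 3, dtype=float)
        masses = 500 + 18 * ages + rng.normal(0, 30, len(ages))
        p1 = gc.compute_growth_params(make_series(ages, masses))
        p2 = gc.compute_growth_params(make_series(ages, 3.0 * masses))
        for scaled in ("peak_mass", "fledge_mass", "steepest_slope", "irregularity"):
            assert getattr(p2, scaled) == pytest.approx(3.0 * getattr(p1, scaled), rel=1e-9)
        for inv in ("rel_mass_loss", "guard_duration", "age_at_peak", "age_at_fledge"):
            assert getattr(p2, inv) == pytest.approx(getattr(p1, inv), abs=1e-12)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(11)
        rows = [("a", "b1", 2001, 20 + 3 * i, float(500 + 30 * i + rng.normal(0, 5))) for i in range(8)]
        df = pd.DataFrame(rows, columns=["chick_id", "brood_id", "season", "age_days", "mass_g"])
        shuffled = df.sample(frac=1, random_state=5)
        p1 = gc.params_table(gc.validate_series(df)[0])
        p2 = gc.params_table(gc.validate_series(shuffled)[0])
        pd.testing.assert_frame_equal(p1, p2)


class TestBroodCrossTab:
    def test_concordant_fast_pairs(self):
        assignments = {f"c{i}": "fast" for i in range(4)}
        broods = pd.DataFrame(
            {"brood_id": ["b1", "b1", "b2", "b2"], "chick_id": ["c0", "c1", "c2", "c3"]}
        )
        tab = gc.brood_cross_tab(assignments, broods)
        assert tab.loc["fast", "fast"] == 4
        assert tab.loc["none", "fast"] == 0

    def test_singletons_fall_in_none_row(self):
        assignments = {"c0": "fast", "c1": "slow"}
        broods = pd.DataFrame({"brood_id": ["b1", "b2"], "chick_id": ["c0", "c1"]})
        tab = gc.brood_cross_tab(assignments, broods)
        assert tab.loc["none", "fast"] == 1
        assert tab.loc["none", "slow"] == 1

    def test_column_sums_conserve_cluster_sizes(self):
        rng = np.random.default_rng(0)
        labels = ["fast", "slow", "light"]
        assignments, brood_rows = {}, []
        for b in range(150):
            size = 1 if rng.random() < 0.3 else 2
            for j in range(size):
                cid = f"c{b}_{j}"
                assignments[cid] = labels[rng.integers(3)]
                brood_rows.append((f"b{b}", cid))
        broods = pd.DataFrame(brood_rows, columns=["brood_id", "chick_id"])
        tab = gc.brood_cross_tab(assignments, broods)
        counts = tab.iloc[:4].astype(int)
        sizes = pd.Series(assignments).value_counts()
        for lab in labels:
            assert counts[lab].sum() == sizes[lab]

    def test_three_chick_brood_rejected(self):
        broods = pd.DataFrame({"brood_id": ["b1"] * 3, "chick_id": ["c0", "c1", "c2"]})
        with pytest.raises(ValueError, match="at most 2"):
            gc.brood_cross_tab({"c0": "fast"}, broods)
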