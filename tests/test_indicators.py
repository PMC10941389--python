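import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from resilink import indicators as ind
from resilink.feedclean import DailyIntakeSeries


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def oracle_lag1(e):
    obs = ~np.isnan(e)
    vals = e[obs]
    m = vals.mean()
    num = sum(
        (e[t] - m) * (e[t + 1] - m)
        for t in range(len(e) - 1)
        if obs[t] and obs[t + 1]
    )
    return num / ((vals - m) ** 2).sum()


def oracle_runs(e, min_len=3):
    runs, cur = [], []
    for i, v in enumerate(e):
        if not np.isnan(v) and v < 0:
            cur.append(i)
        else:
            if len(cur) >= min_len:
                runs.append((cur[0], cur[-1]))
            cur = []
    if len(cur) >= min_len:
        runs.append((cur[0], cur[-1]))
    return runs


def oracle_maxarea(e, min_len=3):
    areas = []
    for s, t in oracle_runs(e, min_len):
        seg = -e[s: t + 1]
        areas.append(sum((seg[i] + seg[i + 1]) / 2 for i in range(len(seg) - 1)))
    if not areas or max(areas) <= 0:
        return math.nan
    return math.log(max(areas))


def oracle_summin(e):
    total = 0.0
    for i in range(1, len(e) - 1):
        if np.isnan(e[i - 1]) or np.isnan(e[i]) or np.isnan(e[i + 1]):
            continue
        if e[i] < e[i - 1] and e[i] < e[i + 1]:
            total += e[i]
    return total


# ---------------------------------------------------------------------------
# smoothing and trend
# ---------------------------------------------------------------------------

class TestMovingMedian:
    def test_constant_series_unchanged(self):
        out = ind.moving_median(np.full(10, 3.0))
        assert np.allclose(out, 3.0)

    def test_spike_suppressed_by_window_median(self):
        out = ind.moving_median(np.array([1.0, 2, 100, 3, 4]))
        assert out[2] == 3  # median of the full 5-window

    def test_monotone_series_keeps_interior_values(self):
        x = np.arange(10, dtype=float)
        out = ind.moving_median(x)
        assert np.allclose(out[2:-2], x[2:-2])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            ind.moving_median(np.ones(5), window=4)

    def test_missing_days_stay_missing(self):
        x = np.array([1.0, np.nan, 1, 1, 1])
        out = ind.moving_median(x)
        assert np.isnan(out[1])


class TestLinearTrend:
    def test_perfect_line_gives_zero_residuals(self):
        ages = np.arange(99, 120)
        smoothed = 0.5 + 0.02 * ages
        *_, resid = ind.fit_linear_trend(smoothed, ages)
        assert np.allclose(resid, 0, atol=1e-10)

    def test_three_point_closed_form(self):
        intercept, slope, _, _ = ind.fit_linear_trend(
            np.array([1.0, 2, 4]), np.array([1, 2, 3])
        )
        assert slope == pytest.approx(1.5)
        assert intercept == pytest.approx(-2 / 3)

    def test_residuals_sum_to_zero(self, rng):
        ages = np.arange(99, 141)
        smoothed = rng.normal(2, 0.3, len(ages))
        *_, resid = ind.fit_linear_trend(smoothed, ages)
        assert abs(np.nansum(resid)) < 1e-8 * len(ages)

    def test_identical_ages_rejected(self):
        with pytest.raises(ValueError):
            ind.fit_linear_trend(np.array([1.0, 2, 3]), np.array([5, 5, 5]))


# ---------------------------------------------------------------------------
# the four indicators
# ---------------------------------------------------------------------------

class TestLag1:
    def test_alternating_series_value(self):
        e = np.array([1.0, -1, 1, -1, 1, -1])
        assert ind.lag1_autocorrelation(e) == pytest.approx(-5 / 6)

    def test_ar1_simulation_recovers_phi(self, rng):
        phi, n = 0.5, 1000
        x = np.empty(n)
        x[0] = rng.normal()
        for t in range(1, n):
            x[t] = phi * x[t - 1] + rng.normal(0, math.sqrt(1 - phi**2))
        assert 0.45 <= ind.lag1_autocorrelation(x) <= 0.55

    def test_constant_residuals_rejected(self):
        with pytest.raises(ValueError):
            ind.lag1_autocorrelation(np.full(10, 2.0))


class TestLnVar:
    def test_two_point_value(self):
        assert ind.ln_variance(np.array([-2.0, 2.0])) == pytest.approx(math.log(8))

    def test_scaling_law(self, rng):
        e = rng.normal(0, 1, 50)
        k = 3.7
        assert ind.ln_variance(k * e) == pytest.approx(
            ind.ln_variance(e) + 2 * math.log(k)
        )

    def test_iid_normal_recovers_log_variance(self, rng):
        e = rng.normal(0, 2, 1000)
        assert abs(ind.ln_variance(e) - math.log(4)) < 0.15

    def test_zero_variance_is_missing_with_warning(self):
        with pytest.warns(UserWarning):
            assert math.isnan(ind.ln_variance(np.zeros(5)))


class TestNegativeRunsAndArea:
    def test_all_positive_no_runs(self):
        assert ind.negative_runs(np.ones(10)) == []
        assert math.isnan(ind.max_negative_area(np.ones(10)))

    def test_minimal_run_of_three(self):
        assert ind.negative_runs(np.array([-1.0, -1, -1])) == [(0, 2)]

    def test_missing_day_terminates_run(self):
        e = np.array([-1.0, -1, np.nan, -1, -1, -1, -1])
        assert ind.negative_runs(e) == [(3, 6)]

    def test_largest_run_area_selected(self):
        e = np.array([-1.0, -1, -1, 1, -2, -2, -2, -2])
        # areas: 2 (trapezoid of -1 over 3 days) and 6
        assert ind.max_negative_area(e) == pytest.approx(math.log(6))

    def test_constant_run_area_formula(self):
        for c, length in [(0.5, 3), (1.5, 5), (2.0, 7)]:
            e = np.full(length, -c)
            assert ind.max_negative_area(e) == pytest.approx(math.log(c * (length - 1)))

    def test_deepening_a_run_never_decreases_area(self, rng):
        e = -np.abs(rng.normal(1, 0.3, 6))
        deeper = e.copy()
        deeper[2] -= 1.0
        assert ind.max_negative_area(deeper) >= ind.max_negative_area(e)


class TestSumMin:
    def test_monotone_has_no_minima(self):
        assert ind.sum_local_minima(np.arange(5.0)) == 0.0

    def test_single_v(self):
        assert ind.sum_local_minima(np.array([0.0, -3, 0])) == -3

    def test_two_minima(self):
        e = np.array([2.0, -1, 2, -4, 2, 1])
        assert ind.sum_local_minima(e) == -5

    def test_plateau_is_not_a_minimum(self):
        assert ind.sum_local_minima(np.array([1.0, 0, 0, 1])) == 0.0


class TestOracleEquivalence:
    """Randomised series (with gaps) against independent brute-force oracles."""

    def test_indicators_match_oracles_on_random_series(self, rng):
        for _ in range(300):
            n = int(rng.integers(6, 50))
            e = rng.normal(0, 1, n)
            e[rng.random(n) < 0.1] = np.nan
            if (~np.isnan(e)).sum() < 4 or np.nanstd(e) == 0:
                continue
            assert ind.lag1_autocorrelation(e) == pytest.approx(
                oracle_lag1(e), abs=1e-10
            )
            assert ind.negative_runs(e) == oracle_runs(e)
            ours, ref = ind.max_negative_area(e), oracle_maxarea(e)
            assert (math.isnan(ours) and math.isnan(ref)) or ours == pytest.approx(
                ref, abs=1e-10
            )
            assert ind.sum_local_minima(e) == pytest.approx(oracle_summin(e), abs=1e-10)


# ---------------------------------------------------------------------------
# per-animal pipeline invariances
# ---------------------------------------------------------------------------

def _series_from_fcd(fcd, ages=None):
    ages = np.arange(99, 99 + len(fcd)) if ages is None else ages
    return DailyIntakeSeries(
        animal_id="A", breed="DR", pen_id="P", room_id="R", sire_id="S",
        ages=ages, fcd=fcd,
    )


class TestPipelineInvariance:
    def test_translation_invariance(self, rng):
        fcd = rng.normal(2.0, 0.4, 42)
        base = ind.compute_indicators([_series_from_fcd(fcd)])
        shifted = ind.compute_indicators([_series_from_fcd(fcd + 5.0)])
        for col in ind.INDICATOR_NAMES:
            a, b = base[col].iloc[0], shifted[col].iloc[0]
            if math.isnan(a):
                assert math.isnan(b)
            else:
                assert a == pytest.approx(b, abs=1e-8)

    def test_linear_trend_absorbed_by_detrending(self, rng):
        # the OLS stage absorbs any linear-in-age term exactly (the
        # moving-median stage is not trend-equivariant, so the identity
        # holds at the smoothed-series level)
        ages = np.arange(99, 141)
        smoothed = rng.normal(2.0, 0.3, 42)
        *_, resid_base = ind.fit_linear_trend(smoothed, ages)
        *_, resid_tilt = ind.fit_linear_trend(smoothed + 0.05 * ages + 3.0, ages)
        assert np.allclose(resid_base, resid_tilt, atol=1e-10)

    def test_determinism(self, rng):
        fcd = rng.normal(2.0, 0.4, 42)
        a = ind.compute_indicators([_series_from_fcd(fcd)])
        b = ind.compute_indicators([_series_from_fcd(fcd.copy())])
        pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# class labels
# ---------------------------------------------------------------------------

class TestClasses:
    def _frame(self, values, breed="DR"):
        return pd.DataFrame(
            {
                "animal_id": [f"A{i}" for i in range(len(values))],
                "breed": breed,
                "lnvar": values,
            }
        )

    def test_tail_sizes_at_n200(self, rng):
        df = self._frame(rng.normal(0, 1, 200))
        lab = ind.assign_classes(df, "lnvar")
        counts = lab["label"].value_counts()
        assert counts["H"] == 10 and counts["L"] == 10
        assert abs(counts["M"] - 10) <= 1

    def test_low_values_are_high_resilience(self, rng):
        vals = np.sort(rng.normal(0, 1, 100))
        df = self._frame(vals)
        lab = ind.assign_classes(df, "lnvar").set_index("animal_id")["label"]
        assert lab["A0"] == "H" and lab["A99"] == "L"

    def test_tail_sizes_within_one_of_five_percent(self, rng):
        for n in (83, 117, 200):
            df = self._frame(rng.normal(0, 1, n))
            counts = ind.assign_classes(df, "lnvar")["label"].value_counts()
            assert abs(counts.get("H", 0) - math.ceil(0.05 * n)) <= 1
            assert abs(counts.get("L", 0) - math.ceil(0.05 * n)) <= 1

    def test_ties_resolved_deterministically(self):
        vals = [1.0] * 10 + [2.0] * 10 + [3.0] * 10 + [4.0] * 10
        df = self._frame(vals)
        a = ind.assign_classes(df, "lnvar")
        b = ind.assign_classes(df, "lnvar")
        pd.testing.assert_frame_equal(a, b)
        # first-occurrence rank order: the first tied value lands in the low bin
        assert a.set_index("animal_id").loc["A0", "label"] == "H"

    def test_too_few_animals_rejected(self):
        with pytest.raises(ValueError):
            ind.assign_classes(self._frame([1.0] * 10), "lnvar")

    def test_ntile_matches_equal_frequency_semantics(self):
        bins = ind.ntile(np.arange(5), 2)
        assert list(bins) == [1, 1, 1, 2, 2]  # larger bins first


# ---------------------------------------------------------------------------
# trait correlations
# ---------------------------------------------------------------------------

class TestSpearman:
    def _tables(self, x, y):
        inds = pd.DataFrame(
            {
                "animal_id": [f"A{i}" for i in range(len(x))],
                "breed": "DR",
                "lag1": x, "lnvar": x, "maxarea": x, "summin": x,
            }
        )
        traits = pd.DataFrame(
            {"animal_id": [f"A{i}" for i in range(len(x))], "muscle": y}
        )
        return inds, traits

    def test_perfect_monotone_correlations(self, rng):
        x = rng.normal(0, 1, 30)
        inds, traits = self._tables(x, np.exp(x))
        out = ind.spearman_with_traits(inds, traits, n_boot=10, seed=0)
        assert np.allclose(out["rho"], 1.0)
        inds, traits = self._tables(x, -np.exp(x))
        out = ind.spearman_with_traits(inds, traits, n_boot=10, seed=0)
        assert np.allclose(out["rho"], -1.0)

    def test_ties_match_rank_then_pearson(self):
        x = np.array([1.0, 2, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        inds, traits = self._tables(x, y)
        out = ind.spearman_with_traits(inds, traits, n_boot=10, seed=0)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert out["rho"].iloc[0] == pytest.approx(expected)
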