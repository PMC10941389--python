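"""Resilience indicators from daily feed-consumption variability.

A resilient animal keeps its daily feed consumption close to its expected
growth trajectory; deviations from that trajectory carry the signal.  Per
animal the pipeline is:

1. smooth the daily series with a centred 5-day moving median (white-noise
   suppression; missing days are skipped, never imputed);
2. fit an ordinary least-squares line of the smoothed series on age and
   take residuals (removes the growth trend, so variability is not inflated
   by the animal simply eating more as it grows);
3. summarise the residual series into four scalar indicators:

   * ``lag1``    — sample lag-1 autocorrelation of residuals (persistence of
     deviations; pairs spanning a missing day are dropped);
   * ``lnvar``   — natural log of the residual sample variance;
   * ``maxarea`` — natural log of the largest trapezoidal area of a run of
     at least three consecutive negative residual days (depth x duration of
     the worst intake depression, e.g. a disease episode);
   * ``summin``  — sum of residual values at strict interior local minima
     (accumulated depth of transient dips; more negative = more dips).

Low variability reads as high resilience, so for lag1/lnvar/maxarea small
values mean resilient animals.  ``summin`` runs the other way (values are
negative sums); the class assignment nevertheless applies one common rule
to all indicators unless ``invert_summin`` is requested.

Class labels bin each indicator within breed: lowest 5% of values -> H
(high resilience), highest 5% -> L (low resilience), the central
47.5-52.5% band -> M (control).  Binning uses equal-frequency rank bins
(ntile semantics, first-occurrence order for ties) so class sizes are
deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .feedclean import DailyIntakeSeries

INDICATOR_NAMES = ["lag1", "lnvar", "maxarea", "summin"]
MIN_RUN_LENGTH = 3  # "more than two consecutive days" of negative residuals


# ---------------------------------------------------------------------------
# residual construction
# ---------------------------------------------------------------------------

def moving_median(fcd: np.ndarray, window: int = 5, min_obs: int = 3) -> np.ndarray:
    """Centred moving median over available values; NaN-aware.

    The smoothed value is defined only at observed positions whose window
    contains at least ``min_obs`` observed values.  ``window`` must be odd
    and >= 3.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    fcd = np.asarray(fcd, dtype=float)
    half = window // 2
    out = np.full_like(fcd, np.nan)
    for i in range(len(fcd)):
        if np.isnan(fcd[i]):
            continue  # gaps stay gaps
        win = fcd[max(0, i - half): i + half + 1]
        vals = win[~np.isnan(win)]
        if len(vals) >= min_obs:
            out[i] = np.median(vals)
    return out


def fit_linear_trend(smoothed: np.ndarray, ages: np.ndarray):
    """Per-animal OLS of the smoothed series on age.

    Returns ``(intercept, slope, predicted, residuals)``; predicted and
    residuals carry NaN wherever the smoothed value is undefined.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    ages = np.asarray(ages, dtype=float)
    obs = ~np.isnan(smoothed)
    if obs.sum() < 3:
        raise ValueError("need at least 3 smoothed points to fit a trend")
    x, y = ages[obs], smoothed[obs]
    if np.ptp(x) == 0:
        raise ValueError("all ages identical: singular design")
    slope, intercept = np.polyfit(x, y, 1)
    predicted = np.where(obs, intercept + slope * ages, np.nan)
    residuals = smoothed - predicted
    return float(intercept), float(slope), predicted, residuals


# ---------------------------------------------------------------------------
# scalar indicators on a residual series (NaN = missing day; unit-step ages)
# ---------------------------------------------------------------------------

def lag1_autocorrelation(residuals: np.ndarray) -> float:
    """Sample lag-1 autocorrelation; adjacent-day pairs only.

    r1 = sum over consecutive observed pairs of (e_t - m)(e_{t+1} - m)
    divided by the total sum of squares around the mean m of all observed
    residuals.  Raises if the residual variance is zero.
    """
    e = np.asarray(residuals, dtype=float)
    obs = ~np.isnan(e)
    vals = e[obs]
    if len(vals) < 3:
        raise ValueError("need at least 3 residuals for lag-1 autocorrelation")
    m = vals.mean()
    denom = float(((vals - m) ** 2).sum())
    if denom == 0:
        raise ValueError("zero residual variance: lag-1 autocorrelation undefined")
    pair = obs[:-1] & obs[1:]
    num = float(((e[:-1][pair] - m) * (e[1:][pair] - m)).sum())
    return num / denom


def ln_variance(residuals: np.ndarray) -> float:
    """Natural log of the sample variance (n-1 denominator) of residuals.

    Returns NaN (with a warning) for zero variance rather than -inf.
    """
    vals = np.asarray(residuals, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) < 2:
        raise ValueError("need at least 2 residuals for a variance")
    var = float(np.var(vals, ddof=1))
    if var == 0:
        warnings.warn("zero residual variance: lnvar undefined")
        return math.nan
    return math.log(var)


def negative_runs(residuals: np.ndarray, min_length: int = MIN_RUN_LENGTH):
    """Maximal runs of consecutive days with residual < 0, length >= min_length.

    A missing day terminates a run.  Returns [(start, end)] with inclusive
    end indices into the residual array.
    """
    e = np.asarray(residuals, dtype=float)
    runs, start = [], None
    for i, v in enumerate(e):
        if not np.isnan(v) and v < 0:
            if start is None:
                start = i
        else:
            if start is not None and i - start >= min_length:
                runs.append((start, i - 1))
            start = None
    if start is not None and len(e) - start >= min_length:
        runs.append((start, len(e) - 1))
    return runs


def max_negative_area(residuals: np.ndarray, min_length: int = MIN_RUN_LENGTH) -> float:
    """ln of the largest trapezoidal area among qualifying negative runs.

    The area integrates -residual over the run's days at unit spacing
    (a run of constant depth c over L days has area c*(L-1)).  NaN when no
    run of at least ``min_length`` days exists.
    """
    e = np.asarray(residuals, dtype=float)
    best = None
    for s, t in negative_runs(e, min_length):
        area = float(np.trapezoid(-e[s: t + 1]))
        best = area if best is None else max(best, area)
    if best is None or best <= 0:
        return math.nan
    return math.log(best)


def sum_local_minima(residuals: np.ndarray) -> float:
    """Sum of residual values at strict interior local minima.

    A position qualifies when both immediate (adjacent-day) neighbours are
    observed and strictly larger; endpoints and positions adjacent to a
    missing day are ineligible.  Zero when no minimum exists.
    """
    e = np.asarray(residuals, dtype=float)
    if len(e) < 3:
        raise ValueError("need at least 3 residuals")
    total = 0.0
    for i in range(1, len(e) - 1):
        trio = e[i - 1: i + 2]
        if np.any(np.isnan(trio)):
            continue
        if trio[1] < trio[0] and trio[1] < trio[2]:
            total += float(trio[1])
    return total


# ---------------------------------------------------------------------------
# per-animal pipeline
# ---------------------------------------------------------------------------

@dataclass
class ResidualSeries:
    animal_id: str
    ages: np.ndarray
    smoothed: np.ndarray
    predicted: np.ndarray
    residuals: np.ndarray


def residual_series(series: DailyIntakeSeries, window: int = 5) -> ResidualSeries:
    smoothed = moving_median(series.fcd, window=window)
    _, _, predicted, resid = fit_linear_trend(smoothed, series.ages)
    return ResidualSeries(series.animal_id, series.ages, smoothed, predicted, resid)


def compute_indicators(
    series_list: list[DailyIntakeSeries], window: int = 5
) -> pd.DataFrame:
    """Four indicators per animal; columns animal_id, breed, lag1, lnvar,
    maxarea, summin.  Undefined indicators (zero variance, no negative run)
    are NaN."""
    rows = []
    for s in series_list:
        rs = residual_series(s, window=window)
        e = rs.residuals
        try:
            lag1 = lag1_autocorrelation(e)
        except ValueError:
            lag1 = math.nan
        try:
            lnvar = ln_variance(e)
        except ValueError:
            lnvar = math.nan
        rows.append(
            {
                "animal_id": s.animal_id,
                "breed": s.breed,
                "lag1": lag1,
                "lnvar": lnvar,
                "maxarea": max_negative_area(e),
                "summin": sum_local_minima(e),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# class labels
# ---------------------------------------------------------------------------

def ntile(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency rank bins, 1..n_bins, larger bins first.

    Ties are broken by first occurrence (stable sort), so labels are
    deterministic.
    """
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    rank = np.empty(len(values), dtype=int)
    rank[order] = np.arange(len(values))  # 0-based dense rank
    return (n_bins * rank) // len(values) + 1


def assign_classes(
    indicators: pd.DataFrame,
    indicator: str,
    min_per_breed: int = 20,
    invert_summin: bool = False,
) -> pd.DataFrame:
    """Within-breed L/M/H class labels for one indicator.

    Lowest 5% of values -> H, highest 5% -> L, central 47.5-52.5% band -> M,
    everything else unassigned.  With ``invert_summin`` the H/L ends are
    swapped for the summin indicator, whose sign convention is inverted
    relative to the variability indicators.
    """
    if indicator not in indicators.columns:
        raise KeyError(indicator)
    out = []
    for breed, grp in indicators.groupby("breed", sort=True):
        grp = grp.dropna(subset=[indicator])
        if len(grp) < min_per_breed:
            raise ValueError(
                f"breed {breed} has {len(grp)} animals with {indicator}; "
                f"need >= {min_per_breed} for percentile classes"
            )
        vals = grp[indicator].to_numpy()
        bins20 = ntile(vals, 20)
        bins40 = ntile(vals, 40)
        label = np.full(len(grp), "unassigned", dtype=object)
        low_tail = bins20 == 1
        high_tail = bins20 == 20
        if invert_summin and indicator == "summin":
            label[low_tail], label[high_tail] = "L", "H"
        else:
            label[low_tail], label[high_tail] = "H", "L"
        label[np.isin(bins40, (20, 21))] = "M"
        out.append(
            pd.DataFrame(
                {
                    "animal_id": grp["animal_id"].to_numpy(),
                    "breed": breed,
                    "indicator": indicator,
                    "label": label,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# correlation with performance traits
# ---------------------------------------------------------------------------

def spearman_with_traits(
    indicators: pd.DataFrame,
    traits: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    by_breed: bool = False,
) -> pd.DataFrame:
    """Spearman rho of each indicator x trait pair with bootstrap SEs.

    ``traits`` must carry ``animal_id`` plus numeric trait columns; pairs
    are pairwise-complete, entries with < 4 complete pairs are NaN.
    Returns a long table (group, indicator, trait, rho, se, n).
    """
    merged = indicators.merge(traits, on="animal_id", how="inner")
    trait_cols = [c for c in traits.columns if c != "animal_id"]
    rng = np.random.default_rng(seed)
    groups = [("ALL", merged)]
    if by_breed:
        groups += [(b, g) for b, g in merged.groupby("breed", sort=True)]
    rows = []
    for gname, g in groups:
        for ind in INDICATOR_NAMES:
            for trait in trait_cols:
                pair = g[[ind, trait]].dropna()
                n = len(pair)
                if n < 4:
                    rows.append((gname, ind, trait, math.nan, math.nan, n))
                    continue
                rho = stats.spearmanr(pair[ind], pair[trait]).statistic
                boots = np.empty(n_boot)
                x, y = pair[ind].to_numpy(), pair[trait].to_numpy()
                for b in range(n_boot):
                    idx = rng.integers(0, n, n)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        boots[b] = stats.spearmanr(x[idx], y[idx]).statistic
                se = float(np.nanstd(boots, ddof=1))
                rows.append((gname, ind, trait, float(rho), se, n))
    return pd.DataFrame(rows, columns=["group", "indicator", "trait", "rho", "se", "n"])
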