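"""Microbiota-resilience association tests.

* ``permanova`` — distance-based permutational MANOVA with sequential
  (Type-I) partitioning, so a resilience indicator entered after room and
  breed is tested conditional on those covariates.  Continuous and
  categorical terms are both supported; p-values come from free permutation
  of the sample labels (the adonis convention).
* ``diversity_regression`` — OLS of alpha diversity on an indicator, with
  optional room/breed adjustment.
* ``ks_class_test`` — two-sample Kolmogorov-Smirnov comparisons of a
  diversity measure between resilience classes.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centred inner-product matrix G = -1/2 * J D^2 J."""
    a = -0.5 * d**2
    n = len(a)
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _design(col: pd.Series) -> np.ndarray:
    """Design columns for one model term (dummies for categoricals,
    centred column for numerics; the intercept lives in the base model)."""
    if pd.api.types.is_numeric_dtype(col):
        x = col.to_numpy(dtype=float)[:, None]
        if np.ptp(x) == 0:
            raise ValueError(f"term {col.name!r} is constant")
        return x
    dummies = pd.get_dummies(col, drop_first=True)
    return dummies.to_numpy(dtype=float)


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


@dataclass
class PermanovaResults:
    """Sequential PERMANOVA table and the inputs needed to reproduce it."""

    table: pd.DataFrame
    n_permutations: int
    seed: int | None

    def summary(self) -> str:
        lines = [
            f"PERMANOVA (sequential SS, {self.n_permutations} permutations, "
            f"seed={self.seed})",
            self.table.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


def permanova(
    dist: pd.DataFrame,
    metadata: pd.DataFrame,
    terms: list[str],
    n_perm: int = 1000,
    seed: int | None = None,
    permutations: str = "random",
) -> PermanovaResults:
    """Distance-based MANOVA with sequential sum-of-squares partitioning.

    Parameters
    ----------
    dist : square symmetric distance matrix, index aligned to ``metadata``.
    metadata : per-sample covariates; ``terms`` are entered in order, so the
        last term is conditional on the earlier ones.
    permutations : "random" (seeded sampling of ``n_perm`` label orders) or
        "exact" (all n! orders, n <= 8 only).

    Pseudo-F for each term uses the residual of the *full* model; each
    permutation relabels the samples (rows+columns of the distance matrix)
    and recomputes all statistics.
    """
    meta = metadata.loc[dist.index]
    d = dist.to_numpy(dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = len(d)
    g = _gower_center(d)
    ss_total = float(np.trace(g))

    # cumulative hat matrices: intercept, +term1, +term2, ...
    blocks = []
    x = np.ones((n, 1))
    hats = [_hat(x)]
    dfs = []
    kept_terms = []
    for t in terms:
        xt = _design(meta[t])
        x_new = np.hstack([x, xt])
        rank_gain = np.linalg.matrix_rank(x_new) - np.linalg.matrix_rank(x)
        if rank_gain == 0:
            warnings.warn(f"term {t!r} is rank-deficient given earlier terms; dropped")
            continue
        x = x_new
        hats.append(_hat(x))
        dfs.append(rank_gain)
        kept_terms.append(t)
        blocks.append(xt)
    h_full = hats[-1]
    df_res = n - int(np.linalg.matrix_rank(x))
    resid_proj = np.eye(n) - h_full
    term_proj = [hats[i + 1] - hats[i] for i in range(len(kept_terms))]

    def stats_for(gm: np.ndarray):
        ss_terms = np.array([float(np.sum(p * gm)) for p in term_proj])
        ss_res = float(np.sum(resid_proj * gm))
        f = (ss_terms / np.array(dfs)) / (ss_res / df_res)
        return ss_terms, ss_res, f

    ss_terms, ss_res, f_obs = stats_for(g)

    if permutations == "exact":
        if n > 8:
            raise ValueError("exact permutation only for n <= 8")
        orders = list(itertools.permutations(range(n)))
        count = np.zeros(len(kept_terms))
        for order in orders:
            idx = np.asarray(order)
            _, _, f_perm = stats_for(g[np.ix_(idx, idx)])
            count += f_perm >= f_obs - 1e-12
        pvals = count / len(orders)
        n_used = len(orders)
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(kept_terms))
        for _ in range(n_perm):
            idx = rng.permutation(n)
            _, _, f_perm = stats_for(g[np.ix_(idx, idx)])
            count += f_perm >= f_obs - 1e-12
        pvals = (count + 1) / (n_perm + 1)
        n_used = n_perm

    rows = []
    for i, t in enumerate(kept_terms):
        rows.append(
            {
                "term": t,
                "Df": dfs[i],
                "SumSq": ss_terms[i],
                "F": f_obs[i],
                "Pr(>F)": pvals[i],
                "VarExp": 100 * ss_terms[i] / ss_total,
            }
        )
    rows.append(
        {
            "term": "Residual",
            "Df": df_res,
            "SumSq": ss_res,
            "F": math.nan,
            "Pr(>F)": math.nan,
            "VarExp": 100 * ss_res / ss_total,
        }
    )
    rows.append(
        {
            "term": "Total",
            "Df": n - 1,
            "SumSq": ss_total,
            "F": math.nan,
            "Pr(>F)": math.nan,
            "VarExp": 100.0,
        }
    )
    table = pd.DataFrame(rows).set_index("term")
    return PermanovaResults(table=table, n_permutations=n_used, seed=seed)


# ---------------------------------------------------------------------------
# diversity ~ indicator regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    slope: float
    r: float
    p_value: float
    n: int
    adjusted_slope: float | None = None
    adjusted_p_value: float | None = None

    def summary(self) -> str:
        s = (
            f"OLS diversity ~ indicator: slope={self.slope:.4g}, R={self.r:.3f}, "
            f"p={self.p_value:.3g}, n={self.n}"
        )
        if self.adjusted_slope is not None:
            s += (
                f"; room/breed adjusted: slope={self.adjusted_slope:.4g}, "
                f"p={self.adjusted_p_value:.3g}"
            )
        return s


def diversity_regression(
    diversity: pd.Series,
    indicator: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> RegressionResult:
    """OLS of alpha diversity on a resilience indicator.

    R is the Pearson correlation of the simple model (its sign matches the
    slope); the p-value is the slope t-test.  When ``covariates`` (e.g.
    room, breed as categoricals) are given, an adjusted slope/p for the
    indicator is reported as well.
    """
    df = pd.DataFrame({"y": diversity, "x": indicator}).dropna()
    if len(df) < 5:
        raise ValueError(f"need >= 5 complete pairs, got {len(df)}")
    x = sm.add_constant(df["x"].to_numpy())
    fit = sm.OLS(df["y"].to_numpy(), x).fit()
    slope = float(fit.params[1])
    if df["y"].std() == 0:
        r, p = 0.0, 1.0
    else:
        r = float(np.corrcoef(df["x"], df["y"])[0, 1])
        p = float(fit.pvalues[1])
    adj_slope = adj_p = None
    if covariates is not None:
        cov = pd.get_dummies(covariates.loc[df.index], drop_first=True, dtype=float)
        xa = sm.add_constant(np.hstack([df[["x"]].to_numpy(), cov.to_numpy()]))
        fit_a = sm.OLS(df["y"].to_numpy(), xa).fit()
        adj_slope, adj_p = float(fit_a.params[1]), float(fit_a.pvalues[1])
    return RegressionResult(slope, r, p, len(df), adj_slope, adj_p)


# ---------------------------------------------------------------------------
# class-wise Kolmogorov-Smirnov tests
# ---------------------------------------------------------------------------

def ks_class_test(
    values: pd.Series,
    labels: pd.Series,
    pairs: tuple = (("L", "M"), ("M", "H"), ("L", "H")),
    min_per_class: int = 5,
) -> pd.DataFrame:
    """Two-sample KS test of a diversity measure between class pairs.

    Returns a table (class_a, class_b, D, p, n_a, n_b); pairs with an
    empty or undersized class are skipped with a warning.
    """
    rows = []
    for a, b in pairs:
        va = values[labels == a].dropna()
        vb = values[labels == b].dropna()
        if len(va) < min_per_class or len(vb) < min_per_class:
            warnings.warn(f"class pair ({a},{b}) skipped: too few values")
            continue
        res = stats.ks_2samp(va, vb, method="asymp")
        rows.append((a, b, float(res.statistic), float(res.pvalue), len(va), len(vb)))
    return pd.DataFrame(rows, columns=["class_a", "class_b", "D", "p", "n_a", "n_b"])
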