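"""ASV count tables: filtering, CLR transform, distances, diversity, kernel.

Counts are held as a pandas DataFrame with samples (= animal ids) on the
rows and ASVs on the columns.  The analysis chain mirrors common
compositional practice: drop shallow samples (total count < 700), drop
rare ASVs (present in < 5% of samples), replace zeros with a small
constant pseudo-count, centre log-ratio (CLR) transform, and derive from
the CLR matrix both the Aitchison (Euclidean-on-CLR) distance used by
PERMANOVA and the microbial similarity kernel used by the variance
component model.  Alpha diversity (Shannon, inverse Simpson) is computed
on the *unfiltered* counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy

MIN_DEPTH = 700
MIN_PREVALENCE = 0.05
CONST_FACTOR = 0.65  # zero replacement: 0.65 x smallest nonzero count


@dataclass
class CLRMatrix:
    """CLR-transformed table plus the zero-imputation constant used."""

    values: pd.DataFrame
    imputation_const: float


@dataclass
class MicrobialKernel:
    """Inner-product similarity K = X X' / p of the column-standardised CLR
    matrix (p = number of ASVs); symmetric PSD with mean diagonal ~ 1."""

    K: pd.DataFrame
    n_features: int


def read_counts(path) -> pd.DataFrame:
    """TSV with sample ids in the first column, ASVs as remaining columns."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    if (table.to_numpy() < 0).any():
        raise ValueError("negative counts in ASV table")
    return table


def filter_samples_by_depth(table: pd.DataFrame, min_total: int = MIN_DEPTH) -> pd.DataFrame:
    """Drop samples whose total count is strictly below ``min_total``."""
    keep = table.sum(axis=1) >= min_total
    if not keep.any():
        raise ValueError(f"no sample reaches total count {min_total}")
    return table.loc[keep]


def filter_asvs_by_prevalence(
    table: pd.DataFrame, min_prev: float = MIN_PREVALENCE
) -> pd.DataFrame:
    """Drop ASVs present (count > 0) in strictly fewer than ``min_prev`` of
    the retained samples."""
    prev = (table > 0).mean(axis=0)
    return table.loc[:, prev >= min_prev]


def clr_transform(table: pd.DataFrame, const: float | None = None) -> CLRMatrix:
    """Centred log-ratio transform with constant zero replacement.

    Zeros are replaced by ``const`` (default 0.65 x the smallest nonzero
    count of the whole table); each row x then maps to ln(x) - mean(ln(x)),
    so rows sum to zero.
    """
    x = table.to_numpy(dtype=float)
    zero_rows = np.where(x.sum(axis=1) == 0)[0]
    if len(zero_rows):
        raise ValueError(
            f"sample(s) with all-zero counts: {list(table.index[zero_rows])}"
        )
    if const is None:
        const = CONST_FACTOR * x[x > 0].min()
    x = np.where(x == 0, const, x)
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return CLRMatrix(
        values=pd.DataFrame(clr, index=table.index, columns=table.columns),
        imputation_const=float(const),
    )


def aitchison_distance(clr: CLRMatrix) -> pd.DataFrame:
    """Pairwise Euclidean distance between CLR rows (Aitchison distance)."""
    d = squareform(pdist(clr.values.to_numpy(), metric="euclidean"))
    return pd.DataFrame(d, index=clr.values.index, columns=clr.values.index)


def alpha_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Shannon entropy (nats) and inverse Simpson per sample, on raw counts.

    Zero-total samples get NaN.
    """
    x = table.to_numpy(dtype=float)
    totals = x.sum(axis=1)
    shannon = np.full(len(x), np.nan)
    inv_simpson = np.full(len(x), np.nan)
    ok = totals > 0
    p = x[ok] / totals[ok, None]
    shannon[ok] = entropy(p, axis=1)
    inv_simpson[ok] = 1.0 / (p**2).sum(axis=1)
    return pd.DataFrame(
        {"shannon": shannon, "inv_simpson": inv_simpson}, index=table.index
    )


def remove_diversity_outliers(values: pd.Series) -> tuple[pd.Series, list]:
    """Tukey-fence outlier removal: drop values strictly beyond
    Q1 - 1.5*IQR or Q3 + 1.5*IQR (fences from the input, single pass)."""
    vals = values.dropna()
    if len(vals) < 4:
        raise ValueError("need at least 4 values for fence-based outlier removal")
    q1, q3 = np.percentile(vals, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = vals[(vals < lo) | (vals > hi)]
    return values.drop(index=outliers.index), list(outliers.index)


def build_kernel(clr: CLRMatrix) -> MicrobialKernel:
    """Microbial similarity kernel from the filtered CLR matrix.

    Columns are standardised to mean 0, sd 1 (zero-variance columns dropped
    with a warning), then K = X X' / p, which is symmetric PSD with a mean
    diagonal of about one — the same scaling convention as a genomic
    relationship matrix.
    """
    x = clr.values.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance CLR columns")
        x = x[:, keep]
        sd = sd[keep]
    x = (x - x.mean(axis=0)) / sd
    p = x.shape[1]
    K = x @ x.T / p
    return MicrobialKernel(
        K=pd.DataFrame(K, index=clr.values.index, columns=clr.values.index),
        n_features=p,
    )


def prepare_microbiome(
    counts: pd.DataFrame,
    min_depth: int = MIN_DEPTH,
    min_prev: float = MIN_PREVALENCE,
    const: float | None = None,
) -> dict:
    """Standard chain: depth filter -> prevalence filter -> CLR -> distance,
    kernel; plus alpha diversity on the unfiltered table.

    Returns a dict with keys filtered_counts, clr, distance, kernel,
    diversity, n_samples_removed, n_asvs_removed.
    """
    deep = filter_samples_by_depth(counts, min_depth)
    filtered = filter_asvs_by_prevalence(deep, min_prev)
    clr = clr_transform(filtered, const=const)
    return {
        "filtered_counts": filtered,
        "clr": clr,
        "distance": aitchison_distance(clr),
        "kernel": build_kernel(clr),
        "diversity": alpha_diversity(counts),
        "n_samples_removed": len(counts) - len(deep),
        "n_asvs_removed": counts.shape[1] - filtered.shape[1],
    }
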