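"""Heterogeneity scores, diversity indices and the normality classifier.

Per tumour/marker, four measures summarize how unevenly positivity is
distributed over the grid squares: the sample s.d., the MAX-μ score
(maximum minus mean, an outlier highlighter), and — after binning values
into at most 20 data categories — the Shannon index H = −Σ p ln p and the
inverse Simpson index D = 1/Σ p².  A sample is classified heterogeneous
when the D'Agostino–Pearson omnibus test rejects normality of its square
values (p < 0.05).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grids import MarkerGrid

__all__ = [
    "HeterogeneityReport",
    "sd_score",
    "max_mu_score",
    "bin_values",
    "binning_for_range",
    "shannon_index",
    "inverse_simpson_index",
    "dagostino_pearson",
    "subgroup_compare",
    "score_grid",
]

ALPHA = 0.05

#: binning schemes: full-range markers use 5% bins over 0-100 (20 categories);
#: restricted-range markers use 2% bins over a 40% span to keep s = 20
FULL_RANGE_BINNING = (100.0, 5.0)
RESTRICTED_RANGE_BINNING = (40.0, 2.0)


@dataclass
class HeterogeneityReport:
    """Per tumour/marker heterogeneity summary."""

    marker: str
    n_squares: int
    mean: float
    sd: float
    max_mu: float
    shannon: float
    inv_simpson: float
    n_categories_s: int
    k2: float
    p_norm: float
    heterogeneous: bool


def _clean(values) -> np.ndarray:
    v = np.asarray(values, dtype=float).ravel()
    return v[np.isfinite(v)]


def sd_score(values) -> float:
    """Sample standard deviation (n−1 denominator) of square positivities."""
    v = _clean(values)
    if len(v) < 2:
        raise ValueError("sd_score needs at least 2 values")
    return float(np.std(v, ddof=1))


def max_mu_score(values) -> float:
    """MAX-μ: maximum minus mean square positivity; highlights outlier squares.

    The mean is taken over all analysed squares (not only positive ones).
    """
    v = _clean(values)
    if len(v) == 0:
        raise ValueError("max_mu_score needs at least 1 value")
    return float(v.max() - v.mean())


def binning_for_range(value_range_max: float) -> tuple[float, float]:
    """(range_max, bin_width) giving s = 20 categories for a marker's range."""
    return FULL_RANGE_BINNING if value_range_max > 25 else RESTRICTED_RANGE_BINNING


def bin_values(values, range_max: float = 100.0, bin_width: float = 5.0) -> np.ndarray:
    """Count values into half-open bins [k·w, (k+1)·w), last bin closed.

    The number of defined bins is ceil(range_max / bin_width) — 20 for the
    default 5% bins over 0–100%.  Out-of-range values are assigned to the
    nearest end bin with a warning.
    """
    if bin_width <= 0 or range_max <= 0:
        raise ValueError("range_max and bin_width must be positive")
    v = _clean(values)
    n_bins = math.ceil(range_max / bin_width)
    if ((v < 0) | (v > range_max)).any():
        warnings.warn("values outside [0, range_max] assigned to end bins", stacklevel=2)
        v = np.clip(v, 0.0, range_max)
    edges = np.arange(n_bins + 1) * bin_width
    edges[-1] = max(edges[-1], range_max)
    counts, _ = np.histogram(v, bins=edges)
    return counts


def shannon_index(counts) -> float:
    """Shannon diversity H = −Σ p_i ln p_i over occupied data categories (nats)."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("shannon_index needs a non-empty sample")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def inverse_simpson_index(counts, bias_corrected: bool = False) -> float:
    """Inverse Simpson diversity D = 1/Σ p_i² (effective number of categories).

    With ``bias_corrected`` the small-sample form
    1 / [Σ n_i(n_i−1) / (N(N−1))] is used instead.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("inverse_simpson_index needs a non-empty sample")
    if bias_corrected:
        if total < 2:
            raise ValueError("bias-corrected form needs N >= 2")
        denom = (c * (c - 1)).sum() / (total * (total - 1))
        if denom == 0:
            return float("inf")
        return float(1.0 / denom)
    p = c[c > 0] / total  # empty categories contribute nothing (exactly)
    return float(1.0 / (p**2).sum())


def dagostino_pearson(
    values, alpha: float = ALPHA, min_n: int = 8
) -> tuple[float, float, bool]:
    """D'Agostino–Pearson omnibus normality test as heterogeneity classifier.

    Combines the skewness and kurtosis normalizing transforms into
    K² = Z(√b1)² + Z(b2)², referred to a χ²(2) upper tail.  A sample that
    rejects normality (p < alpha) is classified heterogeneous.  The test is
    unreliable below n ≈ 20; ``min_n`` is a hard floor.

    Returns (k2, p, heterogeneous).
    """
    v = _clean(values)
    if len(v) < min_n:
        raise ValueError(f"normality test needs n >= {min_n}, got n = {len(v)}")
    if np.ptp(v) == 0:
        raise ValueError("zero-variance sample: normality test undefined")
    k2, p = stats.normaltest(v)
    return float(k2), float(p), bool(p < alpha)


def subgroup_compare(values, labels) -> tuple[float, float]:
    """Compare a per-tumour summary score between prognostic subgroups.

    Kruskal–Wallis for three or more groups, two-sided Mann–Whitney U for
    two.  Returns (statistic, p).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in np.unique(labels)]
    groups = [g[np.isfinite(g)] for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 tumours each")
    if len(groups) == 2:
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
    else:
        res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def score_grid(
    grid: MarkerGrid,
    range_max: float | None = None,
    bin_width: float | None = None,
    alpha: float = ALPHA,
) -> HeterogeneityReport:
    """Compute the full heterogeneity report for one marker grid.

    The binning scheme defaults to 5% bins over 0–100% for full-range
    markers (HIF-type PNC) and 2% bins over a 40% span otherwise, both
    giving s = 20 categories.
    """
    v = grid.analysed_values()
    if range_max is None or bin_width is None:
        full = grid.mode == "PNC" and grid.marker in ("HIF1A", "HIF2A", "synthetic")
        range_max, bin_width = FULL_RANGE_BINNING if full else RESTRICTED_RANGE_BINNING
    counts = bin_values(v, range_max=range_max, bin_width=bin_width)
    k2, p, het = dagostino_pearson(v, alpha=alpha)
    return HeterogeneityReport(
        marker=grid.marker,
        n_squares=len(v),
        mean=float(v.mean()),
        sd=sd_score(v),
        max_mu=max_mu_score(v),
        shannon=shannon_index(counts),
        inv_simpson=inverse_simpson_index(counts),
        n_categories_s=len(counts),
        k2=k2,
        p_norm=p,
        heterogeneous=het,
    )
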