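"""Binned normal-approximation test for distribution shape.

The procedure draws a reference sample of the same size from
Normal(mean(x), sd(x)), partitions the reference range into k equal-width
bins (the outer breaks widened to ±inf so every observation falls in some
bin), counts both samples into the bins, and then applies a Pearson
chi-square test of independence to the *paired bin counts*: the k
(observed, reference) count pairs are cross-tabulated by distinct count
value into an r×c contingency table.

This paired-count statistic measures association between the two count
patterns, not goodness of fit in the conventional sense; notably, whenever
all reference counts are distinct it collapses to the structural identity
statistic = k·(r−1), df = (r−1)·(k−1) regardless of the actual data.  A
conventional goodness-of-fit test against the fitted normal is provided as
an opt-in alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BinSummary",
    "ChiSqResult",
    "make_reference_bins",
    "paired_count_chisq",
    "norm_approx_test",
    "classic_gof_test",
]


@dataclass(frozen=True)
class BinSummary:
    """Paired observed/reference bin counts over a shared partition."""

    k: int
    breaks: np.ndarray  # k+1 ascending, breaks[0] = -inf, breaks[k] = +inf
    obs_counts: np.ndarray
    ref_counts: np.ndarray

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least 2 partitions")
        if len(self.breaks) != self.k + 1:
            raise ValueError("breaks must have length k+1")
        if int(self.obs_counts.sum()) != int(self.ref_counts.sum()):
            raise ValueError("observed and reference totals differ")


@dataclass(frozen=True)
class ChiSqResult:
    """A chi-square statistic with its degrees of freedom and p-value."""

    statistic: float
    df: int
    p: float


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[np.isfinite(x)]


def make_reference_bins(x, k: int, seed: int, equal_quantile: bool = False) -> BinSummary:
    """Bin data and a matched normal reference sample into k partitions.

    A reference sample of length len(x) is drawn from
    Normal(mean(x), sd(x)) with the given seed.  The k partitions are
    equal-width over [min(ref), max(ref)] by default (``equal_quantile``
    switches to equal-probability breaks of the reference sample); the
    first break is then replaced by −inf and the last by +inf so both
    samples are fully counted.  Binning is half-open: [break_i, break_{i+1}).
    """
    x = _clean(x)
    if k < 2:
        raise ValueError("need at least 2 partitions")
    if len(x) < k:
        raise ValueError(f"need at least k={k} finite values, got {len(x)}")
    mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("sd(x) is zero; distribution shape is degenerate")
    rng = np.random.default_rng(seed)
    ref = rng.normal(mu, sd, size=len(x))
    if equal_quantile:
        breaks = np.quantile(ref, np.linspace(0.0, 1.0, k + 1))
    else:
        breaks = np.linspace(ref.min(), ref.max(), k + 1)
    breaks = breaks.astype(float)
    breaks[0] = -np.inf
    breaks[-1] = np.inf
    obs = np.histogram(x, bins=breaks)[0]
    refc = np.histogram(ref, bins=breaks)[0]
    # np.histogram closes the last bin on the right; with an infinite upper
    # break that matches the half-open convention for every finite value.
    return BinSummary(k=k, breaks=breaks, obs_counts=obs, ref_counts=refc)


def paired_count_chisq(u, v) -> ChiSqResult:
    """Pearson chi-square of independence on cross-tabulated count pairs.

    The k pairs (u_i, v_i) are tabulated by distinct value into an r×c
    contingency table (r = #distinct u values, c = #distinct v values);
    the statistic is Σ(O−E)²/E with expectations from the margins, df =
    (r−1)(c−1), no continuity correction.  If either vector is constant
    the table is degenerate: statistic 0, df 0, p 1, with a warning.
    """
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("u and v must be 1-D vectors of equal length")
    uu, ui = np.unique(u, return_inverse=True)
    vv, vi = np.unique(v, return_inverse=True)
    r, c = len(uu), len(vv)
    if r == 1 or c == 1:
        warnings.warn("degenerate paired-count table (a constant vector)", stacklevel=2)
        return ChiSqResult(statistic=0.0, df=0, p=1.0)
    table = np.zeros((r, c), dtype=int)
    np.add.at(table, (ui, vi), 1)
    res = stats.chi2_contingency(table, correction=False)
    return ChiSqResult(statistic=float(res.statistic), df=int(res.dof), p=float(res.pvalue))


def norm_approx_test(x, k: int, seed: int, equal_quantile: bool = False) -> ChiSqResult:
    """Normal-approximation shape test: reference binning + paired-count chi-square.

    The null hypothesis is that the data are well-approximated by a normal
    distribution, so a small p-value indicates deviance.
    """
    bins = make_reference_bins(x, k, seed, equal_quantile=equal_quantile)
    return paired_count_chisq(bins.obs_counts, bins.ref_counts)


def classic_gof_test(x, k: int) -> ChiSqResult:
    """Conventional chi-square goodness of fit against the fitted normal.

    Expected counts come from the Normal(mean(x), sd(x)) CDF over k
    equal-width bins spanning the data range (outer breaks at ±inf);
    df = k − 1 − 2 for the two estimated parameters.  Warns when any
    expected count drops below 1.
    """
    x = _clean(x)
    if k < 2:
        raise ValueError("need at least 2 partitions")
    if len(x) < k:
        raise ValueError(f"need at least k={k} finite values, got {len(x)}")
    mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("sd(x) is zero; distribution shape is degenerate")
    breaks = np.linspace(x.min(), x.max(), k + 1)
    breaks[0], breaks[-1] = -np.inf, np.inf
    obs = np.histogram(x, bins=breaks)[0]
    cdf = stats.norm.cdf(breaks, loc=mu, scale=sd)
    expected = len(x) * np.diff(cdf)
    if (expected < 1).any():
        warnings.warn("expected count below 1 in some bins", stacklevel=2)
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = k - 3
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else float("nan")
    return ChiSqResult(statistic=statistic, df=df, p=p)
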