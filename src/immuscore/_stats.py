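"""Shared rank-test and multiplicity helpers.

Group comparisons throughout the package use the two-sided Wilcoxon
rank-sum (Mann-Whitney) test with the normal approximation, tie
correction and continuity correction; an exact-enumeration mode is
available for very small samples. Multiplicity control is
Benjamini-Hochberg.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["wilcoxon_rank_sum", "bh_adjust", "significance_stars"]


def wilcoxon_rank_sum(x, y, method: str = "asymptotic") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Parameters
    ----------
    x, y : array-like
        Observations of the two groups.
    method : {"asymptotic", "exact"}
        "asymptotic" uses the normal approximation with tie and
        continuity corrections (the package default); "exact" enumerates
        the permutation distribution (no ties allowed by scipy's exact
        path, small n only).

    Returns
    -------
    (W, p) : Mann-Whitney U statistic of ``x`` and two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if method not in ("asymptotic", "exact"):
        raise ValueError(f"unknown method {method!r}")
    res = stats.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method=method,
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs propagate)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def significance_stars(p: float) -> str:
    """Star annotation at the 0.05 / 0.01 / 0.001 / 0.0001 levels."""
    if np.isnan(p):
        return ""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
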