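"""Nonparametric test wrappers and multiple-testing utilities.

Thin, deterministic wrappers over :mod:`scipy.stats` and
:mod:`statsmodels` that fix the small-sample conventions used throughout the
pipeline:

* Mann–Whitney U — exact enumeration when both groups have at most
  ``MW_EXACT_MAX`` observations and the pooled sample is tie-free; otherwise
  the normal approximation with tie and continuity corrections.
* Wilcoxon signed-rank — zero differences dropped first; exact null
  distribution when the remaining sample is small and tie-free, normal
  approximation with correction otherwise.
* Benjamini–Hochberg step-up adjustment via statsmodels.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

MW_EXACT_MAX = 8
WILCOXON_EXACT_MAX = 25


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def mann_whitney_u(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann–Whitney U statistic (for ``x``) and p-value.

    Exact when both groups have ≤ 8 observations and no ties occur in the
    pooled sample; otherwise asymptotic with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    exact = (
        max(len(x), len(y)) <= MW_EXACT_MAX
        and not _has_ties(pooled)
    )
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(diff, alternative: str = "greater") -> tuple[float, float, int]:
    """One-sample Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking (the classical convention).
    Returns ``(W, p, n_zero_dropped)`` where W is the signed-rank statistic
    reported by scipy.  All-zero input returns ``(0, 1, n)``.
    """
    diff = np.asarray(diff, dtype=float)
    nonzero = diff[diff != 0.0]
    n_zero = int(len(diff) - len(nonzero))
    if len(nonzero) == 0:
        return 0.0, 1.0, n_zero
    exact = len(nonzero) <= WILCOXON_EXACT_MAX and not _has_ties(np.abs(nonzero))
    res = stats.wilcoxon(
        nonzero,
        alternative=alternative,
        zero_method="wilcox",
        correction=not exact,
        method="exact" if exact else "approx",
    )
    return float(res.statistic), float(res.pvalue), n_zero


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def p_to_stars(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001."""
    if p is None or np.isnan(p):
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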