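"""Independent brute-force oracles used to verify the pipeline.

These deliberately avoid the library code paths they check: exhaustive
all-pairs minima, full enumeration of rank-test null distributions, and the
literal step-up definition of the Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata


def brute_nearest_distances(points: np.ndarray, references: np.ndarray) -> np.ndarray:
    """Exhaustive O(n·m) minimum Euclidean distance to any reference."""
    out = np.empty(len(points))
    for i, p in enumerate(points):
        out[i] = np.sqrt(((references - p) ** 2).sum(axis=1)).min()
    return out


def mann_whitney_enum(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Exact Mann–Whitney U by enumerating all group assignments."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = rankdata(pooled)

    def u_of(idx):
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2.0

    u_obs = u_of(range(n1))
    us = np.array([u_of(c) for c in itertools.combinations(range(n), n1)])
    ge = np.mean(us >= u_obs)
    le = np.mean(us <= u_obs)
    if alternative == "greater":
        p = ge
    elif alternative == "less":
        p = le
    else:
        p = min(1.0, 2.0 * min(ge, le))
    return float(u_obs), float(p)


def wilcoxon_enum(diff, alternative: str = "greater") -> tuple[float, float]:
    """Exact signed-rank test by enumerating all 2^n sign assignments.

    Zero differences are dropped first (matching the classical convention);
    |differences| are average-ranked, and W+ (sum of positive ranks) is the
    statistic.
    """
    d = np.asarray(diff, float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.empty(2**n)
    for k, signs in enumerate(itertools.product([0, 1], repeat=n)):
        ws[k] = ranks[np.array(signs, dtype=bool)].sum()
    ge = np.mean(ws >= w_obs)
    le = np.mean(ws <= w_obs)
    if alternative == "greater":
        p = ge
    elif alternative == "less":
        p = le
    else:
        p = min(1.0, 2.0 * min(ge, le))
    return float(w_obs), float(p)


def bh_stepup(pvalues) -> np.ndarray:
    """Literal Benjamini–Hochberg step-up: q_(i) = min_{j>=i} m·p_(j)/j, capped at 1."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
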