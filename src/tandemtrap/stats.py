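"""Inferential tests with explicit small-sample contracts.

The rank-sum statistic is the Mann-Whitney count
``W = sum_ij 1[x_i > y_j] + 0.5 * 1[x_i == y_j]``; for small samples
(n1 + n2 <= 20) its exact null distribution is computed by the standard
counting recursion, so the reported p is an exact permutation p rather
than a normal approximation.  Larger samples (or ties) fall back to the
normal approximation with continuity and tie corrections.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache

import numpy as np
from scipy import stats as sps


@dataclasses.dataclass
class TestResult:
    __test__ = False  # not a pytest class, despite the name

    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("sample sizes must be positive")


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Number of arrangements giving each Mann-Whitney U in 0..n1*n2.

    Counting recursion: f(n1, n2, u) = f(n1-1, n2, u-n2) + f(n1, n2-1, u).
    """
    if n1 == 0 or n2 == 0:
        return (1,) + (0,) * (n1 * n2)
    counts = np.zeros(n1 * n2 + 1, dtype=object)
    prev_a = np.array(_u_counts(n1 - 1, n2), dtype=object)  # length (n1-1)*n2+1
    prev_b = np.array(_u_counts(n1, n2 - 1), dtype=object)  # length n1*(n2-1)+1
    counts[n2 : n2 + prev_a.size] += prev_a
    counts[: prev_b.size] += prev_b
    return tuple(int(c) for c in counts)


def _exact_rank_sum_p(w: float, n1: int, n2: int) -> float:
    counts = np.array(_u_counts(n1, n2), dtype=float)
    total = counts.sum()
    u = np.arange(counts.size)
    lower = counts[u <= w].sum() / total
    upper = counts[u >= w].sum() / total
    return float(min(1.0, 2.0 * min(lower, upper)))


def rank_sum(x, y, exact: bool | None = None, permutation_ties: bool = False) -> TestResult:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    ``W`` counts pairs with x > y (ties count one half).  ``exact=None``
    picks the exact enumeration when n1 + n2 <= 20 and there are no ties,
    else the normal approximation with continuity correction.  Exact mode
    refuses tied data unless ``permutation_ties`` is set, in which case
    the exact p is computed by permuting the observed pooled values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    diff = x[:, None] - y[None, :]
    w = float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))
    has_ties = np.unique(np.concatenate([x, y])).size < n1 + n2
    if exact is None:
        exact = (n1 + n2 <= 20) and not has_ties
    if exact:
        if has_ties and not permutation_ties:
            raise ValueError(
                "exact rank-sum requires untied data; pass permutation_ties=True "
                "to use an exact permutation p over the observed values"
            )
        if has_ties:
            from itertools import combinations
            from math import comb

            if comb(n1 + n2, n1) > 200_000:
                raise ValueError("tied exact permutation test infeasible at this size")
            pooled = np.concatenate([x, y])
            idx = np.arange(n1 + n2)
            ws = []
            for pick in combinations(idx, n1):
                xi = pooled[list(pick)]
                yi = np.delete(pooled, list(pick))
                d = xi[:, None] - yi[None, :]
                ws.append(np.sum(d > 0) + 0.5 * np.sum(d == 0))
            ws = np.asarray(ws, dtype=float)
            p = min(1.0, 2.0 * min(np.mean(ws <= w), np.mean(ws >= w)))
            return TestResult(w, float(p), "rank_sum exact (permutation, ties)", n1, n2)
        return TestResult(w, _exact_rank_sum_p(w, n1, n2), "rank_sum exact", n1, n2)
    # normal approximation with continuity correction and tie correction
    mu = n1 * n2 / 2.0
    n = n1 + n2
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var == 0:
        raise ValueError("degenerate samples: zero rank variance")
    z = (w - mu - 0.5 * np.sign(w - mu)) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult(w, p, "rank_sum normal approx", n1, n2)


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (D = sup ECDF gap, asymptotic p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(x, y, method="asymp")
    return TestResult(float(res.statistic), float(res.pvalue), "ks_two_sample asymptotic", x.size, y.size)


def paired_t(a, b) -> TestResult:
    """Two-sided paired t test on differences a - b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.all(d == d[0]):
        raise ValueError("zero-variance differences: paired t undefined")
    res = sps.ttest_rel(a, b)
    return TestResult(float(res.statistic), float(res.pvalue), "paired_t", a.size, a.size)


__all__ = ["TestResult", "rank_sum", "ks_two_sample", "paired_t"]
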