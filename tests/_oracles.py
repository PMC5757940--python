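"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive expected values by the dumbest correct route
(full dynamic programming, exhaustive enumeration) so they stay
independent of the implementation paths they check.
"""

from __future__ import annotations

import itertools
import math


def gotoh_full_score(
    x: str, y: str,
    match: int = 1, mismatch: int = -1,
    gap_open: int = -5, gap_extend: int = -1,
) -> int:
    """Unbanded affine-gap global alignment score, O(nm), three matrices.

    Gap cost convention: a length-k gap scores gap_open + k*gap_extend.
    """
    n, m = len(x), len(y)
    NEG = -(10 ** 9)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in y (consumes x)
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in x (consumes y)
    M[0][0] = 0
    for j in range(1, n + 1):
        X[0][j] = gap_open + gap_extend * j
    for i in range(1, m + 1):
        Y[i][0] = gap_open + gap_extend * i
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if x[j - 1] == y[i - 1] else mismatch
            best_prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            if best_prev > NEG // 2:
                M[i][j] = best_prev + s
            opn = max(M[i][j - 1], Y[i][j - 1])
            X[i][j] = max(
                opn + gap_open + gap_extend if opn > NEG // 2 else NEG,
                X[i][j - 1] + gap_extend if X[i][j - 1] > NEG // 2 else NEG,
            )
            opn = max(M[i - 1][j], X[i - 1][j])
            Y[i][j] = max(
                opn + gap_open + gap_extend if opn > NEG // 2 else NEG,
                Y[i - 1][j] + gap_extend if Y[i - 1][j] > NEG // 2 else NEG,
            )
    return max(M[m][n], X[m][n], Y[m][n])


def fisher_enum_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct enumeration of all tables with the
    observed margins (probability-mass rule with R's tie tolerance)."""
    r1, c1, n = a + b, a + c, a + b + c + d

    def log_comb(n_: int, k_: int) -> float:
        return (
            math.lgamma(n_ + 1) - math.lgamma(k_ + 1) - math.lgamma(n_ - k_ + 1)
        )

    def pmf(k: int) -> float:
        return math.exp(
            log_comb(r1, k) + log_comb(n - r1, c1 - k) - log_comb(n, c1)
        )

    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    p_obs = pmf(a)
    total = sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-7))
    return min(1.0, total)


def poisson_binomial_enum(p: list[float]) -> list[float]:
    """PMF of a Poisson-binomial by exhaustive 2^m subset enumeration
    (only sane for m <= ~15)."""
    m = len(p)
    pmf = [0.0] * (m + 1)
    for bits in itertools.product([0, 1], repeat=m):
        prob = 1.0
        for i, b in enumerate(bits):
            prob *= p[i] if b else 1 - p[i]
        pmf[sum(bits)] += prob
    return pmf


def wilcoxon_exact_p(x: list[float], y: list[float]) -> float:
    """Two-sided exact Mann–Whitney p by enumerating all group-label
    assignments of the pooled (tie-free) values."""
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    nx = len(x)

    def u_of(subset: tuple[int, ...]) -> int:
        xs = [pooled[i] for i in subset]
        return sum(1 for xv in xs for yv in pooled if yv not in xs and xv > yv)

    u_obs = sum(1 for xv in x for yv in y if xv > yv)
    us = [
        u_of(s) for s in itertools.combinations(range(len(pooled)), nx)
    ]
    n_total = len(us)
    mean_u = nx * (len(y)) / 2
    extreme = sum(1 for u in us if abs(u - mean_u) >= abs(u_obs - mean_u))
    return extreme / n_total
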