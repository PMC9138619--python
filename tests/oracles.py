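"""Independent brute-force oracles used only by the tests.

Exact rational arithmetic throughout — these never call the code paths
they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def poisson_pair_pvalue_oracle(x: int, y: int, n1: int, n2: int) -> float:
    """Two-library two-sided p by exact finite summation.

    Conditional on t = x + y, Y ~ Binomial(t, n2/(n1+n2)); both inclusive
    tails are summed as exact rationals over y' in [0, t] and the smaller
    one doubled.
    """
    t = x + y
    den = (n1 + n2) ** t
    pmf = [comb(t, j) * n2**j * n1 ** (t - j) for j in range(t + 1)]
    lower = sum(pmf[: y + 1])
    upper = sum(pmf[y:])
    p = Fraction(2 * min(lower, upper), den)
    return float(min(p, Fraction(1)))


def binom_tail_table(t: int, n1: int, n2: int) -> list[Fraction]:
    """Exact inclusive lower-tail CDF of Binomial(t, n2/(n1+n2))."""
    den = (n1 + n2) ** t
    acc = 0
    out = []
    for j in range(t + 1):
        acc += comb(t, j) * n2**j * n1 ** (t - j)
        out.append(Fraction(acc, den))
    return out


def hypergeom_upper_tail_oracle(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by exhaustive enumeration."""
    total = comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += comb(K, j) * comb(N - K, n - j)
    return Fraction(acc, total)


def pearson_one_tailed_oracle(x, y) -> tuple[float, float]:
    """Pearson r and one-tailed (r > 0) p via the t transform, from scratch.

    t = r * sqrt(df / (1 - r^2)) with df = n - 2; p = P(T_df > t).
    """
    import numpy as np
    from scipy.stats import t as tdist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    r = float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
    df = len(x) - 2
    tstat = r * np.sqrt(df / (1.0 - r**2))
    return r, float(tdist.sf(tstat, df))
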