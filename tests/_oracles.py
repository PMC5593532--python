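"""Independent brute-force oracles used to check the statistical kernels.

These deliberately avoid the code paths (and where possible the library
calls) used by the implementation: the t CDF is computed by numerical
integration of the density, the hypergeometric tail by exact rational
enumeration, local alignment by an exhaustive Smith-Waterman restricted to
ungapped (diagonal) moves, and the ceRNA intersection by a triple loop.
"""

from __future__ import annotations

import math
from fractions import Fraction

from scipy.integrate import quad


def t_density(x: float, df: int) -> float:
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    return c * (1 + x * x / df) ** (-(df + 1) / 2)


def t_two_sided_p(t: float, df: int) -> float:
    """2 * P(T > |t|) by adaptive quadrature of the density."""
    tail, _ = quad(t_density, abs(t), math.inf, args=(df,))
    return 2.0 * tail


def paired_t_p(case, control) -> float:
    n = len(case)
    d = [c - k for c, k in zip(case, control)]
    dbar = sum(d) / n
    s2 = sum((x - dbar) ** 2 for x in d) / (n - 1)
    if s2 == 0:
        return 1.0 if dbar == 0 else 0.0
    t = dbar / math.sqrt(s2 / n)
    return t_two_sided_p(t, n - 1)


def correlation_p(r: float, n: int) -> float:
    if abs(r) == 1:
        return 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return t_two_sided_p(t, n - 2)


def pooled_t_p(case, control) -> float:
    n1, n2 = len(case), len(control)
    m1, m2 = sum(case) / n1, sum(control) / n2
    s2 = (sum((x - m1) ** 2 for x in case) + sum((x - m2) ** 2 for x in control)) / (
        n1 + n2 - 2
    )
    if s2 == 0:
        return 1.0 if m1 == m2 else 0.0
    t = (m1 - m2) / math.sqrt(s2 * (1 / n1 + 1 / n2))
    return t_two_sided_p(t, n1 + n2 - 2)


def hypergeom_tail_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) as an exact rational number."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), math.comb(N, n))
    return total


def ungapped_smith_waterman(a: str, b: str, match: int = 1, mismatch: int = -3) -> int:
    """Best local segment score over all diagonals, no gaps allowed."""
    best = 0
    for diag in range(-(len(b) - 1), len(a)):
        run = 0
        i = max(0, diag)
        j = i - diag
        while i < len(a) and j < len(b):
            run = max(0, run + (match if a[i] == b[j] else mismatch))
            best = max(best, run)
            i += 1
            j += 1
    return best


def cerna_triple_loop(lncs, mirs, mrnas, edge_sign, targets):
    """Exhaustive check of the five ceRNA conditions over all triples.

    ``edge_sign`` maps frozenset({a, b}) -> "+" or "-" for retained edges;
    ``targets`` is a set of (mirna, target) pairs.
    """
    out = set()
    for l in lncs:
        for m in mirs:
            for g in mrnas:
                if (
                    edge_sign.get(frozenset((m, g))) == "-"
                    and (m, g) in targets
                    and edge_sign.get(frozenset((m, l))) == "-"
                    and (m, l) in targets
                    and edge_sign.get(frozenset((l, g))) == "+"
                ):
                    out.add((l, m, g))
    return out
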