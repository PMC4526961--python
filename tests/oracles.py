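"""Brute-force enumeration oracles, independent of the package's code paths.

Each oracle recomputes a two-sided p-value from first principles: exact
rational hypergeometric sums (Fisher), pair-counting U over every group
allocation (Mann-Whitney), and explicit sign-pattern enumeration over
hand-computed midranks (signed-rank).
"""

from fractions import Fraction
from itertools import combinations, product
from math import comb


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Sum of exact hypergeometric probabilities <= that of the observed table."""
    N, K, n1 = a + b + c + d, a + b, a + c

    def prob(k: int) -> Fraction:
        return Fraction(comb(K, k) * comb(N - K, n1 - k), comb(N, n1))

    p_obs = prob(a)
    lo, hi = max(0, n1 - (N - K)), min(K, n1)
    return float(sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs))


def _pair_count_u(xs, ys) -> float:
    """U of xs vs ys by direct pair counting (ties count half)."""
    u = 0.0
    for xi in xs:
        for yi in ys:
            u += 1.0 if xi > yi else (0.5 if xi == yi else 0.0)
    return u


def mann_whitney_oracle(x, y) -> float:
    """Exact permutation p over all C(m+n, m) allocations (pair-counting U)."""
    pooled = list(x) + list(y)
    m, N = len(x), len(x) + len(y)
    mu = m * (N - m) / 2.0
    u_obs = _pair_count_u(x, y)
    count = total = 0
    for idx in combinations(range(N), m):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(N) if i not in chosen]
        total += 1
        if abs(_pair_count_u(xs, ys) - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total


def _midranks(values) -> list[float]:
    """Midranks computed by explicit position averaging over a sort."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    j = 0
    while j < len(order):
        k = j
        while k < len(order) and values[order[k]] == values[order[j]]:
            k += 1
        r = (j + 1 + k) / 2.0  # mean of positions j+1 .. k
        for t in range(j, k):
            ranks[order[t]] = r
        j = k
    return ranks


def signed_rank_oracle(diffs) -> float:
    """Exact p over all 2^n sign patterns of the midranks of |d| (zeros dropped)."""
    d = [v for v in diffs if v != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = _midranks([abs(v) for v in d])
    w_obs = sum(r for r, v in zip(ranks, d) if v > 0)
    mu = sum(ranks) / 2.0
    count = total = 0
    for signs in product((0, 1), repeat=n):
        total += 1
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total
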