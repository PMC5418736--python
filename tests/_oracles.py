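"""Independent brute-force oracles used to pin expected values in tests.

Everything here is deliberately naive: exact rational arithmetic, full
enumeration, sort-based ranking. None of it shares code with the package.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


def hypergeom_tail_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), as an exact rational."""
    total = comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            acc += comb(K, i) * comb(N - K, n - i)
    return Fraction(acc, total)


def hypergeom_tail_suffix(K: int, n: int, N: int) -> list[Fraction]:
    """Tail probabilities P(X >= k) for every k in 0..n (suffix sums)."""
    total = comb(N, n)
    pmf_num = [
        comb(K, i) * comb(N - K, n - i) if (i <= K and n - i <= N - K) else 0
        for i in range(n + 1)
    ]
    out = [Fraction(0)] * (n + 1)
    acc = 0
    for i in range(n, -1, -1):
        acc += pmf_num[i]
        out[i] = Fraction(acc, total)
    return out


def mannwhitney_exact_two_sided(a: list[float], b: list[float]) -> float:
    """Two-sided p by full enumeration of group labelings (no ties assumed)."""
    pooled = sorted(a + b)
    na = len(a)

    def u_stat(group_a: tuple[float, ...]) -> float:
        gb = list(pooled)
        for x in group_a:
            gb.remove(x)
        return sum(1 for x in group_a for y in gb if x > y)

    observed = u_stat(tuple(a))
    n_total = 0
    n_extreme = 0
    mean_u = na * (len(b)) / 2
    for combo in itertools.combinations(pooled, na):
        u = u_stat(combo)
        n_total += 1
        if abs(u - mean_u) >= abs(observed - mean_u):
            n_extreme += 1
    return n_extreme / n_total


def spearman_exact(x: list[float], y: list[float]) -> float:
    """Spearman rho via explicit average ranks and Pearson on ranks."""

    def avg_ranks(v: list[float]) -> list[float]:
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    n = len(x)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


def local_clustering(adj: dict[str, set[str]], node: str) -> float:
    """Triangle-count local clustering coefficient; 0 for degree < 2."""
    nbrs = sorted(adj.get(node, set()))
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(
        1
        for i in range(k)
        for j in range(i + 1, k)
        if nbrs[j] in adj.get(nbrs[i], set())
    )
    return 2 * links / (k * (k - 1))
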