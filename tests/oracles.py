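"""Independent brute-force oracles used by unit and acceptance tests.

Every function here is deliberately naive (loops, enumeration,
quadrature) and shares no code with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def pearson_two_pass(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook two-pass Pearson correlation."""
    mx, my = sum(x) / len(x), sum(y) / len(y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def tom_brute_force(adj: np.ndarray) -> np.ndarray:
    """O(n^3) direct-summation TOM with explicit triple loops."""
    n = adj.shape[0]
    out = np.eye(n)
    for i in range(n):
        k_i = sum(adj[i, u] for u in range(n) if u != i)
        for j in range(n):
            if i == j:
                continue
            k_j = sum(adj[j, u] for u in range(n) if u != j)
            l_ij = sum(adj[i, u] * adj[u, j] for u in range(n) if u not in (i, j))
            denom = min(k_i, k_j) + 1.0 - adj[i, j]
            out[i, j] = (l_ij + adj[i, j]) / denom if denom > 0 else 0.0
    return out


def average_linkage_naive(d: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Naive O(n^3) average-linkage agglomeration on a dissimilarity matrix.

    Returns the merge sequence as (cluster_a, cluster_b, height) with
    clusters given as frozensets of leaf indices.
    """
    clusters = [frozenset([i]) for i in range(d.shape[0])]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or dist < best[0]:
                    best = (dist, a, b)
        dist, a, b = best
        merges.append((clusters[a], clusters[b], dist))
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges


def cophenetic_naive(d: np.ndarray) -> np.ndarray:
    """Cophenetic distance matrix from the naive agglomeration."""
    n = d.shape[0]
    out = np.zeros((n, n))
    for ca, cb, h in average_linkage_naive(d):
        for i in ca:
            for j in cb:
                out[i, j] = out[j, i] = h
    return out


def pc1_eigendecomposition(x: np.ndarray) -> np.ndarray:
    """First PC of row-standardized data via the explicit sample covariance.

    ``x`` is genes x samples; returns a length-n_samples profile.
    """
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    z = (x - mu) / sd
    # samples x samples covariance of the gene-standardized data
    cov = z.T @ z
    vals, vecs = np.linalg.eigh(cov)
    return vecs[:, int(np.argmax(vals))]


def hypergeom_upper_tail(k: int, n_universe: int, n_list: int, n_draw: int) -> float:
    """P(X >= k) by direct pmf summation with exact integer combinatorics."""
    total = math.comb(n_universe, n_draw)
    acc = 0
    for j in range(k, min(n_list, n_draw) + 1):
        if n_draw - j > n_universe - n_list:
            continue
        acc += math.comb(n_list, j) * math.comb(n_universe - n_list, n_draw - j)
    return acc / total


def fisher_exact_enumerate(table: list[list[int]], alternative: str = "two-sided") -> float:
    """Fisher's exact p by enumerating all 2x2 tables with fixed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x: int) -> float:
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if alternative == "greater":
        return sum(prob(x) for x in range(a, hi + 1))
    if alternative == "less":
        return sum(prob(x) for x in range(lo, a + 1))
    return sum(p for x in range(lo, hi + 1) if (p := prob(x)) <= p_obs * (1 + 1e-9))


def t_pvalue_quadrature(r: float, n: int) -> float:
    """Two-sided correlation p via numerical quadrature of the explicit
    Student-t density (gamma-function form), independent of any
    distribution-function routine."""
    from scipy.integrate import quad

    nu = n - 2
    t = abs(r) * math.sqrt(nu) / math.sqrt(1.0 - r * r)
    const = math.exp(
        math.lgamma((nu + 1) / 2) - math.lgamma(nu / 2)
    ) / math.sqrt(nu * math.pi)

    def density(x: float) -> float:
        return const * (1.0 + x * x / nu) ** (-(nu + 1) / 2)

    tail, _ = quad(density, t, np.inf)
    return 2.0 * tail
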