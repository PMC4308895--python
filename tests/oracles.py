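"""Independent literal-definition implementations used as test oracles.

Everything here is written directly from the mathematical definition
(loops, enumeration, exact rational arithmetic) and shares no code with
the package implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, sqrt

import numpy as np


def cv_two_pass(values) -> float:
    """CV by explicit two-pass mean/SD loops (n-1 denominator)."""
    n = len(values)
    mean = sum(values) / n
    ss = sum((v - mean) ** 2 for v in values)
    return sqrt(ss / (n - 1)) / mean


def bh_step_up(pvals) -> list[float]:
    """Benjamini-Hochberg step-up from the definition, in input order."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [0.0] * n
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvals[i] * n / rank)
        q[i] = running_min
    return q


def auc_pairwise(scores, labels) -> float:
    """AUC as pairwise concordance enumeration, ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def hypergeom_tail_exact(k: int, n_universe: int, n_set: int, n_query: int
                         ) -> Fraction:
    """P(X >= k) as an exact rational tail sum of binomial coefficients."""
    if k <= 0:
        return Fraction(1)
    denom = comb(n_universe, n_query)
    total = Fraction(0)
    for i in range(k, min(n_set, n_query) + 1):
        total += Fraction(comb(n_set, i) * comb(n_universe - n_set, n_query - i),
                          denom)
    return total


def common_top_k_scan(genes_a: list[str], genes_b: list[str], k: int
                      ) -> tuple[set[str], int]:
    """Exhaustive scan over all depths for the smallest d with >= k common."""
    for d in range(1, max(len(genes_a), len(genes_b)) + 1):
        common = set(genes_a[:d]) & set(genes_b[:d])
        if len(common) >= k:
            return common, d
    raise ValueError("k unreachable")


def prune_low_degree(edges: set[tuple[str, str]], nodes: set[str],
                     min_degree: int) -> tuple[set[str], set[tuple[str, str]]]:
    """Iterated literal low-degree pruning of an edge set to a fixpoint."""
    nodes = set(nodes)
    edges = {tuple(sorted(e)) for e in edges
             if e[0] in nodes and e[1] in nodes and e[0] != e[1]}
    while True:
        degree = {n: 0 for n in nodes}
        for u, v in edges:
            degree[u] += 1
            degree[v] += 1
        low = {n for n in nodes if degree[n] < min_degree}
        if not low:
            return nodes, edges
        nodes -= low
        edges = {(u, v) for u, v in edges if u in nodes and v in nodes}


def welch_t(a, b) -> tuple[float, float]:
    """Welch t statistic and degrees of freedom from the textbook formula."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    return t, df


def f_cdf_via_beta(f: float, d1: int, d2: int) -> float:
    """F-distribution CDF through the regularized incomplete beta function."""
    from scipy.special import betainc
    return float(betainc(d1 / 2, d2 / 2, d1 * f / (d1 * f + d2)))
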