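"""Hypergeometric overlap and gene-set enrichment tests.

Over-representation is tested with the upper-tail hypergeometric
probability P(X >= k) for an observed overlap of k genes between a query
and a set drawn from a finite universe. The tail is accumulated in log
space, so p-values far below double underflow of individual terms are still
computed accurately (overlaps of a few dozen genes out of lists of hundreds
routinely reach p < 1e-16).
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .errors import ValidationError
from .differential import bh_adjust
from .io import GeneSetCollection

__all__ = ["hypergeometric_overlap", "geneset_enrichment"]


def _check_subset(name: str, s: frozenset[str], universe: frozenset[str]) -> None:
    extra = s - universe
    if extra:
        raise ValidationError(
            f"{name} contains {len(extra)} ids outside the universe, "
            f"e.g. {sorted(extra)[:5]}")


def hypergeometric_upper_tail(k: int, n_universe: int, n_set: int, n_query: int
                              ) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space."""
    if k <= 0:
        return 1.0
    upper = min(n_set, n_query)
    if k > upper:
        return 0.0
    support = np.arange(k, upper + 1)
    log_terms = hypergeom.logpmf(support, n_universe, n_set, n_query)
    return float(np.exp(logsumexp(log_terms)))


def hypergeometric_overlap(set_a: Iterable[str], set_b: Iterable[str],
                           universe: Iterable[str]) -> tuple[int, float]:
    """Overlap size and upper-tail hypergeometric p for two gene sets.

    Both sets must be subsets of the universe; the p-value is the
    probability of observing at least the realized overlap when ``set_b``
    is drawn uniformly at random from the universe.
    """
    universe = frozenset(universe)
    set_a = frozenset(set_a)
    set_b = frozenset(set_b)
    if not universe:
        raise ValidationError("universe must be non-empty")
    _check_subset("set A", set_a, universe)
    _check_subset("set B", set_b, universe)
    k = len(set_a & set_b)
    p = hypergeometric_upper_tail(k, len(universe), len(set_a), len(set_b))
    return k, p


def geneset_enrichment(query: Iterable[str], collection: GeneSetCollection,
                       universe: Iterable[str], min_overlap: int = 3,
                       fdr: float = 0.05) -> pd.DataFrame:
    """Over-representation of a query gene list in each set of a collection.

    Sets are clipped to the universe before testing; only sets overlapping
    the query in at least ``min_overlap`` genes are tested and enter the BH
    universe. Returns one row per tested set, ordered by p then set name.
    """
    universe = frozenset(universe)
    query = frozenset(query)
    if not query:
        raise ValidationError("query gene set is empty")
    _check_subset("query", query, universe)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe
        if not members:
            continue
        k = len(members & query)
        if k < min_overlap:
            continue
        p = hypergeometric_upper_tail(k, len(universe), len(members), len(query))
        rows.append({
            "set_name": name, "overlap": k, "set_size": len(members),
            "query_size": len(query), "universe_size": len(universe), "p": p,
        })
    result = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size",
                                         "query_size", "universe_size", "p"])
    if not result.empty:
        result["q"] = bh_adjust(result["p"].to_numpy())
        result["significant"] = result["q"] < fdr
        result = result.sort_values(["p", "set_name"]).reset_index(drop=True)
    else:
        result["q"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result.set_index("set_name")
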