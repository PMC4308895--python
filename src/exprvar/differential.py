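"""Gene-wise differential variability and differential expression.

Differential variability between two sample groups is assessed three ways
per gene — the CV difference (CV_A - CV_B), the EV difference (EV_A -
EV_B), and a variance-ratio F-test — and a gene is called concordantly more
variable in one group only when all three measures agree in direction.
P-values are Benjamini-Hochberg adjusted over the testable genes.

Differential expression is a per-gene Welch two-sample t-test on the log2
values with the conventional call rule: BH-adjusted p < 0.05 and absolute
log2 fold change (M value) strictly greater than 1.

Top-list construction orders concordant DV genes by |CV difference| and by
|EV difference|; ``common_top_k`` expands both ranked lists in lockstep to
the smallest depth at which their intersection reaches k genes — the
procedure used to build a cross-dataset consensus list.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import validate_sample_groups
from .variability import group_variability_tables

__all__ = [
    "RankedGeneList",
    "f_test_two_sided",
    "bh_adjust",
    "differential_variability",
    "differential_expression",
    "select_dv_genes",
    "combine_ranked_lists",
    "common_top_k",
]

logger = logging.getLogger(__name__)


@dataclass
class RankedGeneList:
    """Genes in a deterministic order under a named ranking key.

    Ordering is by the key (descending) with ties broken lexicographically
    on gene id, so identical inputs always yield identical lists.
    """

    genes: list[str]
    key_name: str
    key_values: np.ndarray

    def __len__(self) -> int:
        return len(self.genes)

    def top(self, d: int) -> list[str]:
        return self.genes[:d]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.genes, self.key_name: self.key_values}
                            ).set_index("gene_id")


def _ranked(table: pd.DataFrame, key: str, key_name: str) -> RankedGeneList:
    order = table.sort_values([key, "gene_id"], ascending=[False, True],
                              key=None)
    return RankedGeneList(genes=order["gene_id"].tolist(), key_name=key_name,
                          key_values=order[key].to_numpy())


def f_test_two_sided(x, y) -> tuple[float, float]:
    """Variance-ratio F-test; returns (F, two-sided p).

    F = var(x)/var(y) on (len(x)-1, len(y)-1) degrees of freedom; the
    two-sided p doubles the smaller tail, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValidationError("F-test needs >= 3 values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 or vy == 0:
        raise ValidationError("F-test undefined for zero within-group variance")
    f = vx / vy
    dist = scipy.stats.f(x.size - 1, y.size - 1)
    p = 2 * min(dist.cdf(f), dist.sf(f))
    return float(f), float(min(p, 1.0))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _f_test_vectorized(va: np.ndarray, vb: np.ndarray, dfa: int, dfb: int
                       ) -> tuple[np.ndarray, np.ndarray]:
    f = va / vb
    cdf = scipy.stats.f.cdf(f, dfa, dfb)
    sf = scipy.stats.f.sf(f, dfa, dfb)
    p = np.minimum(2 * np.minimum(cdf, sf), 1.0)
    return f, p


def differential_variability(m: pd.DataFrame, groups: pd.Series,
                             method: str = "gamma_glm_poly", degree: int = 3,
                             window: int = 101, pooled_trend: bool = False
                             ) -> pd.DataFrame:
    """Per-gene differential-variability table between groups A and B.

    Columns: per-group cv/ev, cv_diff = CV_A - CV_B, ev_diff = EV_A - EV_B,
    f_stat = var_A/var_B, two-sided p, BH q (over testable genes only), the
    two mutually exclusive concordance flags, and a testable flag. Genes
    with zero variance in either group are untestable; they are excluded
    from the FDR universe and counted in a log message.
    """
    label_a, label_b = validate_sample_groups(groups, m, min_per_group=3)
    tabs = group_variability_tables(m, groups, method=method, degree=degree,
                                    window=window, pooled_trend=pooled_trend)
    ta, tb = tabs[label_a], tabs[label_b]
    na = int(ta["n"].iloc[0])
    nb = int(tb["n"].iloc[0])
    va = ta["var"].to_numpy()
    vb = tb["var"].to_numpy()
    testable = (va > 0) & (vb > 0)
    n_untestable = int((~testable).sum())
    if testable.sum() == 0:
        raise ValidationError("no testable gene (zero variance everywhere)")
    if n_untestable:
        logger.info("excluded %d zero-variance genes from the F-test universe",
                    n_untestable)

    f = np.full(m.shape[0], np.nan)
    p = np.full(m.shape[0], np.nan)
    f[testable], p[testable] = _f_test_vectorized(va[testable], vb[testable],
                                                  na - 1, nb - 1)
    q = np.full(m.shape[0], np.nan)
    q[testable] = bh_adjust(p[testable])

    cv_diff = ta["cv"].to_numpy() - tb["cv"].to_numpy()
    ev_diff = ta["ev"].to_numpy() - tb["ev"].to_numpy()
    up_in_b = testable & (cv_diff < 0) & (ev_diff < 0) & (f < 1)
    up_in_a = testable & (cv_diff > 0) & (ev_diff > 0) & (f > 1)

    return pd.DataFrame({
        f"cv_{label_a}": ta["cv"], f"cv_{label_b}": tb["cv"].to_numpy(),
        f"ev_{label_a}": ta["ev"], f"ev_{label_b}": tb["ev"].to_numpy(),
        "cv_diff": cv_diff, "ev_diff": ev_diff,
        "f_stat": f, "p": p, "q": q,
        "concordant_up_in_B": up_in_b, "concordant_up_in_A": up_in_a,
        "testable": testable,
    }, index=m.index)


def differential_expression(m: pd.DataFrame, groups: pd.Series,
                            fdr: float = 0.05, m_cutoff: float = 1.0
                            ) -> pd.DataFrame:
    """Welch t-test differential expression with the q<fdr and |M|>cutoff rule.

    M = mean_B - mean_A (log2 fold change of group B over group A). Genes
    constant in both groups are untestable and excluded from the FDR
    universe.
    """
    label_a, label_b = validate_sample_groups(groups, m)
    cols_a = groups.index[groups == label_a]
    cols_b = groups.index[groups == label_b]
    a = m[cols_a].to_numpy()
    b = m[cols_b].to_numpy()
    m_value = b.mean(axis=1) - a.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    testable = (va > 0) | (vb > 0)

    t = np.full(m.shape[0], np.nan)
    p = np.full(m.shape[0], np.nan)
    if testable.any():
        res = scipy.stats.ttest_ind(b[testable], a[testable], axis=1,
                                    equal_var=False)
        t[testable] = res.statistic
        p[testable] = res.pvalue
    q = np.full(m.shape[0], np.nan)
    if testable.any():
        q[testable] = bh_adjust(p[testable])
    significant = testable & (q < fdr) & (np.abs(m_value) > m_cutoff)

    return pd.DataFrame({
        "m_value": m_value, "t_stat": t, "p": p, "q": q,
        "significant": significant, "testable": testable,
    }, index=m.index)


def select_dv_genes(table: pd.DataFrame, fdr: float = 0.05,
                    direction: str = "B", apply_fdr: bool = True
                    ) -> tuple[RankedGeneList, RankedGeneList]:
    """Concordant DV genes for one direction, ranked by |ΔCV| and by |ΔEV|.

    ``direction`` "B" selects genes concordantly more variable in group B
    (cv_diff < 0, ev_diff < 0, F < 1), "A" the opposite. With ``apply_fdr``
    false the q < fdr cutoff is skipped (useful when few genes reach
    significance but a fixed-length list is wanted). Returns the CV-ordered
    and EV-ordered lists; ties break on gene id.
    """
    if table.empty:
        raise ValidationError("differential-variability table is empty")
    if direction not in ("A", "B"):
        raise ValidationError("direction must be 'A' or 'B'")
    mask = table[f"concordant_up_in_{direction}"]
    if apply_fdr:
        mask = mask & (table["q"] < fdr)
    sel = table.loc[mask, ["cv_diff", "ev_diff"]].copy()
    if sel.empty:
        logger.warning("no gene passed the concordance%s filter",
                       " + FDR" if apply_fdr else "")
    sel["abs_cv_diff"] = sel["cv_diff"].abs()
    sel["abs_ev_diff"] = sel["ev_diff"].abs()
    sel["gene_id"] = sel.index.astype(str)
    sel = sel.reset_index(drop=True)
    return (_ranked(sel, "abs_cv_diff", "abs_cv_diff"),
            _ranked(sel, "abs_ev_diff", "abs_ev_diff"))


def combine_ranked_lists(list_cv: RankedGeneList, list_ev: RankedGeneList
                         ) -> RankedGeneList:
    """Merge the CV- and EV-ordered lists by mean rank (ties on gene id).

    Genes present in only one list get that list's length + 1 as the missing
    rank. Lower mean rank is better; key_values hold the negated mean rank
    so larger is better, consistent with the other lists.
    """
    ranks_cv = {g: i + 1 for i, g in enumerate(list_cv.genes)}
    ranks_ev = {g: i + 1 for i, g in enumerate(list_ev.genes)}
    genes = sorted(set(ranks_cv) | set(ranks_ev))
    mean_rank = {
        g: (ranks_cv.get(g, len(list_cv) + 1) + ranks_ev.get(g, len(list_ev) + 1)) / 2
        for g in genes
    }
    ordered = sorted(genes, key=lambda g: (mean_rank[g], g))
    return RankedGeneList(genes=ordered, key_name="neg_mean_rank",
                          key_values=np.array([-mean_rank[g] for g in ordered]))


def common_top_k(list_a: RankedGeneList, list_b: RankedGeneList, k: int
                 ) -> tuple[set[str], int]:
    """Smallest depth d with |top-d(A) ∩ top-d(B)| >= k; returns (set, d).

    Both lists are expanded in lockstep one rank at a time. The returned
    intersection may exceed k when the final step adds several common genes
    at once; it is reported as-is together with d.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    max_common = len(set(list_a.genes) & set(list_b.genes))
    if max_common < k:
        raise ValidationError(
            f"lists share only {max_common} genes; cannot reach k={k}")
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    common: set[str] = set()
    depth = 0
    max_depth = max(len(list_a), len(list_b))
    while depth < max_depth:
        if depth < len(list_a):
            g = list_a.genes[depth]
            seen_a.add(g)
            if g in seen_b:
                common.add(g)
        if depth < len(list_b):
            g = list_b.genes[depth]
            seen_b.add(g)
            if g in seen_a:
                common.add(g)
        depth += 1
        if len(common) >= k:
            return common, depth
    raise ValidationError(  # pragma: no cover - guarded by max_common check
        f"exhausted lists with only {len(common)} common genes; cannot reach k={k}")
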