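#!/usr/bin/env python
"""Differential variability in both cohorts, top lists, and their overlap.

For each cohort: gene-wise F-tests with BH FDR plus the three-measure
concordance rule (ΔCV, ΔEV, F all pointing the same way), then CV-ranked
top lists of genes more variable in group U. The smaller cohort skips the
FDR cutoff (it is underpowered) to reach a comparable list length, as one
does when a validation cohort yields too few significant genes. The two
lists are expanded in lockstep to 100 common genes and the overlap of the
fixed-length top lists is tested hypergeometrically against the shared
universe. Writes results/diffvar_summary.tsv and results/toplist_common.tsv.

Run after 01_simulate.py:  python analysis/03_differential_variability.py
"""

from pathlib import Path

import pandas as pd

from exprvar.differential import (combine_ranked_lists, common_top_k,
                                  differential_variability, select_dv_genes)
from exprvar.enrichment import hypergeometric_overlap
from exprvar.io import read_expression_matrix, read_sample_groups

TOP = 300     # fixed-length list (top-500 analogue, scaled to the universe)
K_COMMON = 100

indir = Path("scratch/analysis")
results = Path("results")
results.mkdir(exist_ok=True)

truth = pd.read_csv(indir / "truth.tsv", sep="\t", index_col=0)
lists, rows = {}, []
for cohort, apply_fdr in (("cohort1", True), ("cohort2", False)):
    m = read_expression_matrix(indir / f"{cohort}_matrix.tsv")
    groups = read_sample_groups(indir / f"{cohort}_groups.tsv")
    table = differential_variability(m, groups)
    n_up_u = int((table["concordant_up_in_B"] & (table["q"] < 0.05)).sum())
    n_up_m = int((table["concordant_up_in_A"] & (table["q"] < 0.05)).sum())
    list_cv, list_ev = select_dv_genes(table, direction="B", apply_fdr=apply_fdr)
    lists[cohort] = combine_ranked_lists(list_cv, list_ev)
    rows.append({"cohort": cohort, "n_testable": int(table["testable"].sum()),
                 "n_sig_up_in_U": n_up_u, "n_sig_up_in_M": n_up_m,
                 "fdr_cutoff_applied": apply_fdr,
                 "list_length": len(lists[cohort])})
    print(f"{cohort}: {n_up_u} genes significantly more variable in U, "
          f"{n_up_m} in M (q<0.05, concordant); "
          f"ranked list of {len(lists[cohort])} genes"
          f"{'' if apply_fdr else ' (no FDR cutoff)'}")

pd.DataFrame(rows).to_csv(results / "diffvar_summary.tsv", sep="\t", index=False)

common, depth = common_top_k(lists["cohort1"], lists["cohort2"], K_COMMON)
n_true = sum(truth.loc[g, "is_dv"] for g in common)
print(f"lockstep expansion reaches {len(common)} common genes at depth {depth}; "
      f"{n_true} of them are true DV genes")

universe = truth.index
top1 = set(lists["cohort1"].top(TOP))
top2 = set(lists["cohort2"].top(TOP))
k, p = hypergeometric_overlap(top1, top2, universe)
print(f"top-{TOP} lists overlap in {k} genes out of a {len(universe)}-gene "
      f"universe (hypergeometric p = {p:.3g})")

out = pd.DataFrame({"gene_id": sorted(common)})
out["is_true_dv"] = out["gene_id"].map(truth["is_dv"]).astype(bool)
out.to_csv(results / "toplist_common.tsv", sep="\t", index=False)
with open(results / "toplist_overlap.tsv", "w") as fh:
    fh.write("top_k\toverlap\tuniverse\tp\n")
    fh.write(f"{TOP}\t{k}\t{len(universe)}\t{p:.6g}\n")
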