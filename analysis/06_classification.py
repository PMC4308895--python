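#!/usr/bin/env python
"""Cross-cohort subtype classification with expression vs variability features.

Trains random forests on cohort 1 and evaluates them on cohort 2, and
summarizes AUC (mean/median/min/max/SD) over repeated runs. Two settings:

1. the cohorts from 01_simulate.py, which carry both mean-shift (DE) and
   variance-inflation (DV) signal — here every informative feature set
   saturates, since a 1.5 log2 mean shift in 5% of genes is easy;
2. a DV-only regeneration (same seed, no DE genes), the regime that
   matters when the subtypes barely differ in mean expression — here the
   median-distance transform of the top DV genes carries the signal and
   random-gene baselines fall behind.

Writes results/classifier_aucs.tsv and results/classifier_aucs_dv_only.tsv.

Run after 01_simulate.py:  python analysis/06_classification.py
"""

import dataclasses
from pathlib import Path

import pandas as pd

from exprvar.classify import FeatureSpec, build_feature_spec, cross_cohort_classify
from exprvar.differential import differential_expression, differential_variability
from exprvar.io import read_expression_matrix, read_sample_groups
from exprvar.simulate import SyntheticSpec, generate_cohorts

K = 100          # top-list length, scaled with the 3,000-gene universe
N_TREES = 200
N_REPEATS = 25
SEED = 1

indir = Path("scratch/analysis")
results = Path("results")
results.mkdir(exist_ok=True)


def summarize(configs, train, train_groups, test, test_groups, out_name):
    rows = []
    for name, spec in configs:
        summary = cross_cohort_classify(train, train_groups, test, test_groups,
                                        spec, n_trees=N_TREES,
                                        n_repeats=N_REPEATS, seed=SEED)
        rows.append({"classifier": name, "mean": summary.mean,
                     "median": summary.median, "min": summary.min,
                     "max": summary.max, "sd": summary.sd,
                     "n_repeats": summary.n_repeats})
        print(f"  {name}: mean AUC {summary.mean:.4f} "
              f"(median {summary.median:.4f}, sd {summary.sd:.4f})")
    pd.DataFrame(rows).to_csv(results / out_name, sep="\t", index=False)


print("cohorts with DE + DV signal (from 01_simulate.py):")
train = read_expression_matrix(indir / "cohort1_matrix.tsv")
train_groups = read_sample_groups(indir / "cohort1_groups.tsv")
test = read_expression_matrix(indir / "cohort2_matrix.tsv")
test_groups = read_sample_groups(indir / "cohort2_groups.tsv")
shared = train.index.intersection(test.index)

de = differential_expression(train, train_groups)
dv = differential_variability(train, train_groups)
build = lambda kind, source: build_feature_spec(
    kind, source, k=None if source == "all_shared" else K, shared_genes=shared,
    de_table=de, dv_table=dv, seed=SEED)
summarize([
    ("all genes (expression)", build("expression", "all_shared")),
    (f"top {K} DE (expression)", build("expression", "top_de")),
    (f"{K} random (expression)", build("expression", "random")),
    (f"top {K} DV by CV (median distance)", build("median_distance", "top_dv_cv")),
    (f"top {K} DV by EV (median distance)", build("median_distance", "top_dv_ev")),
    (f"{K} random (median distance)", build("median_distance", "random")),
], train, train_groups, test, test_groups, "classifier_aucs.tsv")

print("  note: random median-distance features score far below 0.5 here —\n"
      "  for mean-shifted (DE) genes the within-cohort median sits inside the\n"
      "  majority class, which is M in cohort 1 but U in cohort 2, so the\n"
      "  learned distance rule inverts on transfer; DV genes are immune\n"
      "  because their groups share the same mean.")

print("\nDV-only regime (no mean shifts; variability is the only signal):")
spec = dataclasses.replace(SyntheticSpec(), n_genes=3000, frac_de=0.0, seed=SEED)
m1, g1, m2, g2, truth = generate_cohorts(spec)
shared2 = m1.index.intersection(m2.index)
dv_genes = tuple(sorted(truth.dv_genes))
rand500 = build_feature_spec("expression", "random", k=500,
                             shared_genes=shared2, seed=SEED)
summarize([
    ("true DV genes (median distance)",
     FeatureSpec(kind="median_distance", genes=dv_genes)),
    ("true DV genes (expression)",
     FeatureSpec(kind="expression", genes=dv_genes)),
    ("500 random (median distance)",
     FeatureSpec(kind="median_distance", genes=rand500.genes)),
    ("500 random (expression)",
     FeatureSpec(kind="expression", genes=rand500.genes)),
], m1, g1, m2, g2, "classifier_aucs_dv_only.tsv")

print("\nAUC summaries written to results/classifier_aucs*.tsv")
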