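#!/usr/bin/env python
"""Generate the paired synthetic cohorts every later analysis step reads.

Two two-group expression cohorts (70+52 and 24+36 samples) over a shared
gene universe, with 5% of genes variance-inflated 3-fold in group U and a
disjoint 5% mean-shifted by 1.5 log2 units, plus an additive platform
effect in cohort 2. Matrices and ground truth go under scratch/analysis/
(they are inputs to scripts 02-06, not results).

Run from the repository root:  python analysis/01_simulate.py [--seed 1]
"""

import argparse
import dataclasses
from pathlib import Path

from exprvar.io import write_expression_matrix, write_sample_groups
from exprvar.simulate import SyntheticSpec, generate_cohorts, write_truth

N_GENES = 3000  # scaled-down shared universe; structure is scale-free

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

outdir = Path("scratch/analysis")
outdir.mkdir(parents=True, exist_ok=True)

spec = dataclasses.replace(SyntheticSpec(), n_genes=N_GENES, seed=args.seed)
m1, g1, m2, g2, truth = generate_cohorts(spec)

write_expression_matrix(m1, outdir / "cohort1_matrix.tsv")
write_sample_groups(g1, outdir / "cohort1_groups.tsv")
write_expression_matrix(m2, outdir / "cohort2_matrix.tsv")
write_sample_groups(g2, outdir / "cohort2_groups.tsv")
write_truth(truth, outdir / "truth.tsv")

print(f"cohort 1: {m1.shape[0]} genes x {m1.shape[1]} samples "
      f"({(g1 == 'M').sum()} M / {(g1 == 'U').sum()} U)")
print(f"cohort 2: {m2.shape[0]} genes x {m2.shape[1]} samples "
      f"({(g2 == 'M').sum()} M / {(g2 == 'U').sum()} U)")
print(f"truth: {len(truth.dv_genes)} DV genes (lambda={spec.lambda_dv}), "
      f"{len(truth.de_genes)} DE genes (delta={spec.delta_de}); "
      f"written to {outdir}/")
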