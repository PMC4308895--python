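#!/usr/bin/env python
"""Gene-set enrichment of the consensus DV list.

Builds a small synthetic GMT collection against the simulated universe —
one pathway deliberately seeded with true DV genes, several random
pathways — and tests the cross-cohort common DV list for over-
representation (hypergeometric upper tail, sets clipped to the universe,
minimum overlap 3, BH across sets). The DV-seeded pathway should be the
only significant hit. Writes results/enrichment.tsv.

Run after 03_differential_variability.py:  python analysis/04_enrichment.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from exprvar.enrichment import geneset_enrichment
from exprvar.io import GeneSetCollection

indir = Path("scratch/analysis")
results = Path("results")
results.mkdir(exist_ok=True)

truth = pd.read_csv(indir / "truth.tsv", sep="\t", index_col=0)
universe = list(truth.index)
dv_genes = list(truth.index[truth["is_dv"]])
query = pd.read_csv(results / "toplist_common.tsv", sep="\t")["gene_id"].tolist()

rng = np.random.default_rng(1)
sets = {"dv_seeded_pathway": frozenset(
    list(rng.choice(dv_genes, size=60, replace=False))
    + list(rng.choice(universe, size=40, replace=False)))}
for j in range(8):
    sets[f"random_pathway_{j}"] = frozenset(
        rng.choice(universe, size=int(rng.integers(40, 120)), replace=False))
collection = GeneSetCollection(sets=sets)

table = geneset_enrichment(query, collection, universe, min_overlap=3)
table.to_csv(results / "enrichment.tsv", sep="\t")
print(table[["overlap", "set_size", "p", "q", "significant"]].to_string())
hits = table.index[table["significant"]].tolist()
print(f"significant at q<0.05: {hits} "
      f"(query of {len(query)} genes, universe of {len(universe)})")
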