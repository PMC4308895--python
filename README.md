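# exprvar — differential gene-expression-variability analysis

Two clinically distinct subtypes of a disease can be almost
indistinguishable in *mean* gene expression and still differ sharply in how
widely expression scatters across patients. The motivating case is chronic
lymphocytic leukemia (CLL): the aggressive IgVH-unmutated subtype (U-CLL)
shows higher across-patient expression variability than the indolent
mutated subtype (M-CLL), and that variability — not the expression level —
separates the subtypes. `exprvar` implements the full analysis pipeline
for this question, for anyone with a two-group log2 expression matrix:

* per-group variability statistics — the coefficient of variation
  CV_g = s_g / x̄_g and the expression variability EV_g = s²_g / v̂(x̄_g),
  the observed variance relative to a fitted mean–variance trend v̂(·)
  (gamma GLM on a polynomial basis, or running median);
* gene-wise differential variability — the variance-ratio F-test
  F_g = s²_{g,A} / s²_{g,B} with two-sided p-values and
  Benjamini–Hochberg FDR, combined with a three-measure concordance rule
  (ΔCV, ΔEV and F must agree in direction);
* ranked DV top lists, the lockstep *common top-k* construction for
  cross-dataset consensus lists, and upper-tail hypergeometric
  overlap/enrichment tests computed in log space;
* seed-gene subnetwork extraction (seeds + neighbors, low-degree pruning
  to a fixpoint), Louvain communities, and hub genes by degree;
* cross-cohort random-forest classification from expression features or
  the median-distance variability proxy |x − median(x)|, summarized as
  the AUC distribution over many repeated runs;
* a synthetic two-cohort generator with known DV/DE ground truth, a
  concave SD-vs-mean trend, and a cohort-2 platform effect, so the whole
  pipeline is testable without any external download.

## Worked example

The `analysis/` scripts form a complete narrative run on synthetic
cohorts (3,000 genes; 70+52 and 24+36 samples). From the repository root:

```bash
python analysis/01_simulate.py            # cohorts + ground truth
python analysis/02_variability.py         # CV/EV tables, CV-vs-mean profile
python analysis/03_differential_variability.py
python analysis/04_enrichment.py
python analysis/05_network.py
python analysis/06_classification.py
```

`03_differential_variability.py` prints:

```
cohort1: 140 genes significantly more variable in U, 2 in M (q<0.05, concordant); ranked list of 140 genes
cohort2: 23 genes significantly more variable in U, 0 in M (q<0.05, concordant); ranked list of 1274 genes (no FDR cutoff)
lockstep expansion reaches 100 common genes at depth 131; 100 of them are true DV genes
top-300 lists overlap in 123 genes out of a 3000-gene universe (hypergeometric p = 2.42e-114)
```

The simulation planted 150 variance-inflated genes (λ = 3) in group U: the
large cohort recovers 140 of them at FDR 5%, the small cohort is
underpowered (hence the fixed-length list without the FDR cutoff, as one
does for a weak validation cohort), and the two cohorts' top lists agree
far beyond chance — the consensus list of 100 genes is entirely true DV.
The classifier comparison (`06_classification.py`, DV-only regime where
mean expression carries no signal) prints:

```
true DV genes (median distance): mean AUC 1.0000 (median 1.0000, sd 0.0001)
true DV genes (expression): mean AUC 0.9901 (median 0.9907, sd 0.0053)
500 random (median distance): mean AUC 0.8978 (median 0.9034, sd 0.0235)
500 random (expression): mean AUC 0.7373 (median 0.7361, sd 0.0432)
```

i.e. a forest trained on one cohort predicts the other cohort's subtype
labels from variability information alone, and the median-distance
transform of the true DV genes beats raw expression on the same genes as
well as both 500-random-gene baselines.

The same operations are available as CLI subcommands (`exprvar simulate`,
`variability`, `diffvar`, `diffexpr`, `toplist`, `enrich`, `network`,
`classify`), all deterministic under a fixed `--seed`; see
`exprvar --help`. Library functions live in `src/exprvar/` and are what
the analysis scripts, the CLI and the tests all call.

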