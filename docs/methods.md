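# Methods

`exprvar` quantifies and tests *differential gene-expression variability*
between two groups of samples — the situation where two disease subtypes
barely differ in mean expression but differ in how widely expression
scatters across patients — and carries that signal through set enrichment,
network community analysis, and cross-cohort classification. This note
documents the statistical model, the synthetic-data generator the test
suite runs on, the numerical choices, and the known limitations.

## Variability measures

All statistics operate on log2-scale expression values (e.g. RMA-normalized
microarray intensities) arranged genes × samples. Two per-gene, per-group
measures are computed:

* **CV** — the coefficient of variation, sample SD (n−1 denominator)
  divided by the mean, computed on the log2 scale exactly as supplied. The
  CV confounds variability with expression level: its 1/mean component
  dominates at low expression, and the SD itself follows a concave trend
  peaking at intermediate means. `cv_mean_profile` exposes this shape.
* **EV** — expression variability, the ratio of a gene's observed variance
  to the variance expected at its mean under a trend fitted across all
  genes. By construction EV is approximately independent of the mean
  (median ≈ 1, |Spearman ρ(EV, mean)| < 0.1 on null simulations).

The mean–variance trend is fitted by a gamma-family GLM with log link on a
standardized polynomial basis of the mean (default degree 3). This is a
deterministic stand-in for local polynomial likelihood estimation with
gamma regression: it reproduces a noise-free exponential mean–variance law
to within 1% and is exact for a flat law. A windowed running median
(window = 101 genes, linear interpolation) is available as a robust
fallback (`method="running_median"`). Evaluation outside the fitted mean
range clamps to the boundary, so extrapolated expected variances are never
non-positive. The trend is fitted within each group by default — EV then
measures departure from that group's own mean–variance relationship — with
a pooled-trend option.

## Differential variability and expression

Per gene, variance equality between groups A and B is tested with the
variance-ratio F-test, F = s²_A/s²_B on (n_A−1, n_B−1) degrees of freedom;
the two-sided p doubles the smaller tail (capped at 1). P-values are
Benjamini–Hochberg adjusted over the *testable* genes only — genes with
zero variance in either group are flagged untestable and counted, never
silently included. A gene is called concordantly more variable in one group
only when ΔCV, ΔEV and F all point that way; the two direction flags are
mutually exclusive by construction.

Differential expression uses a per-gene Welch two-sample t-test with the
conventional call rule q < 0.05 and |M| > 1 (strict), where M is the log2
fold change of group B over group A. A moderated (empirical-Bayes) linear
model would share variance information across genes; the Welch test was
chosen because the DE step is supporting machinery here, not the object of
study, and an unmoderated test keeps the statistic self-contained. With 52+
samples per group the moderation would change little.

Top lists of DV genes are built from the concordant genes (optionally
skipping the FDR cutoff when an underpowered cohort yields too few
significant genes, to reach a fixed-length list), ranked by |ΔCV| and by
|ΔEV|, ties broken on gene id so all outputs are deterministic. Because the
rule for merging the two orderings into a single list is a genuine design
choice, both raw lists are returned and a documented combined ranking (mean
of the two ranks, ties on id) is provided and used as the default seed list
for the network step. `common_top_k` expands two ranked lists in lockstep
to the smallest depth whose intersection reaches k genes — the
cross-dataset consensus construction; the returned set may exceed k if the
final depth adds several common genes at once.

## Enrichment

Over-representation is the upper-tail hypergeometric probability
P(X ≥ k), with candidate sets clipped to an explicit background universe
before testing, a minimum-overlap filter (default 3 genes), and BH
adjustment across the tested sets. The tail is accumulated in log space
(log-PMF + log-sum-exp), so overlaps such as 69 genes between two 500-gene
lists in a 12,307-gene universe give correctly computed p-values around
1e-19 instead of underflowing. Depletion testing is out of scope.

## Network analysis

Given a background interaction network (two-column edge list; self-loops
rejected, duplicate edges collapsed) and a seed list, the analysis
subnetwork is the subgraph induced on seeds plus direct neighbors, pruned
of nodes with degree below 2. Pruning is iterated to a fixpoint by default
(the k-core reading of "keep genes connected to at least two others");
a single-pass variant is provided because one pass is also a defensible
reading. Communities come from the Louvain modularity heuristic with a
fixed seed; the graph is first rebuilt with sorted nodes and edges so the
partition depends only on the graph's content, not on edge input order,
and community ids are relabeled by decreasing size for stability. Hub genes
are nodes at or above a degree cutoff (default 35, appropriate for
networks of a few thousand edges), ordered by degree then id.

## Classification

Cross-cohort classification trains a random forest on one cohort and
evaluates on the other, never mixing the two. Features are either raw
expression values or the **median-distance** transform |x − median(x)|, a
per-sample proxy for variability. Medians are computed within each cohort
separately — the two cohorts are assumed independently normalized, so
training-cohort medians do not transfer; a `train_medians` flag preserves
the alternative. Feature gene lists come from the shared-gene universe:
all shared genes, top DE by |M| among significant genes, top DV
(CV- or EV-ranked concordant genes), or k random genes (seeded).

Forests use 1,000 trees by default with the library defaults otherwise
(≈√p features per split, unlimited depth), and performance is the
Mann–Whitney AUC (ties counted half) of the forest's positive-class vote
fraction on the test cohort, with group B ("U") as the positive class.
The run is repeated (default 1,000 times; sub-seed = seed + repeat) and
summarized as mean/median/min/max/SD.

One transfer artifact is worth knowing: for a *mean-shifted* gene the
within-cohort median sits inside the majority class, so if the majority
class flips between cohorts (70/52 vs 24/36 here), median-distance rules
learned on the training cohort invert on the test cohort and AUC can fall
far below 0.5. Genes that differ only in variance are immune, which is
another reason the median-distance transform pairs naturally with DV gene
lists.

## Synthetic-data generator

The generator emulates the statistical structure this analysis assumes,
at the shape of two real microarray cohorts: cohort 1 with 70+52 samples,
cohort 2 with 24+36, a shared universe of 12,307 genes (scalable down; the
bundled analyses and tests use 3,000–5,000 genes to keep runtimes in
seconds-to-minutes). Per gene g, a base mean m_g is uniform on (4, 14)
log2 units and the baseline SD follows

    σ(m) = s0 + s1·m − s2·m²,  (s0, s1, s2) = (−0.515, 0.27, 0.015),

clamped to ≥ 0.01 — a concave-down arc rising from ≈0.33 at the range ends
to ≈0.70 at m = 9, which reproduces the observed shape of variability
against expression (SD peaked at intermediate means; CV falling as 1/mean
at the top of the range). Values are Gaussian on the log2 scale, matching
approximately Gaussian normalized intensities and keeping closed-form
truth for every gene.

Ground truth: 5% of genes are DV (group-U variance multiplied by λ = 3)
and a disjoint 5% are DE (group-U mean shifted by 1.5 log2 units, safely
past the |M| > 1 call rule). The disjointness keeps recovery metrics
unconfounded. Cohort 2 reuses the same truth with an independent noise
realization plus a platform effect — a global +0.3 log2 intercept and
per-gene jitter of SD 0.1 — so cross-cohort procedures must genuinely
transfer rather than memorize intensities. Identical spec (including seed)
reproduces bit-identical cohorts.

What the generator does **not** model: probe-level structure, batch and
spatial artifacts, heavy-tailed or skewed noise, correlated gene modules,
mixed DV+DE genes (available behind a config choice, off by default), and
continuous effect-size distributions — every DV gene has the same λ.
Passing tests therefore demonstrate that the machinery recovers the
signal it was designed for under clean conditions, not that real cohorts
would behave as cleanly. In particular the homogeneous λ = 3 makes random
gene baskets (which inherit ~5% DV genes) unrealistically informative for
classification compared with real data, where effect sizes taper off.

## Numerical and design choices

* Sample SD uses the n−1 denominator throughout.
* CV is NaN-flagged (not an exception) when a gene's mean is ≤ 0 — possible
  after user-supplied centering; such genes are excluded from CV rankings
  but keep EV and F-test results.
* All randomized operations take one integer seed; sub-seeds are derived
  deterministically (seed + repeat index), and fixed seeds give
  byte-identical CLI outputs.
* Ties everywhere break lexicographically on gene id.
* BH adjustment delegates to `statsmodels` (`fdr_bh`); the test suite
  checks it against a literal step-up implementation, as it does for AUC,
  the hypergeometric tail, the lockstep list expansion, and subnetwork
  pruning.
* Problem sizes in the bundled analyses (3,000–5,000 genes, 20 simulation
  seeds, 25–50 forest repeats, 100–200 trees) were chosen so each script
  finishes in seconds to a few minutes on one CPU; all are parameters, and
  the statistical structure does not depend on them.

## Limitations

* The gamma-GLM trend is a global polynomial, not a local likelihood fit;
  strongly non-polynomial mean–variance laws should use the running-median
  method.
* The F-test is the variance test of record here and assumes approximate
  normality per group; robust alternatives (Levene, Brown–Forsythe,
  permutation) are not implemented.
* Only two-group designs are supported, and each group needs ≥3 samples
  for the variance tests.
* Enrichment tests over-representation only, against a user-supplied
  universe; no annotation databases are bundled.
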