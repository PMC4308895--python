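"""Cross-cohort subtype classification from expression or variability features.

A random-forest classifier is trained on one cohort and evaluated on an
independent second cohort, using either raw expression values or a
per-sample proxy for expression variability: the median-distance feature
|x - median(x)|, where the median of each gene is taken across the samples
of the same cohort. Because the two cohorts were normalized independently,
medians are computed within each cohort by default (a flag applies the
training-cohort medians to the test cohort instead).

Performance is summarized as the distribution of test-set AUC over many
independently seeded forest fits (default 1,000 trees × 1,000 repeats),
reported as mean/median/min/max/SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.ensemble import RandomForestClassifier

from .errors import ValidationError
from .io import validate_sample_groups

__all__ = [
    "FeatureSpec",
    "AUCSummary",
    "median_distance_features",
    "compute_auc",
    "build_feature_spec",
    "cross_cohort_classify",
]


@dataclass(frozen=True)
class FeatureSpec:
    """Which genes to use and how to turn their values into features."""

    kind: str  # "expression" | "median_distance"
    genes: tuple[str, ...]
    source: str = "custom"

    def __post_init__(self) -> None:
        if self.kind not in ("expression", "median_distance"):
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if not self.genes:
            raise ValidationError("feature gene list is empty")


@dataclass
class AUCSummary:
    """Distribution of AUC over repeated classifier runs."""

    aucs: np.ndarray
    mean: float = field(init=False)
    median: float = field(init=False)
    min: float = field(init=False)
    max: float = field(init=False)
    sd: float = field(init=False)
    n_repeats: int = field(init=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.aucs, dtype=float)
        self.aucs = a
        self.mean = float(a.mean())
        self.median = float(np.median(a))
        self.min = float(a.min())
        self.max = float(a.max())
        self.sd = float(a.std(ddof=1)) if a.size > 1 else 0.0
        self.n_repeats = int(a.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "mean": self.mean, "median": self.median, "min": self.min,
            "max": self.max, "sd": self.sd, "n_repeats": self.n_repeats}])


def median_distance_features(m: pd.DataFrame, genes) -> pd.DataFrame:
    """|x - median(x)| per gene and sample; medians across this matrix's samples."""
    genes = list(genes)
    missing = [g for g in genes if g not in m.index]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing[:5]}")
    sub = m.loc[genes]
    med = sub.median(axis=1)
    return sub.sub(med, axis=0).abs()


def compute_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(random positive outscores random negative), ties half.

    ``labels`` is boolean/0-1 with the positive class true; both classes
    must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both classes present")
    ranks = scipy.stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def build_feature_spec(kind: str, source: str, k: int | None = None,
                       shared_genes=None, de_table: pd.DataFrame | None = None,
                       dv_table: pd.DataFrame | None = None,
                       fdr: float = 0.05, seed: int = 0) -> FeatureSpec:
    """Assemble the gene list for a classifier feature set.

    Sources: ``all_shared`` (every shared gene), ``top_de`` (k best by |M|
    among q < fdr), ``top_dv_cv`` / ``top_dv_ev`` (k best concordant DV
    genes by |ΔCV| / |ΔEV|), ``random`` (k genes sampled uniformly with the
    given seed). All lists are restricted to ``shared_genes``.
    """
    if shared_genes is None:
        raise ValidationError("shared_genes (the cross-platform universe) is required")
    shared = pd.Index(shared_genes)

    if source == "all_shared":
        genes = shared.tolist()
    elif source == "random":
        if k is None:
            raise ValidationError("source 'random' needs k")
        if k > len(shared):
            raise ValidationError(f"k={k} exceeds {len(shared)} shared genes")
        rng = np.random.default_rng(seed)
        genes = sorted(rng.choice(np.asarray(shared, dtype=object), size=k,
                                  replace=False).tolist())
    elif source == "top_de":
        if de_table is None:
            raise ValidationError("source 'top_de' needs the DE table")
        tab = de_table.loc[de_table.index.intersection(shared)]
        qualified = tab[tab["q"] < fdr].copy()
        qualified["abs_m"] = qualified["m_value"].abs()
        qualified["gene_id"] = qualified.index.astype(str)
        qualified = qualified.reset_index(drop=True).sort_values(
            ["abs_m", "gene_id"], ascending=[False, True])
        if k is not None and len(qualified) < k:
            raise ValidationError(
                f"only {len(qualified)} genes significant at q<{fdr}, need k={k}")
        genes = qualified["gene_id"].tolist()[:k]
    elif source in ("top_dv_cv", "top_dv_ev"):
        if dv_table is None:
            raise ValidationError(f"source {source!r} needs the DV table")
        from .differential import select_dv_genes
        tab = dv_table.loc[dv_table.index.intersection(shared)]
        list_cv, list_ev = select_dv_genes(tab, fdr=fdr, direction="B")
        ranked = list_cv if source == "top_dv_cv" else list_ev
        if k is not None and len(ranked) < k:
            raise ValidationError(
                f"only {len(ranked)} concordant DV genes available, need k={k}")
        genes = ranked.top(k) if k is not None else ranked.genes
    else:
        raise ValidationError(f"unknown feature source {source!r}")

    if not genes:
        raise ValidationError(f"feature source {source!r} produced no genes")
    return FeatureSpec(kind=kind, genes=tuple(genes), source=source)


def _features(m: pd.DataFrame, spec: FeatureSpec,
              medians: pd.Series | None = None) -> np.ndarray:
    genes = list(spec.genes)
    missing = [g for g in genes if g not in m.index]
    if missing:
        raise ValidationError(f"feature genes absent from matrix: {missing[:5]}")
    if spec.kind == "expression":
        return m.loc[genes].to_numpy().T
    if medians is not None:
        sub = m.loc[genes]
        return sub.sub(medians.loc[genes], axis=0).abs().to_numpy().T
    return median_distance_features(m, genes).to_numpy().T


def cross_cohort_classify(train: pd.DataFrame, train_groups: pd.Series,
                          test: pd.DataFrame, test_groups: pd.Series,
                          spec: FeatureSpec, n_trees: int = 1000,
                          n_repeats: int = 1000, seed: int = 0,
                          train_medians: bool = False) -> AUCSummary:
    """Train on one cohort, score the other; AUC summary over repeats.

    Each repeat r fits a fresh random forest (``n_trees`` trees, random
    state seed + r) on the training cohort's features and computes the
    Mann-Whitney AUC of its positive-class vote fraction on the test
    cohort. The positive class is group B (the second label in sorted
    order, conventionally "U"). Median-distance features use each cohort's
    own medians unless ``train_medians`` applies the training medians to
    the test cohort.
    """
    label_a, label_b = validate_sample_groups(train_groups, train)
    tla, tlb = validate_sample_groups(test_groups, test)
    if (label_a, label_b) != (tla, tlb):
        raise ValidationError(
            f"group labels differ between cohorts: {(label_a, label_b)} vs {(tla, tlb)}")
    counts = train_groups.value_counts()
    if (counts < 2).any():
        raise ValidationError("need >= 2 training samples per class")

    train_m = train[train_groups.index]
    test_m = test[test_groups.index]
    medians = None
    if train_medians and spec.kind == "median_distance":
        medians = train_m.loc[list(spec.genes)].median(axis=1)
    x_train = _features(train_m, spec)
    x_test = _features(test_m, spec, medians=medians)
    y_train = (train_groups.to_numpy() == label_b)
    y_test = (test_groups.to_numpy() == label_b)

    aucs = np.empty(n_repeats)
    for r in range(n_repeats):
        forest = RandomForestClassifier(n_estimators=n_trees,
                                        random_state=seed + r, n_jobs=1)
        forest.fit(x_train, y_train)
        pos = list(forest.classes_).index(True)
        scores = forest.predict_proba(x_test)[:, pos]
        aucs[r] = compute_auc(scores, y_test)
    return AUCSummary(aucs=aucs)
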