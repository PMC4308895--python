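"""Two-cohort synthetic expression generator with known variability structure.

The generator emulates the shape of two microarray CLL cohorts measured on
different platforms: a large cohort (default 70 + 52 samples) and a smaller
validation cohort (default 24 + 36), sharing a common gene universe
(default 12,307 genes, scalable down). Values are Gaussian on the log2
scale. Each gene g has a base mean m_g drawn uniformly over ``mean_range``
and a baseline standard deviation that follows a concave-down quadratic in
the mean,

    sigma(m) = s0 + s1*m - s2*m**2   (clamped to >= 0.01),

so the SD peaks at intermediate expression and the CV = sigma(m)/m has the
characteristic 1/mean component at low expression.

Ground truth: a fraction ``frac_dv`` of genes have their group-B variance
multiplied by ``lambda_dv`` (differential variability), and a disjoint
fraction ``frac_de`` have their group-B mean shifted by ``delta_de``
(differential expression). Cohort 2 reuses the same truth on a shared gene
subset with an independent noise realization plus a platform effect: a
global additive intercept and small per-gene jitter, mimicking independent
normalization of the two studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate_cohorts",
           "sd_trend", "theoretical_cv", "write_truth", "null_spec"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the two-cohort generative model.

    Defaults mirror the study conditions the generator emulates: cohort 1
    of 70+52 samples, cohort 2 of 24+36, a 12,307-gene shared universe,
    5% DV genes with a 3-fold group-B variance inflation, and 5% DE genes
    shifted by 1.5 log2 units (comfortably past the |M| > 1 call cutoff).
    """

    n_genes: int = 12307
    group_sizes_cohort1: tuple[int, int] = (70, 52)
    group_sizes_cohort2: tuple[int, int] = (24, 36)
    shared_gene_fraction: float = 1.0
    frac_dv: float = 0.05
    lambda_dv: float = 3.0
    frac_de: float = 0.05
    delta_de: float = 1.5
    mean_range: tuple[float, float] = (4.0, 14.0)
    sd_trend_params: tuple[float, float, float] = (-0.515, 0.27, 0.015)
    platform_offset: float = 0.3
    platform_jitter_sd: float = 0.1
    group_labels: tuple[str, str] = ("M", "U")
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        for sizes in (self.group_sizes_cohort1, self.group_sizes_cohort2):
            if min(sizes) < 3:
                raise ValidationError(
                    f"each group needs >= 3 samples for variance tests, got {sizes}"
                )
        if not (0 < self.shared_gene_fraction <= 1):
            raise ValidationError("shared_gene_fraction must lie in (0, 1]")
        if self.frac_dv < 0 or self.frac_de < 0 or self.frac_dv + self.frac_de > 1:
            raise ValidationError("need frac_dv, frac_de >= 0 and frac_dv+frac_de <= 1")
        if self.frac_dv > 0 and self.lambda_dv <= 1:
            raise ValidationError("lambda_dv must be > 1")
        lo, hi = self.mean_range
        if not lo < hi:
            raise ValidationError("mean_range must be an increasing pair")
        grid = np.linspace(lo, hi, 512)
        if np.any(_raw_sd(self.sd_trend_params, grid) <= 0):
            raise ValidationError("SD trend must be strictly positive over mean_range")
        if len(set(self.group_labels)) != 2:
            raise ValidationError("group_labels must be two distinct labels")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated pair of cohorts.

    ``table`` has one row per gene: base_mean, mean/sd per group (cohort-1
    scale), is_dv, is_de, the inflation factor and mean shift actually
    applied, the cohort-2 per-gene platform offset, and shared-gene flag.
    """

    table: pd.DataFrame
    dv_genes: frozenset[str] = field(init=False)
    de_genes: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        self.dv_genes = frozenset(self.table.index[self.table["is_dv"]])
        self.de_genes = frozenset(self.table.index[self.table["is_de"]])
        if self.dv_genes & self.de_genes:
            raise ValidationError("DV and DE truth sets must be disjoint")


def _raw_sd(params: tuple[float, float, float], mean) -> np.ndarray:
    s0, s1, s2 = params
    return s0 + s1 * np.asarray(mean, dtype=float) - s2 * np.asarray(mean, dtype=float) ** 2


def sd_trend(spec: SyntheticSpec, mean) -> np.ndarray:
    """Baseline (non-DV) SD at a given log2 mean, clamped to >= 0.01."""
    return np.maximum(_raw_sd(spec.sd_trend_params, mean), 0.01)


def theoretical_cv(spec: SyntheticSpec, gene_mean: float, group: str,
                   is_dv: bool = False) -> float:
    """CV implied by the generative model at a given mean.

    For a DV gene in group B the SD is inflated by sqrt(lambda_dv); the CV
    scales accordingly.
    """
    if gene_mean <= 0:
        raise ValidationError("theoretical CV undefined for mean <= 0")
    lo, hi = spec.mean_range
    if not (lo <= gene_mean <= hi):
        raise ValidationError(f"gene_mean {gene_mean} outside mean_range {spec.mean_range}")
    if group not in spec.group_labels:
        raise ValidationError(f"unknown group {group!r}")
    sigma = float(sd_trend(spec, gene_mean))
    if is_dv and group == spec.group_labels[1]:
        sigma *= np.sqrt(spec.lambda_dv)
    return sigma / gene_mean


def _simulate_matrix(rng: np.random.Generator, gene_ids: pd.Index,
                     means_a: np.ndarray, means_b: np.ndarray,
                     sds_a: np.ndarray, sds_b: np.ndarray,
                     n_a: int, n_b: int, sample_prefix: str,
                     labels: tuple[str, str]) -> tuple[pd.DataFrame, pd.Series]:
    g = len(gene_ids)
    vals_a = rng.normal(means_a[:, None], sds_a[:, None], size=(g, n_a))
    vals_b = rng.normal(means_b[:, None], sds_b[:, None], size=(g, n_b))
    samples = [f"{sample_prefix}_{i + 1:03d}" for i in range(n_a + n_b)]
    m = pd.DataFrame(np.hstack([vals_a, vals_b]), index=gene_ids, columns=samples)
    m.index.name = "gene_id"
    groups = pd.Series([labels[0]] * n_a + [labels[1]] * n_b,
                       index=pd.Index(samples, name="sample_id"), name="group")
    return m, groups


def generate_cohorts(spec: SyntheticSpec) -> tuple[
        pd.DataFrame, pd.Series, pd.DataFrame, pd.Series, SyntheticTruth]:
    """Generate the paired cohorts and their ground truth.

    Returns ``(matrix1, groups1, matrix2, groups2, truth)``. Identical spec
    (including seed) yields bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g = spec.n_genes
    gene_ids = pd.Index([f"g{i + 1:06d}" for i in range(g)], name="gene_id")

    base_means = rng.uniform(*spec.mean_range, size=g)
    base_sds = sd_trend(spec, base_means)

    perm = rng.permutation(g)
    n_dv = int(round(spec.frac_dv * g))
    n_de = int(round(spec.frac_de * g))
    is_dv = np.zeros(g, dtype=bool)
    is_de = np.zeros(g, dtype=bool)
    is_dv[perm[:n_dv]] = True
    is_de[perm[n_dv:n_dv + n_de]] = True

    means_a = base_means
    means_b = base_means + spec.delta_de * is_de
    sds_a = base_sds
    sds_b = base_sds * np.where(is_dv, np.sqrt(spec.lambda_dv), 1.0)

    n1a, n1b = spec.group_sizes_cohort1
    m1, g1 = _simulate_matrix(rng, gene_ids, means_a, means_b, sds_a, sds_b,
                              n1a, n1b, "c1s", spec.group_labels)

    n_shared = max(1, int(round(spec.shared_gene_fraction * g)))
    shared_idx = np.sort(rng.permutation(g)[:n_shared])
    shared = np.zeros(g, dtype=bool)
    shared[shared_idx] = True

    jitter = rng.normal(0.0, spec.platform_jitter_sd, size=g)
    offset = spec.platform_offset + jitter
    n2a, n2b = spec.group_sizes_cohort2
    m2, g2 = _simulate_matrix(
        rng, gene_ids[shared_idx],
        (means_a + offset)[shared_idx], (means_b + offset)[shared_idx],
        sds_a[shared_idx], sds_b[shared_idx],
        n2a, n2b, "c2s", spec.group_labels)

    table = pd.DataFrame({
        "base_mean": base_means,
        "mean_A": means_a,
        "mean_B": means_b,
        "sd_A": sds_a,
        "sd_B": sds_b,
        "is_dv": is_dv,
        "is_de": is_de,
        "lambda": np.where(is_dv, spec.lambda_dv, 1.0),
        "delta": np.where(is_de, spec.delta_de, 0.0),
        "cohort2_offset": offset,
        "in_cohort2": shared,
    }, index=gene_ids)
    return m1, g1, m2, g2, SyntheticTruth(table=table)


def write_truth(truth: SyntheticTruth, path) -> None:
    """Write the ground-truth table as TSV."""
    truth.table.to_csv(path, sep="\t", index_label="gene_id")


def null_spec(**overrides) -> SyntheticSpec:
    """A spec with no DV and no DE genes (both groups exchangeable)."""
    return replace(SyntheticSpec(frac_dv=0.0, frac_de=0.0), **overrides)
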