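"""Per-group gene-expression variability statistics: CV, mean-variance
trend, and EV.

Two measures of across-sample variability are provided for each gene:

* **CV** (coefficient of variation): sample SD (n-1 denominator) divided by
  the mean, computed on the log2 scale as provided. CV confounds
  variability with expression level (a 1/mean component), so it is
  complemented by
* **EV** (expression variability): the ratio of a gene's observed variance
  to the variance expected at its mean under a trend fitted across all
  genes. EV is designed to be independent of the expression mean.

The mean-variance trend is fitted either by a gamma-family GLM with log
link on a polynomial basis of the mean (default, degree 3) — a
deterministic approximation of local polynomial likelihood estimation with
gamma regression — or by a windowed running median with linear
interpolation as a robust fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError
from .io import validate_sample_groups

__all__ = [
    "MeanVarianceTrend",
    "compute_cv",
    "fit_mean_variance_trend",
    "compute_ev",
    "variability_table",
    "group_variability_tables",
    "cv_mean_profile",
]

MIN_TREND_GENES = 50


@dataclass
class MeanVarianceTrend:
    """Expected variance as a function of mean expression.

    Evaluation outside the fitted mean domain clamps to the boundary value,
    so extrapolation can never produce a non-positive expected variance.
    """

    method: str
    params: dict
    fit_domain: tuple[float, float]
    _evaluate: Callable[[np.ndarray], np.ndarray]

    def __call__(self, means) -> np.ndarray:
        scalar = np.isscalar(means) or np.ndim(means) == 0
        means = np.atleast_1d(np.asarray(means, dtype=float))
        clamped = np.clip(means, *self.fit_domain)
        out = np.asarray(self._evaluate(clamped), dtype=float)
        if np.any(out <= 0):
            raise ValidationError(
                f"{self.method} trend evaluated non-positive; invariant violated")
        return float(out[0]) if scalar else out


def compute_cv(values) -> float:
    """Sample SD over mean; NaN (flagged undefined) when the mean is zero."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("CV needs at least 2 values")
    mean = values.mean()
    if mean == 0:
        return float("nan")
    return float(values.std(ddof=1) / mean)


def fit_mean_variance_trend(means, variances, method: str = "gamma_glm_poly",
                            degree: int = 3, window: int = 101) -> MeanVarianceTrend:
    """Fit the expected-variance-vs-mean trend across genes.

    ``gamma_glm_poly`` fits a gamma GLM with log link on a standardized
    polynomial basis of the mean (degree ``degree``); ``running_median``
    fits a centered rolling median of variance against sorted means with
    linear interpolation (``window`` genes wide).
    """
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if means.shape != variances.shape:
        raise ValidationError("means and variances must have equal length")
    if means.size < MIN_TREND_GENES:
        raise ValidationError(
            f"trend fitting needs >= {MIN_TREND_GENES} genes, got {means.size}")
    if np.any(variances <= 0):
        raise ValidationError("all variances must be > 0 to fit the trend")
    domain = (float(means.min()), float(means.max()))

    if method == "gamma_glm_poly":
        # a (near-)constant response is degenerate for the gamma GLM (zero
        # dispersion); the trend is the constant itself
        if variances.max() - variances.min() <= 1e-12 * variances.mean():
            v0 = float(variances.mean())
            return MeanVarianceTrend("gamma_glm_poly", {"degree": 0, "const": v0},
                                     domain, lambda m, _v=v0: np.full(np.shape(m), _v))
        loc, scale = means.mean(), means.std()
        if scale == 0:
            scale = 1.0
        z = (means - loc) / scale
        basis = np.vander(z, degree + 1, increasing=True)
        model = sm.GLM(variances, basis,
                       family=sm.families.Gamma(link=sm.families.links.Log()))
        try:
            fit = model.fit(maxiter=200)
        except Exception as exc:  # pragma: no cover - convergence failure path
            raise ValidationError(
                "gamma_glm_poly failed to converge; try method='running_median'"
            ) from exc
        coef = np.asarray(fit.params)

        def evaluate(m, _coef=coef, _loc=loc, _scale=scale, _deg=degree):
            zz = (np.asarray(m, dtype=float) - _loc) / _scale
            return np.exp(np.vander(zz, _deg + 1, increasing=True) @ _coef)

        params = {"degree": degree, "coef": coef, "loc": loc, "scale": scale}
        return MeanVarianceTrend("gamma_glm_poly", params, domain, evaluate)

    if method == "running_median":
        order = np.argsort(means, kind="stable")
        xs = means[order]
        med = (pd.Series(variances[order])
               .rolling(window, center=True, min_periods=1).median().to_numpy())
        # collapse duplicate means so np.interp sees a strictly increasing grid
        grid = pd.DataFrame({"x": xs, "y": med}).groupby("x", sort=True)["y"].mean()
        gx, gy = grid.index.to_numpy(), grid.to_numpy()

        def evaluate(m, _gx=gx, _gy=gy):
            return np.interp(np.asarray(m, dtype=float), _gx, _gy)

        return MeanVarianceTrend("running_median", {"window": window}, domain, evaluate)

    raise ValidationError(f"unknown trend method {method!r}")


def compute_ev(means, variances, trend: MeanVarianceTrend) -> np.ndarray:
    """EV per gene: observed variance over trend-expected variance."""
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    return variances / trend(means)


def variability_table(m: pd.DataFrame, method: str = "gamma_glm_poly",
                      degree: int = 3, window: int = 101) -> pd.DataFrame:
    """Per-gene variability statistics for one sample group.

    Columns: n, mean, sd, var, cv, expected_var, ev. CV is NaN where the
    mean is non-positive (flagged undefined); the trend is fitted on genes
    with positive variance only.
    """
    values = m.to_numpy()
    n = values.shape[1]
    if n < 2:
        raise ValidationError("variability statistics need >= 2 samples")
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    var = sd ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)

    ok = var > 0
    if ok.sum() < MIN_TREND_GENES:
        raise ValidationError("too few genes with positive variance to fit trend")
    trend = fit_mean_variance_trend(mean[ok], var[ok], method=method,
                                    degree=degree, window=window)
    expected = trend(mean)
    ev = np.where(ok, var / expected, np.nan)

    return pd.DataFrame({
        "n": n, "mean": mean, "sd": sd, "var": var, "cv": cv,
        "expected_var": expected, "ev": ev,
    }, index=m.index)


def group_variability_tables(m: pd.DataFrame, groups: pd.Series,
                             method: str = "gamma_glm_poly", degree: int = 3,
                             window: int = 101, pooled_trend: bool = False,
                             ) -> dict[str, pd.DataFrame]:
    """Variability table per group (trend fitted within each group by default).

    With ``pooled_trend`` the trend is fitted once on all samples and reused
    for both groups' expected variances.
    """
    label_a, label_b = validate_sample_groups(groups, m)
    out: dict[str, pd.DataFrame] = {}
    shared_trend = None
    if pooled_trend:
        pooled = variability_table(m[groups.index], method=method,
                                   degree=degree, window=window)
        ok = pooled["var"] > 0
        shared_trend = fit_mean_variance_trend(
            pooled.loc[ok, "mean"], pooled.loc[ok, "var"],
            method=method, degree=degree, window=window)
    for label in (label_a, label_b):
        cols = groups.index[groups == label]
        sub = m[cols]
        if shared_trend is None:
            out[label] = variability_table(sub, method=method, degree=degree,
                                           window=window)
        else:
            values = sub.to_numpy()
            mean = values.mean(axis=1)
            sd = values.std(axis=1, ddof=1)
            var = sd ** 2
            with np.errstate(divide="ignore", invalid="ignore"):
                cv = np.where(mean > 0, sd / mean, np.nan)
            expected = shared_trend(mean)
            ev = np.where(var > 0, var / expected, np.nan)
            out[label] = pd.DataFrame({
                "n": values.shape[1], "mean": mean, "sd": sd, "var": var,
                "cv": cv, "expected_var": expected, "ev": ev}, index=sub.index)
    return out


def cv_mean_profile(m: pd.DataFrame, n_bins: int = 20) -> pd.DataFrame:
    """Median CV and SD within equal-count bins of mean expression.

    The profile reproduces the characteristic shape of variability against
    expression level: SD peaks at intermediate means while CV adds a 1/mean
    component that dominates at low expression.
    """
    if n_bins < 3:
        raise ValidationError("need n_bins >= 3")
    if m.shape[0] < n_bins:
        raise ValidationError(f"fewer genes ({m.shape[0]}) than bins ({n_bins})")
    values = m.to_numpy()
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    order = np.argsort(mean, kind="stable")
    bins = np.array_split(order, n_bins)
    rows = []
    for b, idx in enumerate(bins):
        rows.append({
            "bin": b,
            "n_genes": len(idx),
            "mean": float(np.mean(mean[idx])),
            "median_cv": float(np.nanmedian(cv[idx])),
            "median_sd": float(np.median(sd[idx])),
        })
    return pd.DataFrame(rows).set_index("bin")
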