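"""Fit statistics, model ranking, interval comparisons and prediction bands.

The evaluation conventions used throughout:

* RMSE = sqrt(SSE / denominator), denominator either n (plain root mean
  square) or n - p (root MSE of a regression with p parameters; the
  default, matching standard NLS software output).
* MD (mean deviation) = mean(predicted - observed), signed, in metres.
* Fit index = 1 - SSE/SST, the nonlinear-regression analogue of R^2.
* Interval narrowing = 100 * (1 - width(comparison)/width(reference)),
  in percent: how much tighter one 95% interval is than another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .models import get_model, predict_height
from .summaries import FitSummary


def _check_pair(observed, predicted):
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValidationError("observed and predicted must be 1-d and equal length")
    if obs.size < 1:
        raise ValidationError("need at least one observation")
    return obs, pred


def mean_deviation(observed, predicted) -> float:
    """Signed mean of (predicted - observed); 0 means unbiased on average."""
    obs, pred = _check_pair(observed, predicted)
    return float(np.mean(pred - obs))


def rmse(observed, predicted, n_params: int = 0, denominator: str = "n-p") -> float:
    """Root mean square error with an n or n-p denominator."""
    obs, pred = _check_pair(observed, predicted)
    sse = float(np.sum((obs - pred) ** 2))
    if denominator == "n":
        denom = obs.size
    elif denominator == "n-p":
        denom = obs.size - n_params
        if denom <= 0:
            raise ValidationError(
                f"n-p denominator requires n > n_params ({obs.size} <= {n_params})"
            )
    else:
        raise ValidationError(f"denominator must be 'n' or 'n-p', got {denominator!r}")
    return float(np.sqrt(sse / denom))


def fit_index(observed, predicted) -> float:
    """1 - SSE/SST; 1 for a perfect fit, 0 for predicting the mean."""
    obs, pred = _check_pair(observed, predicted)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValidationError("fit index undefined when all observations are equal")
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sst


def interval_width_reduction(reference, comparison) -> float:
    """Percent narrowing of ``comparison`` relative to ``reference``.

    Both arguments are (low, high) pairs.  Positive means the comparison
    interval is tighter; returned at full precision (round for reporting).
    """
    ref_lo, ref_hi = map(float, reference)
    cmp_lo, cmp_hi = map(float, comparison)
    if not (ref_hi > ref_lo and cmp_hi > cmp_lo):
        raise ValidationError("intervals must have high > low")
    return 100.0 * (1.0 - (cmp_hi - cmp_lo) / (ref_hi - ref_lo))


def rank_models(reports: list[FitSummary], criterion: str) -> list[str]:
    """Order model ids ascending by RMSE or DIC (smaller is better).

    Ties broken by fewer parameters, then lexicographic model id, so the
    ranking is deterministic.
    """
    if criterion not in ("rmse", "dic"):
        raise ValidationError(f"criterion must be 'rmse' or 'dic', got {criterion!r}")
    if len(reports) < 2:
        raise ValidationError("need at least two models to rank")
    keyed = []
    for r in reports:
        if criterion not in r.fit_stats:
            raise ValidationError(f"{r.model_id}: missing {criterion!r} value")
        keyed.append(
            (r.fit_stats[criterion], get_model(r.model_id).n_params, r.model_id)
        )
    return [model_id for _, _, model_id in sorted(keyed)]


@dataclass
class ComparisonReport:
    """Model x method comparison assembled from individual fits."""

    fits: list[FitSummary]

    def table(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            for name, e in f.estimates.items():
                row = {
                    "model": f.model_id,
                    "method": f.method,
                    "parameter": name,
                    "mean": e.mean,
                    "sd": e.sd,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                }
                row.update(f.fit_stats)
                rows.append(row)
        return pd.DataFrame(rows)

    def fit_stat_table(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            row = {"model": f.model_id, "method": f.method, "n_obs": f.n_obs}
            row.update(f.fit_stats)
            rows.append(row)
        return pd.DataFrame(rows)

    def ranking(self, criterion: str) -> list[str]:
        return rank_models(self.fits, criterion)

    def to_dict(self) -> dict:
        return {"fits": [f.to_dict() for f in self.fits]}

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonReport":
        return cls(fits=[FitSummary.from_dict(f) for f in d["fits"]])


def fit_statistics(
    dataset, fit: FitSummary, denominator: str = "n-p"
) -> dict[str, float]:
    """RMSE, MD and fit index of a fitted curve on a dataset."""
    pred = predict_height(fit.model_id, fit.point_estimates, dataset.dbh)
    p = len(fit.estimates)
    return {
        "rmse": rmse(dataset.height, pred, n_params=p, denominator=denominator),
        "md": mean_deviation(dataset.height, pred),
        "fit_index": fit_index(dataset.height, pred),
    }


def prediction_band(
    fit,
    dbh_grid,
    level: float = 0.95,
    band_type: str = "mean_curve",
    seed: int = 0,
) -> pd.DataFrame:
    """Pointwise 95% (by default) band of the fitted curve over a DBH grid.

    For an :class:`~hdbayes.bayes.MCMCChains` input the band is formed from
    equal-tailed quantiles of the curve evaluated at each posterior draw
    (``mean_curve``), optionally with Gaussian noise added per draw
    (``predictive``).  For a classical :class:`FitSummary` the band is the
    delta-method Wald band around the NLS curve; ``predictive`` adds the
    residual variance.

    Returns a DataFrame with columns (dbh, center, low, high).
    """
    if band_type not in ("mean_curve", "predictive"):
        raise ValidationError(f"unknown band_type {band_type!r}")
    grid = np.atleast_1d(np.asarray(dbh_grid, dtype=float))
    if np.any(grid < 0) or not np.all(np.isfinite(grid)):
        raise ValidationError("DBH grid must be finite and non-negative")
    alpha = 1.0 - level

    from .bayes import MCMCChains  # local import to avoid a cycle

    if isinstance(fit, MCMCChains):
        theta = fit.pooled()  # (n_draws, p + 1), last column sigma
        params = [theta[:, j][:, None] for j in range(theta.shape[1] - 1)]
        from .models import _eval

        with np.errstate(invalid="ignore", over="ignore"):
            curves = _eval(fit.model_id, params, grid[None, :])
        if band_type == "predictive":
            rng = np.random.default_rng(seed)
            curves = curves + theta[:, -1][:, None] * rng.standard_normal(curves.shape)
        center = curves.mean(axis=0)
        low = np.quantile(curves, alpha / 2, axis=0)
        high = np.quantile(curves, 1 - alpha / 2, axis=0)
    elif isinstance(fit, FitSummary):
        if fit.method != "classical":
            raise ValidationError(
                "FitSummary bands are delta-method Wald bands; pass MCMCChains "
                "for Bayesian bands"
            )
        cov = getattr(fit, "covariance", None)
        if cov is None:
            raise ValidationError("classical FitSummary lacks a covariance matrix")
        theta = np.asarray(fit.point_estimates)
        center = predict_height(fit.model_id, theta, grid)
        # numerical gradient of the curve wrt parameters at each grid point
        grads = np.empty((grid.size, theta.size))
        for j in range(theta.size):
            h = 1e-6 * max(abs(theta[j]), 1.0)
            up, dn = theta.copy(), theta.copy()
            up[j] += h
            dn[j] -= h
            grads[:, j] = (
                predict_height(fit.model_id, up, grid)
                - predict_height(fit.model_id, dn, grid)
            ) / (2 * h)
        var = np.einsum("ij,jk,ik->i", grads, cov, grads)
        if band_type == "predictive":
            var = var + fit.fit_stats.get("rmse", 0.0) ** 2
        dof = max(fit.n_obs - theta.size, 1)
        half = stats.t.ppf(1 - alpha / 2, dof) * np.sqrt(var)
        low, high = center - half, center + half
    else:
        raise ValidationError(f"cannot build a band from {type(fit).__name__}")

    return pd.DataFrame({"dbh": grid, "center": center, "low": low, "high": high})
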