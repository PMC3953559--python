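"""Nonlinear least-squares fitting of the height-diameter forms.

Point estimates minimise the residual sum of squares via a
Levenberg-Marquardt / trust-region least-squares solver launched from a
deterministic grid of starting values (nonlinear growth curves routinely
have poor local minima when started far from the data scale).  Standard
errors come from the asymptotic covariance s^2 (J'J)^{-1} with
s^2 = SSE/(n - p); 95% confidence intervals are Wald intervals with a
t_{n-p} critical value.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
from scipy import optimize, stats

from .datasets import TreeDataset
from .exceptions import ConvergenceError, SingularityWarning, ValidationError
from .models import _eval, get_model
from .summaries import FitSummary, ParamEstimate


def _initial_grid(model_id: str, dataset: TreeDataset) -> list[tuple[float, ...]]:
    """Deterministic multistart grid on the scale each form operates at.

    The asymptote-like ``a`` is anchored to the tallest observed tree; the
    shape/rate values cover the range typical for conifer H-D fits of each
    functional family.
    """
    hmax = float(dataset.height.max())
    a_grid = (hmax, 1.5 * hmax)
    if model_id in ("chapman_richards", "weibull"):
        grids = (a_grid, (0.01, 0.05, 0.1), (0.5, 1.0, 2.0))
    elif model_id == "bertalanffy":
        grids = (a_grid, (0.01, 0.05, 0.1))
    elif model_id == "logistic":
        grids = (a_grid, (1.0, 3.0, 5.0), (0.05, 0.1, 0.2))
    elif model_id == "gompertz":
        grids = (a_grid, (-15.0, -5.0, -1.0), (1.0, 3.0, 5.0))
    elif model_id == "power_law":
        grids = ((1.0, 3.0), (0.3, 0.6, 1.0))
    else:
        raise ValidationError(f"unknown model {model_id!r}")
    return list(itertools.product(*grids))


def fit_nls(
    dataset: TreeDataset,
    model_id: str,
    rmse_denominator: str = "n-p",
    fixed: dict[str, float] | None = None,
    n_starts: int = 3,
) -> FitSummary:
    """Fit one model form by nonlinear least squares.

    Parameters
    ----------
    dataset : TreeDataset
    model_id : str
        One of the six form ids.
    rmse_denominator : {"n-p", "n"}
        Convention for the reported RMSE (the root MSE ``n-p`` is the
        default, matching standard NLS software).
    fixed : dict, optional
        Parameters to hold at given values (profiled out of the fit).
    n_starts : int
        Number of grid points (best by initial SSE) to launch the
        optimizer from; the full grid is always screened.

    Returns
    -------
    FitSummary
        With a ``covariance`` attribute (free-parameter order) attached
        for downstream delta-method bands.
    """
    spec = get_model(model_id)
    fixed = dict(fixed or {})
    for name in fixed:
        if name not in spec.param_names:
            raise ValidationError(f"{model_id} has no parameter {name!r}")
    free_names = [p for p in spec.param_names if p not in fixed]
    p_free = len(free_names)
    n = dataset.n
    if n < spec.n_params + 2:
        raise ValidationError(
            f"need at least {spec.n_params + 2} trees to fit {model_id}, got {n}"
        )
    if np.ptp(dataset.dbh) == 0.0:
        raise ValidationError("all DBH values identical; model unidentifiable")

    dbh, height = dataset.dbh, dataset.height

    def full_params(free):
        vals = dict(zip(free_names, free))
        vals.update(fixed)
        return [vals[p] for p in spec.param_names]

    def residuals(free):
        with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
            pred = _eval(model_id, full_params(free), dbh)
        r = pred - height
        return np.where(np.isfinite(r), r, 1e10)

    starts = [
        tuple(v for name, v in zip(spec.param_names, s) if name in free_names)
        for s in _initial_grid(model_id, dataset)
    ]
    # screen the whole grid by SSE, optimize from the best few
    sses = [float(np.sum(residuals(np.asarray(s)) ** 2)) for s in starts]
    order = np.argsort(sses, kind="stable")[: max(1, n_starts)]

    best = None
    for idx in order:
        try:
            sol = optimize.least_squares(
                residuals, np.asarray(starts[idx], dtype=float), method="lm"
            )
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.isfinite(best.cost):
        raise ConvergenceError(
            f"NLS failed to converge for {model_id} from any start",
            best_params=None if best is None else best.x,
        )

    theta = best.x
    sse = float(2.0 * best.cost)
    dof = n - p_free
    s2 = sse / dof
    jtj = best.jac.T @ best.jac
    rank = np.linalg.matrix_rank(jtj)
    if rank < p_free:
        warnings.warn(
            f"rank-deficient Jacobian at the {model_id} solution; "
            "standard errors are inflated",
            SingularityWarning,
        )
    cov = s2 * np.linalg.pinv(jtj)
    se = np.sqrt(np.diag(cov))
    tcrit = stats.t.ppf(0.975, dof)

    estimates = {
        name: ParamEstimate(
            mean=float(m), sd=float(s),
            ci_low=float(m - tcrit * s), ci_high=float(m + tcrit * s),
        )
        for name, m, s in zip(free_names, theta, se)
    }
    with np.errstate(invalid="ignore", over="ignore"):
        pred = _eval(model_id, full_params(theta), dbh)
    from .evaluation import fit_index, mean_deviation, rmse as _rmse

    summary = FitSummary(
        method="classical",
        model_id=model_id,
        estimates=estimates,
        fit_stats={
            "rmse": _rmse(height, pred, n_params=p_free, denominator=rmse_denominator),
            "md": mean_deviation(height, pred),
            "fit_index": fit_index(height, pred),
            "sse": sse,
        },
        n_obs=n,
    )
    summary.covariance = cov
    summary.fixed = fixed
    summary.multistart_sses = sses
    return summary
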