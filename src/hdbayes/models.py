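"""Candidate height-diameter model forms.

Six nonlinear allometric curves routinely used to predict total tree
height H (m) from diameter at breast height DBH (cm).  All forms include
the additive 1.3 m breast-height offset, so H(0) starts at breast height
for the saturating forms and the asymptote parameter ``a`` is the height
above breast height.

Forms (H in m, DBH in cm):

========================  =================================================
chapman_richards          H = 1.3 + a * (1 - exp(-b * DBH)) ** c
weibull                   H = 1.3 + a * (1 - exp(-b * DBH ** c))
logistic                  H = 1.3 + a / (1 + b * exp(-c * DBH))
gompertz                  H = 1.3 + a * exp(b / (DBH + c))
bertalanffy               H = 1.3 + a * (1 - exp(-b * DBH)) ** 3
power_law                 H = 1.3 + a * DBH ** b
========================  =================================================

The Gompertz form above is deliberately kept as published for Chinese-fir
height-diameter work (a decaying exponential in 1/(DBH + c), fitted with
negative ``b``) rather than the textbook double-exponential Gompertz.

Parameters are treated as unconstrained reals: the samplers and
optimizers place no positivity constraints, and each form is evaluated
wherever it is mathematically defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, ParameterArityError, ValidationError

#: Breast height in metres; DBH is measured here and curves are offset by it.
BREAST_HEIGHT = 1.3


@dataclass(frozen=True)
class ModelSpec:
    """Metadata for one height-diameter functional form."""

    model_id: str
    param_names: tuple[str, ...]
    breast_height_offset: float = field(default=BREAST_HEIGHT)

    @property
    def n_params(self) -> int:
        return len(self.param_names)


MODELS: dict[str, ModelSpec] = {
    "chapman_richards": ModelSpec("chapman_richards", ("a", "b", "c")),
    "weibull": ModelSpec("weibull", ("a", "b", "c")),
    "logistic": ModelSpec("logistic", ("a", "b", "c")),
    "gompertz": ModelSpec("gompertz", ("a", "b", "c")),
    "bertalanffy": ModelSpec("bertalanffy", ("a", "b")),
    "power_law": ModelSpec("power_law", ("a", "b")),
}

MODEL_IDS: tuple[str, ...] = tuple(MODELS)


def get_model(model_id: str) -> ModelSpec:
    try:
        return MODELS[model_id]
    except KeyError:
        raise ValidationError(
            f"unknown model {model_id!r}; choose from {sorted(MODELS)}"
        ) from None


def _eval(model_id: str, params, dbh):
    """Raw vectorised evaluation, no validation.

    ``params`` is a sequence of scalars or broadcastable arrays; out-of-domain
    combinations yield nan/inf rather than raising, which the MCMC sampler
    relies on to reject such proposals.
    """
    d = dbh
    if model_id == "chapman_richards":
        a, b, c = params
        return BREAST_HEIGHT + a * (1.0 - np.exp(-b * d)) ** c
    if model_id == "weibull":
        a, b, c = params
        return BREAST_HEIGHT + a * (1.0 - np.exp(-b * d**c))
    if model_id == "logistic":
        a, b, c = params
        return BREAST_HEIGHT + a / (1.0 + b * np.exp(-c * d))
    if model_id == "gompertz":
        a, b, c = params
        return BREAST_HEIGHT + a * np.exp(b / (d + c))
    if model_id == "bertalanffy":
        a, b = params
        return BREAST_HEIGHT + a * (1.0 - np.exp(-b * d)) ** 3
    if model_id == "power_law":
        a, b = params
        return BREAST_HEIGHT + a * d**b
    raise ValidationError(f"unknown model {model_id!r}")


def predict_height(model_id: str, params, dbh):
    """Evaluate a height-diameter curve at one or many DBH values.

    Parameters
    ----------
    model_id : str
        One of :data:`MODEL_IDS`.
    params : sequence of float
        Parameter vector in the order given by ``MODELS[model_id].param_names``.
    dbh : float or array-like
        Diameter(s) at breast height, cm, non-negative.

    Returns
    -------
    float or ndarray
        Predicted total height(s) in metres (scalar in, scalar out).
    """
    spec = get_model(model_id)
    params = np.asarray(params, dtype=float)
    if params.ndim != 1 or params.size != spec.n_params:
        raise ParameterArityError(
            f"{model_id} takes {spec.n_params} parameters "
            f"({', '.join(spec.param_names)}); got {params.size}"
        )
    if not np.all(np.isfinite(params)):
        raise DomainError(f"non-finite parameters for {model_id}: {params}")
    d = np.asarray(dbh, dtype=float)
    scalar = d.ndim == 0
    if not np.all(np.isfinite(d)):
        raise DomainError("non-finite DBH input")
    if np.any(d < 0):
        raise DomainError("DBH must be non-negative (cm)")
    if model_id == "gompertz" and np.any(d + params[2] == 0.0):
        raise DomainError("gompertz undefined where DBH + c = 0")
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        h = _eval(model_id, params, d)
    return float(h) if scalar else h
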