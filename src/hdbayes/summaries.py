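"""Fit-result containers shared by the classical and Bayesian fitters."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ValidationError

METHODS = ("classical", "bayes_uninformative", "bayes_informative")


@dataclass(frozen=True)
class ParamEstimate:
    """Point estimate with uncertainty and a 95% interval.

    ``sd`` is the standard error for classical fits and the posterior SD
    for Bayesian fits; the interval is Wald (classical) or equal-tailed
    credible (Bayesian).
    """

    mean: float
    sd: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        tol = 1e-9 * max(1.0, abs(self.mean))  # float slack for degenerate chains
        if not self.ci_low - tol <= self.mean <= self.ci_high + tol:
            raise ValidationError(
                f"interval [{self.ci_low}, {self.ci_high}] must bracket "
                f"the mean {self.mean}"
            )

    @property
    def width(self) -> float:
        return self.ci_high - self.ci_low


@dataclass
class FitSummary:
    """One model x method fit: estimates, intervals, fit statistics."""

    method: str
    model_id: str
    estimates: dict[str, ParamEstimate]
    fit_stats: dict[str, float] = field(default_factory=dict)
    n_obs: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        if "rmse" in self.fit_stats and self.fit_stats["rmse"] < 0:
            raise ValidationError("rmse must be non-negative")
        if "fit_index" in self.fit_stats and self.fit_stats["fit_index"] > 1:
            raise ValidationError("fit index cannot exceed 1")

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(self.estimates)

    @property
    def point_estimates(self) -> tuple[float, ...]:
        return tuple(e.mean for e in self.estimates.values())

    def to_frame(self) -> pd.DataFrame:
        """One row per parameter, published-table style."""
        rows = [
            {
                "method": self.method,
                "model": self.model_id,
                "parameter": name,
                "mean": e.mean,
                "sd": e.sd,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
            }
            for name, e in self.estimates.items()
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "model_id": self.model_id,
            "n_obs": self.n_obs,
            "estimates": {
                name: {
                    "mean": e.mean,
                    "sd": e.sd,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                }
                for name, e in self.estimates.items()
            },
            "fit_stats": dict(self.fit_stats),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitSummary":
        return cls(
            method=d["method"],
            model_id=d["model_id"],
            estimates={
                name: ParamEstimate(**vals) for name, vals in d["estimates"].items()
            },
            fit_stats=dict(d["fit_stats"]),
            n_obs=int(d["n_obs"]),
        )
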