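"""Sequential Bayesian updating between measurement campaigns.

The posterior from an earlier campaign is converted into an informative
prior for the next one by independent-normal moment matching: each
parameter's new prior is N(posterior mean, posterior SD).  Posterior
correlations between parameters are deliberately discarded so the prior
stays expressible as an independent :class:`~hdbayes.bayes.PriorSpec`;
the noise prior is reset to the vague default, since the residual
variance of a new campaign is not assumed known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import (
    DEFAULT_NOISE_PRIOR,
    MCMCChains,
    MCMCConfig,
    PriorSpec,
    run_mcmc,
    summarize_posterior,
)
from .classical import fit_nls
from .datasets import TreeDataset
from .evaluation import fit_statistics, interval_width_reduction
from .exceptions import DegeneratePriorError, HDBayesError, ValidationError
from .summaries import FitSummary


def posterior_to_prior(chains: MCMCChains) -> PriorSpec:
    """Moment-match an MCMC posterior into an independent-normal prior."""
    pooled = chains.pooled()
    if not np.all(np.isfinite(pooled)):
        raise ValidationError("chains contain non-finite draws")
    params = {}
    for j, name in enumerate(chains.param_names):
        mean = float(pooled[:, j].mean())
        sd = float(pooled[:, j].std(ddof=1))
        if sd == 0.0:
            raise DegeneratePriorError(
                f"posterior for {name!r} has zero variance; cannot form a prior"
            )
        params[name] = (mean, sd)
    return PriorSpec(
        params=params,
        noise_shape=DEFAULT_NOISE_PRIOR[0],
        noise_rate=DEFAULT_NOISE_PRIOR[1],
        kind="informative",
    )


@dataclass
class SequentialResult:
    """Everything the two-campaign comparison produces."""

    classical: FitSummary
    bayes_uninformative: FitSummary
    bayes_informative: FitSummary
    chains_uninformative: MCMCChains
    chains_informative: MCMCChains
    chains_campaign1: MCMCChains
    informative_prior: PriorSpec

    def summaries(self) -> tuple[FitSummary, FitSummary, FitSummary]:
        return (self.classical, self.bayes_uninformative, self.bayes_informative)

    def comparison_table(self) -> pd.DataFrame:
        """Method x parameter table of estimates and 95% intervals."""
        return pd.concat(
            [s.to_frame() for s in self.summaries()], ignore_index=True
        )

    def narrowing_vs_classical(self) -> pd.DataFrame:
        """Percent interval narrowing of each Bayesian method vs classical."""
        rows = []
        for s in (self.bayes_uninformative, self.bayes_informative):
            for name, est in s.estimates.items():
                ref = self.classical.estimates[name]
                rows.append(
                    {
                        "method": s.method,
                        "parameter": name,
                        "narrowing_pct": interval_width_reduction(
                            (ref.ci_low, ref.ci_high), (est.ci_low, est.ci_high)
                        ),
                    }
                )
        return pd.DataFrame(rows)


def _stage(label, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except HDBayesError as exc:
        raise type(exc)(f"[stage {label}] {exc}") from exc


def run_sequential_pipeline(
    dataset1: TreeDataset,
    dataset2: TreeDataset,
    model_id: str,
    config: MCMCConfig | None = None,
    rmse_denominator: str = "n-p",
) -> SequentialResult:
    """Full two-campaign comparison for one model form.

    Stages: (1) NLS on campaign 2; (2) MCMC on campaign 2 under the
    vague prior; (3) MCMC on campaign 1 under the vague prior,
    moment-matched into an informative prior; (4) MCMC on campaign 2
    under that informative prior.
    """
    config = config or MCMCConfig()
    classical = _stage(
        "classical-campaign2", fit_nls, dataset2, model_id,
        rmse_denominator=rmse_denominator,
    )

    chains_u = _stage("bayes-uninformative-campaign2", run_mcmc,
                      dataset2, model_id, config=config)
    chains_1 = _stage("bayes-campaign1", run_mcmc,
                      dataset1, model_id, config=config.with_seed(config.seed + 1))
    prior_inf = _stage("posterior-to-prior", posterior_to_prior, chains_1)
    chains_i = _stage("bayes-informative-campaign2", run_mcmc,
                      dataset2, model_id, prior=prior_inf,
                      config=config.with_seed(config.seed + 2))

    summaries = []
    for label, chains in (
        ("summarize-uninformative", chains_u),
        ("summarize-informative", chains_i),
    ):
        s = _stage(label, summarize_posterior, chains)
        s.fit_stats = fit_statistics(dataset2, s, denominator=rmse_denominator)
        s.n_obs = dataset2.n
        summaries.append(s)

    return SequentialResult(
        classical=classical,
        bayes_uninformative=summaries[0],
        bayes_informative=summaries[1],
        chains_uninformative=chains_u,
        chains_informative=chains_i,
        chains_campaign1=chains_1,
        informative_prior=prior_inf,
    )
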