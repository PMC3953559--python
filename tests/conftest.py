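"""Shared fixtures.

The expensive Monte-Carlo studies (parameter-recovery replicates and the
paired-campaign prior-updating replicates) are session-scoped so the
several tests that look at different aspects of the same experiment run
it only once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

import hdbayes as hb

#: Desk-scale MCMC protocol used across the simulation studies.
DESK_MCMC = dict(n_iterations=30_000, n_burn_in=5_000, thin=3, n_chains=2)


@pytest.fixture(scope="session")
def data1_dataset() -> hb.TreeDataset:
    """One frozen first-campaign-like synthetic stand (n=445)."""
    return hb.generate_dataset(hb.data1_like(seed=1))


@pytest.fixture(scope="session")
def noiseless_weibull() -> tuple[hb.TreeDataset, tuple[float, ...]]:
    cfg = hb.data1_like(seed=3, sigma=0.0)
    return hb.generate_dataset(cfg), cfg.true_params


@dataclass
class RecoveryReplicate:
    true_params: tuple[float, ...]
    nls: hb.FitSummary
    posterior: hb.FitSummary
    rhats: dict[str, float]


@pytest.fixture(scope="session")
def recovery_study() -> list[RecoveryReplicate]:
    """Twenty first-campaign-like replicates fitted by NLS and MCMC.

    Uses the desk-scale MCMC protocol with the true Weibull curve
    (a, b, c) = (26.58, 0.07, 0.85) and residual SD 1.155 m.
    """
    reps = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(20):
            cfg = hb.data1_like(seed=1000 + i)
            ds = hb.generate_dataset(cfg)
            nls = hb.fit_nls(ds, "weibull")
            chains = hb.run_mcmc(
                ds, "weibull", config=hb.MCMCConfig(seed=2000 + i, **DESK_MCMC)
            )
            post = hb.summarize_posterior(chains, check_convergence=False)
            reps.append(
                RecoveryReplicate(
                    true_params=cfg.true_params,
                    nls=nls,
                    posterior=post,
                    rhats=hb.gelman_rubin(chains),
                )
            )
    return reps


@dataclass
class PairedReplicate:
    uninformative: hb.FitSummary
    informative: hb.FitSummary
    band_width_uninformative: float
    band_width_informative: float


@pytest.fixture(scope="session")
def paired_campaign_study() -> list[PairedReplicate]:
    """Twenty paired-campaign replicates of the posterior-as-prior update."""
    grid = np.linspace(8.0, 32.0, 13)
    reps = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(20):
            d1, d2 = hb.generate_paired_campaigns(
                hb.data1_like(seed=5000 + i), hb.data2_like(seed=6000 + i)
            )
            res = hb.run_sequential_pipeline(
                d1, d2, "weibull", config=hb.MCMCConfig(seed=7000 + i, **DESK_MCMC)
            )
            bu = hb.prediction_band(res.chains_uninformative, grid)
            bi = hb.prediction_band(res.chains_informative, grid)
            reps.append(
                PairedReplicate(
                    uninformative=res.bayes_uninformative,
                    informative=res.bayes_informative,
                    band_width_uninformative=float((bu.high - bu.low).mean()),
                    band_width_informative=float((bi.high - bi.low).mean()),
                )
            )
    return reps
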