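"""Bayesian estimation of the height-diameter forms by MCMC.

The sampler is an adaptive random-walk Metropolis-within-Gibbs scheme
written for transparency:

* the shape parameters move by a Gaussian random-walk Metropolis update
  whose proposal covariance is learned during burn-in from the chain's
  own history (Haario-style adaptive Metropolis, with a global scale
  tuned toward the dimension-appropriate acceptance rate) and frozen
  afterwards so the post-burn-in chain satisfies detailed balance;
* every one of the six forms is linear in its leading parameter ``a``
  (H = 1.3 + a * g(DBH; rest)), so with a Gaussian prior ``a`` has a
  conjugate normal full conditional and is updated by an exact Gibbs
  draw by default (``MCMCConfig.linear_gibbs``); a pure random-walk
  update for ``a`` is available for testing the Metropolis machinery;
* the noise precision tau = 1/sigma^2 is conjugate given the residuals
  and is updated by an exact Gibbs draw from its conditional gamma
  distribution.

The exact conditional for ``a`` matters in practice: the asymptote and
shape parameters of saturating growth curves are strongly correlated,
and a componentwise random walk alone traverses that ridge extremely
slowly.

Priors are independent Gaussians on the curve parameters (vague by
default: mean 0, variance 1000) and a vague Gamma(0.001, 0.001) on tau,
the conventional choice in BUGS-style nonlinear regression.  The model
likelihood is Gaussian: H_i ~ N(f(DBH_i; theta), sigma^2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import TreeDataset
from .exceptions import (
    DomainError,
    MixingWarning,
    ValidationError,
)
from .models import BREAST_HEIGHT, _eval, get_model
from .summaries import FitSummary, ParamEstimate

#: Vague gamma prior on the noise precision.
DEFAULT_NOISE_PRIOR = (0.001, 0.001)


@dataclass(frozen=True)
class PriorSpec:
    """Independent Gaussian priors per curve parameter + gamma noise prior.

    ``params`` maps parameter name -> (mean, sd).  ``noise_shape`` and
    ``noise_rate`` parameterise the gamma prior on tau = 1/sigma^2.
    ``kind`` records whether the prior is vague or carries information
    from an earlier fit.
    """

    params: dict[str, tuple[float, float]]
    noise_shape: float = DEFAULT_NOISE_PRIOR[0]
    noise_rate: float = DEFAULT_NOISE_PRIOR[1]
    kind: str = "uninformative"

    def __post_init__(self):
        for name, (_, sd) in self.params.items():
            if sd <= 0:
                raise ValidationError(f"prior sd for {name!r} must be positive")
        if self.noise_shape <= 0 or self.noise_rate <= 0:
            raise ValidationError("gamma noise prior needs positive shape and rate")

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(self.params)

    def means(self) -> np.ndarray:
        return np.array([m for m, _ in self.params.values()])

    def sds(self) -> np.ndarray:
        return np.array([s for _, s in self.params.values()])

    def to_dict(self) -> dict:
        return {
            "params": {k: list(v) for k, v in self.params.items()},
            "noise_shape": self.noise_shape,
            "noise_rate": self.noise_rate,
            "kind": self.kind,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(
            params={k: tuple(v) for k, v in d["params"].items()},
            noise_shape=d.get("noise_shape", DEFAULT_NOISE_PRIOR[0]),
            noise_rate=d.get("noise_rate", DEFAULT_NOISE_PRIOR[1]),
            kind=d.get("kind", "uninformative"),
        )


def uninformative_prior(model_id: str, variance: float = 1000.0) -> PriorSpec:
    """Vague N(0, variance) prior on every parameter of a model form."""
    spec = get_model(model_id)
    sd = math.sqrt(variance)
    return PriorSpec(params={p: (0.0, sd) for p in spec.param_names})


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    The defaults are a desk-scale surrogate (30 000 iterations, 5 000
    burn-in, thin 3, two chains) for the production-scale 300 000 /
    20 000 / 3 protocol, which remains available by overriding the
    fields.
    """

    n_iterations: int = 30_000
    n_burn_in: int = 5_000
    thin: int = 3
    n_chains: int = 2
    seed: int = 0
    target_accept: float | None = None  # default: 0.44/0.35/0.32 for d=1/2/3
    adapt_interval: int = 50
    linear_gibbs: bool = True

    def __post_init__(self):
        if not 0 <= self.n_burn_in < self.n_iterations:
            raise ValidationError("need 0 <= n_burn_in < n_iterations")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValidationError("n_chains must be >= 1")
        if self.target_accept is not None and not 0 < self.target_accept < 1:
            raise ValidationError("target_accept must lie in (0, 1)")

    @property
    def n_retained(self) -> int:
        """Retained draws per chain: floor((iterations - burn-in)/thin)."""
        return (self.n_iterations - self.n_burn_in) // self.thin

    def with_seed(self, seed: int) -> "MCMCConfig":
        return replace(self, seed=seed)


@dataclass
class MCMCChains:
    """Post-burn-in, thinned posterior draws.

    ``draws`` has shape (n_chains, n_retained, p + 1); the last column is
    sigma (residual SD, m), the rest follow ``param_names``.
    """

    draws: np.ndarray
    param_names: tuple[str, ...]
    model_id: str
    prior: PriorSpec
    config: MCMCConfig
    accept_rates: np.ndarray | None = None

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3:
            raise ValidationError("draws must be (chain, iteration, parameter)")
        if self.draws.shape[2] != len(self.param_names) + 1:
            raise ValidationError("last draw column must be sigma")
        if self.draws.size == 0:
            raise ValidationError("empty chains")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_retained(self) -> int:
        return self.draws.shape[1]

    def pooled(self) -> np.ndarray:
        """All chains stacked: (n_chains * n_retained, p + 1)."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def to_dataframe(self) -> pd.DataFrame:
        cols = list(self.param_names) + ["sigma"]
        frames = []
        for c in range(self.n_chains):
            df = pd.DataFrame(self.draws[c], columns=cols)
            df.insert(0, "iter", np.arange(self.n_retained))
            df.insert(0, "chain", c)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def log_likelihood(dataset: TreeDataset, model_id: str, params, sigma: float) -> float:
    """Gaussian log likelihood of the heights given curve parameters."""
    if sigma <= 0:
        raise DomainError("sigma must be positive")
    if dataset.n == 0:
        return 0.0
    with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
        pred = _eval(model_id, np.asarray(params, dtype=float), dataset.dbh)
    resid = dataset.height - pred
    sse = float(resid @ resid)
    n = dataset.n
    return -0.5 * n * math.log(2.0 * math.pi * sigma**2) - sse / (2.0 * sigma**2)


def log_posterior(
    dataset: TreeDataset,
    model_id: str,
    params_and_sigma,
    prior: PriorSpec,
) -> float:
    """Unnormalised log posterior: log likelihood + log priors.

    ``params_and_sigma`` stacks the curve parameters (in model order)
    with sigma last.  The noise prior is evaluated on the precision
    tau = 1/sigma^2.
    """
    spec = get_model(model_id)
    v = np.asarray(params_and_sigma, dtype=float)
    if v.size != spec.n_params + 1:
        raise ValidationError(
            f"expected {spec.n_params} parameters plus sigma, got {v.size}"
        )
    params, sigma = v[:-1], float(v[-1])
    if sigma <= 0:
        raise DomainError("sigma must be positive")
    ll = log_likelihood(dataset, model_id, params, sigma)
    means, sds = prior.means(), prior.sds()
    lp = float(np.sum(stats.norm.logpdf(params, means, sds)))
    tau = 1.0 / sigma**2
    lp += float(
        stats.gamma.logpdf(tau, a=prior.noise_shape, scale=1.0 / prior.noise_rate)
    )
    return ll + lp


def _default_init(dataset, model_id, prior):
    """NLS-based initial state and proposal scales; prior-based fallback."""
    spec = get_model(model_id)
    if dataset.n >= spec.n_params + 2 and np.ptp(dataset.dbh) > 0:
        try:
            from .classical import fit_nls

            nls = fit_nls(dataset, model_id)
            theta0 = np.array([nls.estimates[p].mean for p in spec.param_names])
            scales = np.array(
                [max(nls.estimates[p].sd, 1e-6) for p in spec.param_names]
            )
            sigma0 = max(nls.fit_stats["rmse"], 1e-6)
            return theta0, scales, sigma0
        except Exception:
            pass
    theta0 = prior.means().astype(float)
    scales = np.minimum(prior.sds(), np.abs(theta0) * 0.1 + 1.0)
    return theta0, scales, 1.0


def run_mcmc(
    dataset: TreeDataset,
    model_id: str,
    prior: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    init: np.ndarray | None = None,
    fixed: dict[str, float] | None = None,
    fixed_sigma: float | None = None,
) -> MCMCChains:
    """Sample the posterior of one model form.

    Chains are initialised at the NLS estimate when one is obtainable
    (otherwise at the prior means), jittered chain-to-chain so the
    Gelman-Rubin diagnostic is meaningful.  Identical seeds give
    identical chains.

    ``fixed`` holds named parameters at constant values and ``fixed_sigma``
    suppresses the noise update — useful for conjugate-oracle checks where
    part of the model is known.
    """
    spec = get_model(model_id)
    prior = prior if prior is not None else uninformative_prior(model_id)
    if tuple(prior.param_names) != spec.param_names:
        raise ValidationError(
            f"prior parameters {prior.param_names} do not match "
            f"{model_id} parameters {spec.param_names}"
        )
    config = config or MCMCConfig()
    fixed = dict(fixed or {})
    for name in fixed:
        if name not in spec.param_names:
            raise ValidationError(f"{model_id} has no parameter {name!r}")
    if fixed_sigma is not None and fixed_sigma <= 0:
        raise ValidationError("fixed_sigma must be positive")
    p = spec.n_params
    n = dataset.n
    dbh, height = dataset.dbh, dataset.height

    if init is not None:
        theta0 = np.asarray(init, dtype=float).copy()
        if theta0.size != p:
            raise ValidationError("init length must match parameter count")
        scales0 = np.abs(theta0) * 0.1 + 0.01
        sigma0 = fixed_sigma if fixed_sigma is not None else 1.0
    else:
        theta0, scales0, sigma0 = _default_init(dataset, model_id, prior)
        if fixed_sigma is not None:
            sigma0 = fixed_sigma
    for name, val in fixed.items():
        j = spec.param_names.index(name)
        theta0[j] = val
        scales0[j] = 0.0

    # `a` (index 0) enters every form linearly, so with its Gaussian prior
    # it can be integrated out of the Metropolis step for the shape
    # parameters and redrawn exactly afterwards (partially collapsed
    # Gibbs); this removes the notorious asymptote/shape ridge.
    collapse_a = config.linear_gibbs and "a" not in fixed
    mh_idx = [
        j for j, name in enumerate(spec.param_names)
        if name not in fixed and not (collapse_a and j == 0)
    ]
    pr_mean, pr_sd = prior.means(), prior.sds()
    pr_var2 = 2.0 * pr_sd**2
    a_m0 = pr_mean[0]
    a_v0 = pr_sd[0] ** 2  # prior variance of a
    a_prior_prec = 1.0 / a_v0
    shape_post = prior.noise_shape + 0.5 * n
    n_ret = config.n_retained
    draws = np.empty((config.n_chains, n_ret, p + 1))
    accept_rates = np.full((config.n_chains, p), np.nan)
    yc = height - BREAST_HEIGHT  # heights above breast height
    yy = float(yc @ yc)

    d = len(mh_idx)
    if config.target_accept is not None:
        target = config.target_accept
    else:
        target = {0: 0.44, 1: 0.44, 2: 0.35}.get(d, 0.32)

    def _basis_stats(theta):
        """g = f(dbh; rest)/a basis and its inner products with the data."""
        unit = theta.copy()
        unit[0] = 1.0
        with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
            g = _eval(model_id, unit, dbh) - BREAST_HEIGHT
        return float(g @ g), float(g @ yc)

    def _marginal_loglik(gg, gr, tau):
        """log p(y | shapes, tau) with a integrated out (constants dropped).

        y - 1.3 ~ N(m0 g, tau^{-1} I + v0 g g'); Woodbury/determinant
        lemma reduce everything to the scalars gg = g'g and gr = g'y.
        """
        denom = 1.0 + tau * a_v0 * gg
        rr = yy - 2.0 * a_m0 * gr + a_m0**2 * gg  # ||y - m0 g||^2
        gr_c = gr - a_m0 * gg  # g'(y - m0 g)
        quad = tau * rr - (tau * a_v0) * (tau * gr_c**2) / denom
        return -0.5 * (math.log(denom) + quad)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    for chain in range(config.n_chains):
        rng = np.random.default_rng(seeds[chain])
        # jitter the start (chain 0 keeps the centre) for R-hat validity
        theta = theta0 + (rng.normal(0.0, scales0) if chain else 0.0)
        with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
            pred = _eval(model_id, theta, dbh)
        resid = height - pred
        sse = float(resid @ resid)
        if not np.isfinite(sse):
            raise ValidationError(
                f"non-finite log posterior at the initial state {theta}"
            )
        tau = 1.0 / sigma0**2
        if collapse_a:
            gg, gr = _basis_stats(theta)
            if not (np.isfinite(gg) and np.isfinite(gr)):
                raise ValidationError(
                    f"non-finite basis at the initial state {theta}"
                )
        chol = np.diag(scales0[mh_idx]) if d else None
        lam = 1.0
        hist = np.empty((config.n_burn_in, d))
        mh_mean = pr_mean[mh_idx]
        mh_var2 = pr_var2[mh_idx]
        acc_total = 0.0
        acc_window = 0.0

        n_iter = config.n_iterations
        block = 2000
        t_in_block = block  # force initial fill
        k = 0  # retained index
        for t in range(n_iter):
            if t_in_block == block:
                z = rng.standard_normal((block, p))
                logu = np.log(rng.random(block))
                zg = rng.standard_normal(block)
                gamma_std = rng.standard_gamma(shape_post, block)
                t_in_block = 0
            if d:
                old = theta[mh_idx].copy()
                prop = old + lam * (chol @ z[t_in_block, :d])
                theta[mh_idx] = prop
                dprior = -float(
                    np.sum(((prop - mh_mean) ** 2 - (old - mh_mean) ** 2) / mh_var2)
                )
                if collapse_a:
                    gg_new, gr_new = _basis_stats(theta)
                    ok = np.isfinite(gg_new) and np.isfinite(gr_new)
                    if ok:
                        dlp = (
                            _marginal_loglik(gg_new, gr_new, tau)
                            - _marginal_loglik(gg, gr, tau)
                            + dprior
                        )
                    if ok and logu[t_in_block] < dlp:
                        gg, gr = gg_new, gr_new
                        acc_total += 1
                        acc_window += 1
                    else:
                        theta[mh_idx] = old
                else:
                    with np.errstate(
                        invalid="ignore", over="ignore", divide="ignore"
                    ):
                        pred_new = _eval(model_id, theta, dbh)
                    r = height - pred_new
                    sse_new = float(r @ r)
                    dlp = -0.5 * tau * (sse_new - sse) + dprior
                    if np.isfinite(sse_new) and logu[t_in_block] < dlp:
                        sse = sse_new
                        acc_total += 1
                        acc_window += 1
                    else:
                        theta[mh_idx] = old
                if t < config.n_burn_in:
                    hist[t] = theta[mh_idx]
            if collapse_a:
                # exact draw from a | shapes, tau (linear-Gaussian conditional)
                prec = tau * gg + a_prior_prec
                mean = (tau * gr + a_m0 * a_prior_prec) / prec
                theta[0] = mean + zg[t_in_block] / math.sqrt(prec)
                sse = max(yy - 2.0 * theta[0] * gr + theta[0] ** 2 * gg, 0.0)
            if fixed_sigma is None:
                # conjugate Gibbs step for the precision
                tau = max(
                    gamma_std[t_in_block] / (prior.noise_rate + 0.5 * sse), 1e-300
                )
            t_in_block += 1

            if t < config.n_burn_in:
                if (t + 1) % config.adapt_interval == 0 and d:
                    rate = acc_window / config.adapt_interval
                    lam *= math.exp(rate - target)
                    acc_window = 0.0
                    if t + 1 >= 10 * config.adapt_interval:
                        # learn the proposal shape from the recent history
                        lo = (t + 1) // 3
                        cov = np.cov(hist[lo : t + 1].T).reshape(d, d)
                        cov = cov * (2.38**2 / d) + 1e-12 * np.eye(d)
                        try:
                            chol = np.linalg.cholesky(cov)
                        except np.linalg.LinAlgError:
                            pass
            else:
                s = t - config.n_burn_in
                if s % config.thin == config.thin - 1:
                    draws[chain, k, :p] = theta
                    draws[chain, k, p] = 1.0 / math.sqrt(tau)
                    k += 1
        assert k == n_ret
        if d:
            accept_rates[chain, mh_idx] = acc_total / config.n_iterations

    chains = MCMCChains(
        draws=draws,
        param_names=spec.param_names,
        model_id=model_id,
        prior=prior,
        config=config,
        accept_rates=accept_rates,
    )
    with np.errstate(invalid="ignore"):
        low = accept_rates < 0.01  # NaN (Gibbs/fixed parameters) compares False
    if np.any(low):
        warnings.warn(
            f"acceptance rate below 1% for {model_id}; chains may be stuck",
            MixingWarning,
        )
    return chains


def summarize_posterior(chains: MCMCChains, check_convergence: bool = True) -> FitSummary:
    """Pooled posterior mean, SD and equal-tailed 95% credible interval.

    With two or more chains a split Gelman-Rubin check runs first and a
    :class:`MixingWarning` is raised if any R-hat exceeds 1.1.
    """
    if check_convergence and chains.n_chains >= 2:
        rhats = gelman_rubin(chains)
        bad = {k: v for k, v in rhats.items() if v > 1.1}
        if bad:
            warnings.warn(f"R-hat above 1.1: {bad}", MixingWarning)
    pooled = chains.pooled()
    names = list(chains.param_names) + ["sigma"]
    ests = {}
    for j, name in enumerate(names):
        col = pooled[:, j]
        lo, hi = np.quantile(col, [0.025, 0.975])
        ests[name] = ParamEstimate(
            mean=float(col.mean()),
            sd=float(col.std(ddof=1)),
            ci_low=float(lo),
            ci_high=float(hi),
        )
    sigma_est = ests.pop("sigma")
    summary = FitSummary(
        method=f"bayes_{chains.prior.kind}",
        model_id=chains.model_id,
        estimates=ests,
        n_obs=0,
    )
    summary.sigma = sigma_est
    return summary


def compute_dic(chains: MCMCChains, dataset: TreeDataset):
    """Deviance information criterion from the retained draws.

    D(theta) = -2 log p(y | theta, sigma); Dbar is its posterior mean,
    Dhat the deviance at the posterior mean of (theta, sigma),
    pD = Dbar - Dhat the effective number of parameters, and
    DIC = Dbar + pD.  Returns (dbar, dhat, pd, dic).
    """
    if dataset.n == 0:
        raise ValidationError("DIC needs a non-empty dataset")
    theta = chains.pooled()
    p = len(chains.param_names)
    n = dataset.n
    cols = [theta[:, j][:, None] for j in range(p)]
    with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
        pred = _eval(chains.model_id, cols, dataset.dbh[None, :])
    sse = np.sum((dataset.height[None, :] - pred) ** 2, axis=1)
    sigma2 = theta[:, p] ** 2
    dev = n * np.log(2.0 * np.pi * sigma2) + sse / sigma2
    dbar = float(np.mean(dev))
    mean_vec = theta.mean(axis=0)
    dhat = -2.0 * log_likelihood(
        dataset, chains.model_id, mean_vec[:p], float(mean_vec[p])
    )
    pd_ = dbar - dhat
    return dbar, dhat, pd_, dbar + pd_


def gelman_rubin(chains: MCMCChains) -> dict[str, float]:
    """Classic split-R-hat per parameter (sigma included).

    Each chain is split in half, so a single long chain that drifts is
    caught as well as disagreement between chains.  Values near 1
    indicate convergence; above ~1.1 is conventionally suspect.
    """
    if chains.n_chains < 2:
        raise ValidationError("Gelman-Rubin needs at least two chains")
    names = list(chains.param_names) + ["sigma"]
    half = chains.n_retained // 2
    if half < 2:
        raise ValidationError("chains too short to split")
    out = {}
    for j, name in enumerate(names):
        segs = []
        for c in range(chains.n_chains):
            col = chains.draws[c, : 2 * half, j]
            segs.append(col[:half])
            segs.append(col[half:])
        segs = np.asarray(segs)  # (2C, half)
        w = float(np.mean(np.var(segs, axis=1, ddof=1)))
        b = half * float(np.var(segs.mean(axis=1), ddof=1))
        if w == 0.0:
            out[name] = 1.0 if b == 0.0 else float("inf")
            continue
        var_hat = (half - 1) / half * w + b / half
        out[name] = float(np.sqrt(var_hat / w))
    return out
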