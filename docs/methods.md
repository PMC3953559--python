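# Methods

## Model

Tree height is modelled as
`H_i = f(DBH_i; θ) + ε_i`, `ε_i ~ N(0, σ²)` i.i.d.,
where `f` is one of six allometric forms (Chapman-Richards, Weibull,
logistic, Gompertz, Bertalanffy, power-law), each including the
additive 1.3 m breast-height offset. DBH is in cm, height in m. The
Gompertz form is kept in its published decaying-exponential
parameterisation `H = 1.3 + a·exp(b/(DBH + c))`, which fits with
negative `b`; no positivity constraints are imposed on any parameter,
matching the unconstrained Gaussian priors below.

For the four saturating three-parameter forms and Bertalanffy, `a` is
the asymptotic height above breast height; `b` and `c` control rate and
shape. Bertalanffy and the power law have two parameters, the rest
three.

## Classical fit

`fit_nls` minimises the residual sum of squares with a
Levenberg–Marquardt least-squares solver. Starting values come from a
deterministic, form-specific grid anchored at the tallest observed tree
(e.g. `a ∈ {max H, 1.5·max H}`, Weibull/Chapman-Richards
`b ∈ {0.01, 0.05, 0.1}`, `c ∈ {0.5, 1, 2}`; scale-appropriate values
for the logistic, Gompertz and power-law forms). The SSE is screened at
every grid point and the optimizer launched from the best three, so the
returned optimum is never worse than any start. Standard errors use the
asymptotic covariance `s²(JᵀJ)⁻¹` with `s² = SSE/(n−p)`; 95% intervals
are Wald intervals with a `t_{n−p}` critical value. The reported RMSE
is `sqrt(SSE/(n−p))` by default (`rmse_denominator="n"` switches to the
plain root mean square; the two are linked by `√(n/(n−p))`).

## Priors

Vague priors are independent `N(0, 1000)` on each curve parameter —
1000 is a *variance*, following the precision convention of BUGS-style
software — and `Gamma(0.001, 0.001)` on the precision `τ = 1/σ²`.
Informative priors are built by `posterior_to_prior`: independent
normals moment-matched to the previous campaign's posterior means and
SDs. Posterior correlations are deliberately discarded so the prior
stays expressible as an independent `PriorSpec`; the noise prior is
always reset to the vague default because the new campaign's residual
variance is not assumed known.

## Sampler

`run_mcmc` is a partially collapsed Metropolis-within-Gibbs scheme:

1. **Shape parameters** (`b`, and `c` where present) move jointly by a
   Gaussian random walk whose target is the posterior with `a`
   *analytically integrated out*. Every form is linear in `a`
   (`H − 1.3 = a·g(DBH; shapes)`), so with the Gaussian prior on `a`
   the marginal likelihood given (shapes, τ) is available in closed
   form via the Woodbury identity, reducing to the scalars `gᵀg` and
   `gᵀ(y − 1.3)`. Collapsing `a` removes the long asymptote/shape
   ridge on which a componentwise random walk mixes pathologically
   (effective sample sizes of a few draws out of ~17 000 retained).
2. **`a`** is then redrawn exactly from its normal full conditional,
   and
3. **τ** from its conjugate Gamma conditional
   `Gamma(α₀ + n/2, β₀ + SSE/2)`.

The proposal covariance for step 1 is learned during burn-in from the
chain's own history (Haario-style, scaled by `2.38²/d`), with a global
scale factor tuned toward the dimension-appropriate acceptance rate
(0.44 univariate, 0.35 bivariate); all adaptation freezes at the end of
burn-in so the retained chain satisfies detailed balance. Updating
shapes from the `a`-marginal and immediately redrawing `a` from its
exact conditional is a valid partially collapsed Gibbs sweep. The
sampler was validated against exact grid integration of the Weibull
(b, c, τ) posterior at n = 445 (means and SDs agree to ~1%) and against
closed-form conjugate posteriors in linear special cases.

A plain random-walk path (`MCMCConfig(linear_gibbs=False)`) updates all
free parameters by the adaptive Metropolis step with no collapsing; the
detailed-balance and conjugate-oracle tests run in this mode so the
Metropolis machinery is itself exercised. `fixed=` and `fixed_sigma=`
hold parameters or the noise SD at known values for such checks.

Chains are initialised at the NLS estimate (prior means when no fit is
possible, e.g. prior-only runs), jittered across chains at the scale of
the NLS standard errors so the Gelman–Rubin diagnostic is meaningful.
Identical seeds give identical chains; per-chain streams are spawned
from one `SeedSequence`.

### Protocol sizes

The production-scale protocol for this kind of analysis is 300 000
iterations with 20 000 burn-in and thinning 3. The package default —
and the size used throughout the tests, analysis scripts and
`scripts/acceptance.py` — is a desk-scale surrogate of 30 000
iterations, 5 000 burn-in, thin 3, two chains, which the collapsed
sampler's mixing makes sufficient (split R̂ ≈ 1.00, minimum effective
sample sizes in the thousands). The model-selection replication study
uses further-reduced single-chain runs (6 000/1 000/thin 3) per
replicate. Retained draws per chain are
`floor((iterations − burn-in)/thin)`, keeping every thin-th
post-burn-in state.

## Evaluation

* `rmse`, `mean_deviation` (signed, predicted − observed), and
  `fit_index = 1 − SSE/SST` (the nonlinear R² analogue; the exact
  formula is fixed here by convention since several conventions
  circulate).
* `DIC = D̄ + p_D`, `p_D = D̄ − D(θ̄)`, with the deviance
  `D(θ) = −2 log p(y|θ, σ)` evaluated at every retained draw (σ
  included) and `D(θ̄)` at the posterior mean of (θ, σ). Note that on
  strongly curved ("banana") posteriors — the Weibull and
  Chapman-Richards forms under vague priors — the posterior mean can
  lie off the ridge, making `p_D` negative. This is a known DIC
  pathology, reproduced here deliberately; ranking by DIC still
  recovers the true form in the simulation study.
* `interval_width_reduction` = `100·(1 − width(comparison)/width(reference))`,
  reported at one decimal and, where a published figure does so, at the
  nearest integer (58.7% → 59%).
* `rank_models` sorts ascending by RMSE or DIC with deterministic
  tie-breaks (fewer parameters, then lexicographic id).
* `prediction_band` gives pointwise equal-tailed bands: quantiles of
  the curve over posterior draws (`mean_curve`, the default —
  consistent with published band widths that are far smaller than the
  residual SD), optionally with per-draw Gaussian noise added
  (`predictive`); classical bands use the delta method with a `t_{n−p}`
  critical value.

## Synthetic data

The generator emulates the two published campaigns: DBH from a normal
distribution truncated to the observed range (campaign 1:
mean 15.73, SD 4.28, range [6.7, 31.5] cm, n = 445; campaign 2:
mean 16.41, SD 4.40, range [7.5, 32.4] cm, n = 424 — the simplest
unimodal distribution matching all four published summary statistics),
and heights from a chosen true curve plus homoscedastic Gaussian noise.
Defaults: Weibull truth (a, b, c) = (26.58, 0.07, 0.85) — the published
campaign-1 posterior means — and σ = 1.155 m, the published root MSE.
Noise draws giving non-positive heights are redrawn (vanishingly rare
at this σ).

What the generator does **not** emulate: spatial plot structure and the
five planting-density treatments (trees are pooled), repeated measures
on the same trees across campaigns, heteroscedastic or skewed height
errors, and DBH measurement error. Passing tests therefore demonstrate
the estimators' behaviour under the stated error model at the published
sample sizes, not robustness to those real-data features.

## Numerical choices and degenerate inputs

* Out-of-domain parameter combinations (negative Chapman-Richards base
  with non-integer exponent, Gompertz pole at DBH + c = 0) evaluate to
  NaN/±inf inside the sampler and are rejected as proposals; the public
  `predict_height` validates and raises instead.
* τ draws are floored at 1e−300 so prior-only runs with a near-zero
  gamma shape cannot produce σ = ∞.
* Zero-variance chains: summaries return degenerate intervals
  `[v, v]`; `posterior_to_prior` refuses them (a normal prior needs a
  positive SD).
* Datasets: DBH and heights must be positive and finite; fitting
  requires `n ≥ p + 2` and non-constant DBH. Empty datasets are
  accepted by the sampler (posterior = prior) but not by the fitters.
* Multi-chain summaries warn (`MixingWarning`) when any split R̂
  exceeds 1.1; the CLI turns that warning into exit code 3.

## What the simulation studies can and cannot show

* **Parameter recovery / interval tightening** (Weibull truth,
  σ = 1.155 m, n = 445/424): credible intervals cover the true
  parameters at near-nominal rates, vague-prior posterior means track
  the NLS estimates, and the carried-forward prior tightens every
  parameter's interval in almost all paired replicates. These checks
  pass and are asserted in the test suite.
* **The asymptote is weakly identified.** With trees only up to
  ~32 cm DBH, the likelihood along the (a, b) ridge is nearly flat: in
  ~7% of replicates the *global* SSE optimum has `a` in the hundreds
  (verified by restarting the optimizer at the truth — it converges to
  the same ridge solution with lower SSE). The NLS estimator of `a` is
  therefore consistent but heavy-tailed: its replicate *median*
  recovers the truth to under 1% while its mean does not, and its Wald
  interval covers at ~90% rather than 95%. The Bayesian posterior
  shows the same geometry as a long right tail on `a`.
* **Model selection among the sigmoids is not reproducible at these
  conditions.** When data are generated from the Weibull curve at this
  noise level and diameter range, the Weibull, Chapman-Richards and
  Gompertz fits are statistically indistinguishable (mean RMSEs agree
  to four decimals), so RMSE ranks the true form first only about a
  third of the time — a three-way coin flip. DIC does no better: its
  plug-in term D(θ̄) is evaluated at a posterior mean that falls off
  the curved ridge whenever the asymptote tail is explored, producing
  replicate-to-replicate DIC swings orders of magnitude larger than
  any real model separation. The corresponding selection test is
  retained at its stated threshold and fails; the clearly misspecified
  forms (Bertalanffy, power-law, logistic) *are* reliably ranked below
  the sigmoids in every replicate.

## Known limitations

* The informative prior ignores posterior correlations between
  parameters; a multivariate-normal prior would carry strictly more
  information but cannot be expressed in the independent `PriorSpec`
  format.
* DIC's plug-in point is the posterior mean; no median/mode variant is
  provided, so `p_D` can be negative on curved posteriors (above).
* Single-level analysis only: no hierarchical site/age/density
  extensions, no repeated-measures correlation, no heteroscedastic
  error options.
* Wald intervals for the classical fit (profile-likelihood intervals
  are not implemented); for the weakly identified asymptote the Wald
  interval can be optimistic relative to the likelihood surface.
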