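# hdbayes — Bayesian and classical height–diameter modelling

Foresters measure diameter at breast height (DBH, cm) on every tree but
total height (m) only on a subsample: height–diameter (H–D) curves fill
in the missing heights that volume, site-index, biomass and carbon
estimates depend on. This package implements a complete H–D analysis
for repeated inventory campaigns, built around a Chinese-fir
(*Cunninghamia lanceolata*) case with two campaigns two years apart:

* six standard allometric forms, all offset by the 1.3 m breast height,
  e.g. the Weibull curve `H = 1.3 + a(1 − exp(−b·DBH^c))` alongside
  Chapman-Richards, logistic, Gompertz, Bertalanffy and power-law;
* classical nonlinear least squares (multistart Levenberg–Marquardt,
  Wald 95% confidence intervals from `s²(JᵀJ)⁻¹`);
* a from-scratch MCMC sampler for the Bayesian fit
  `p(θ, τ | y) ∝ p(y | θ, τ) p(θ) p(τ)` with Gaussian priors on the
  curve parameters and a vague Gamma(0.001, 0.001) prior on the noise
  precision τ = 1/σ². Every form is linear in its leading parameter
  `a`, so `a` and τ get exact conjugate Gibbs updates and the shape
  parameters move by an adaptive random-walk Metropolis step with `a`
  integrated out (partially collapsed Gibbs);
* model comparison by RMSE, mean deviation, fit index (1 − SSE/SST) and
  DIC = D̄ + p_D with p_D = D̄ − D(θ̄);
* sequential updating: the campaign-1 posterior is moment-matched into
  independent normal priors for campaign 2, which narrows credible
  intervals and prediction bands relative to both the vague-prior and
  classical fits;
* a synthetic-data generator emulating the two campaigns (truncated-
  normal DBH matched to the published summary statistics, Gaussian
  height noise around a chosen true curve), since the original tree
  measurements were never deposited.

## Worked example

```python
import hdbayes as hb

# two synthetic campaigns from the default Weibull truth
# (a, b, c) = (26.58, 0.07, 0.85), residual SD 1.155 m
d1, d2 = hb.generate_paired_campaigns(hb.data1_like(seed=1),
                                      hb.data2_like(seed=2))

fit = hb.fit_nls(d1, "weibull")
print({k: round(v.mean, 3) for k, v in fit.estimates.items()},
      round(fit.fit_stats["rmse"], 4))
# {'a': 23.0, 'b': 0.075, 'c': 0.904} 1.2119

res = hb.run_sequential_pipeline(d1, d2, "weibull",
                                 config=hb.MCMCConfig(seed=7))
print(res.narrowing_vs_classical().round(1))
#                 method parameter  narrowing_pct
# 0  bayes_uninformative         a         -104.5
# 1  bayes_uninformative         b            0.8
# 2  bayes_uninformative         c            3.6
# 3    bayes_informative         a            7.3
# 4    bayes_informative         b           38.1
# 5    bayes_informative         c           45.9
```

The NLS fit recovers the true curve within sampling error (the asymptote
`a` is weakly identified from trees below ~32 cm DBH, hence its wide
interval), and the RMSE estimates the 1.155 m noise SD. The
`narrowing_pct` column says how much narrower each Bayesian 95% interval
is than the classical one: the vague-prior posterior roughly matches the
classical intervals for `b` and `c` but carries a heavy right tail for
the weakly identified asymptote (hence the negative entry for `a`),
while the informative prior carried over from campaign 1 tightens every
parameter — and tightens all three relative to the vague-prior
posterior.

The same steps are available as narrative drivers under `analysis/`
(`01_simulate_campaigns.py` … `06_prediction_bands.py`), each writing
its tables under `results/`, and as CLI subcommands
(`hdbayes simulate | fit-classical | fit-bayes | sequential | compare`).

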