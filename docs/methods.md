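# Methods

## Model

For one municipality, monthly snakebite counts `y_t` (t = 1..T) are modelled
as Poisson with mean `e_t * exp(eta_t)`.  The offset `e_t = pop_t *
(sum y / sum pop)` scales population to expected counts, so it conserves the
total (`sum e = sum y`) and makes `exp` of every predictor term a relative
risk (RR) against the window-average rate.  The linear predictor is

```
eta_t = beta_0 + beta' x_t + omega_t + delta_t
```

with four mean-centred climate covariates (rainfall mm/month, specific
humidity g/kg, day and night land-surface temperature °C), an RW1 temporal
field `omega` (precision `tau_omega`) capturing smooth unexplained trend,
and iid noise `delta` (precision `tau_delta`) capturing month-to-month
overdispersion.  Covariates are centred but **not** standardised, so
`exp(beta_j)` is the RR per natural unit (per mm, per g/kg, per °C); the
centring constants are stored for back-transforming the intercept.

Priors: `beta_0, beta_j ~ N(0, 1000)` (read as variance); both precisions
get diffuse `Gamma(shape 1, rate 5e-5)` priors — the conventional diffuse
log-gamma-on-the-log-precision default — configurable in `ModelSpec`.

### Identifiability and constraints

The intrinsic RW1 prior is flat along the constant vector and `delta` is
exchangeable with the intercept at T points, so both fields carry
sum-to-zero constraints with a free intercept.  Rather than imposing the
constraints by a kriging correction, the package reparametrises each field
in the orthonormal Helmert basis `B` of the sum-zero subspace: the
constrained intrinsic RW1 is then exactly a proper Gaussian with full-rank
precision `tau_omega * B'QB` (Q the tridiagonal RW1 structure matrix), and
all Newton solves, log-determinants and conjugate Gibbs updates are
standard.  The equivalence is exact (the projection of the anchored
cumulative-sum walk has covariance `(B'QB)^-1`; a unit test verifies this),
and the rank `T-1` appears naturally in the Gibbs conditional
`tau | field ~ Gamma(a + (T-1)/2, b + quadratic/2)`.

## Fitting: nested Laplace scheme

1. For fixed `theta = (log tau_omega, log tau_delta)`, the latent
   conditional is maximised by Newton-Raphson with step halving
   (tolerance `1e-8` on the max update, max 50 iterations; failure raises
   with the iteration trace).  The negative Hessian at the mode gives the
   Gaussian approximation.  At this problem size (T <= 144, latent
   dimension ~291) dense Cholesky factorisations are faster than exploiting
   the band structure, so the implementation stays dense.
2. The Laplace-approximated hyper posterior
   `pi~(theta|y) = pi(y, zhat, theta) / pi_G(zhat|theta, y)` (including the
   log-precision Jacobian) is maximised by Nelder-Mead; its Hessian is
   estimated by central finite differences (step 0.1) and a regular grid —
   default 9x9 points spanning ±3 posterior sd along the Hessian
   eigen-axes — is weighted by the normalised `pi~` values.  A mode landing
   on the outer ring of the grid raises a boundary diagnostic.
   `grid_size=1` collapses to the empirical-Bayes fit at the hyper mode.
3. Latent marginals are finite Gaussian mixtures over the grid; means and
   sds come from mixture moments and quantiles from Brent inversion of the
   mixture CDF.  RR quantiles are `exp` of coefficient quantiles (exact, by
   monotonicity).  This is the simplified Gaussian marginal; no
   skewness-correction terms are applied — the scheme is validated against
   MCMC instead, which is the appropriate check at this scale.  The
   reported temporal trend is `exp(omega_t)` (the smooth component only);
   `trend_frame(include_iid=True)` switches to `exp(omega_t + delta_t)`
   using the per-grid-point cross-covariances.

Hyperparameter summaries are weighted-grid (discrete) moments and
quantiles; they are deliberately coarse — the precisions are nuisance
parameters here and their posteriors are heavy-tailed.

## MCMC cross-check

`fit_mcmc` runs an independent Metropolis-within-Gibbs sampler on the same
posterior: exact conjugate Gamma draws for the precisions; single-site
Gaussian random-walk Metropolis for the intercept and coefficients with
step scales auto-tuned to 20–40% acceptance during burn-in and then frozen;
one-block updates of each field proposing from a local Taylor-Gaussian
approximation of its full conditional with the exact MH correction
(both forward and reverse proposal densities are evaluated).  Defaults:
20,000 iterations, 5,000 burn-in — minutes on one CPU for T <= 144.
Split-chain R-hat and effective sample sizes come from `arviz`.

## Descriptive conventions

* Percentages use the full stratum denominator (all venomous cases in the
  study area), missing values included — the convention of the published
  registry tables; a flag switches to non-missing denominators.  Rounding
  is decimal half-up, matching printed tables, not banker's rounding.
* Cases are binned by notification month (the registry date field).
* Annual census populations apply uniformly to all 12 months of their year.
* The overall monthly incidence interval uses the closed-form posterior of
  a constant Poisson rate under the Jeffreys Gamma(1/2, 0) prior —
  `rate | data ~ Gamma(cases + 1/2, person-months)` — a deliberate,
  documented choice since no computation is specified for the published
  intervals.
* Nonvenomous accidents are removed before all analyses; the studied-area
  share is venomous cases in the four municipalities over *all* state
  reports.

## Synthetic-data generator

The generator emulates the study conditions with known ground truth:

* **Scenario defaults**: T = 144 months (2007–2018), one municipality with
  population 520,000 growing 1.2%/yr, reference rate 2.4 cases per 100,000
  person-months (the published overall Porto Velho level, giving realistic
  counts of ~12–15/month), true RRs of 1.10 per g/kg humidity and 0.95 per
  °C day temperature with null rainfall/night-temperature effects, and
  `tau_omega = tau_delta = 200`, inside the ranges reported for the fitted
  cities.
* **Climate**: one annual sinusoid per covariate plus Gaussian noise;
  rainfall is censored at zero.  Where city moments are published (rainfall
  Porto Velho 149.0/107.0 and Cacoal 142.0/116.0 mm; day temperature
  Cacoal 32.4/2.1 °C; night temperature Vilhena 19.9/1.0 °C) the presets
  are calibrated by a closed-form censored-moment solver so long-run sample
  moments reproduce them; all other presets (including all humidity levels,
  plausible 14–16 g/kg) are illustrative interpolations, not data.
* **Latent fields**: `omega` as a centred cumulative-sum walk (exactly the
  constrained RW1 law, see above); `delta` centred iid.
* **Line list**: each month's count expands into case rows whose attributes
  follow the published study-area composition (2655 venomous cases:
  *Bothrops* 2171, rural 2271, male 2101, feet 1343, ...); levels that the
  published tables do not break out (e.g. the urban/periurban split, the
  female/missing split) absorb the remainder with illustrative values.
  Ages are N(34, 15²) clipped to [0, 95], matching the published median.
  Aggregating the generated line list back to monthly counts recovers `y`
  exactly for every seed.

What the generator does **not** emulate: spatial correlation between
cities, reporting delays and duplicate notifications, climate-change
trends, covariate measurement error, and any dependence between a case's
attributes (columns are drawn independently).  Passing recovery tests
therefore show that the *fitting machinery* is calibrated under the assumed
model, not that the model is adequate for real registry data.

## Simulation studies and what they show

* Coverage: over 100 replicates of the default scenario the 95% CrI for the
  humidity coefficient covers truth at close to the nominal rate
  (frequentist coverage at a fixed truth need not be exactly 95%); the
  acceptance band is 89–100%.
* Null calibration: with all coefficients zero the humidity RR interval
  contains 1.00 at a similar rate.  Across seeds this sits around 92–98%;
  the mild undercoverage reflects the seasonal collinearity between
  humidity and the RW1 trend at a fixed (not prior-drawn) truth.
* Laplace-vs-MCMC: coefficient posterior means agree within Monte-Carlo
  error and sds within a few percent on a 60-month series.
* Recovery runs use a reduced 5x5 hyper grid; single fits default to 9x9.

## Known limitations

* The iid precision `tau_delta` is weakly identified when counts carry
  little extra-Poisson noise; its posterior is then very diffuse (this is
  visible in the worked example) and is reported as such rather than
  suppressed.
* Hyperparameter quantiles are discrete-grid approximations.
* The intercept's Laplace marginal carries a small skewness bias relative
  to MCMC (order 1e-2 sd units at T=60); coefficient marginals are
  unaffected at measurable precision.
* No spatial/CAR components, RW2, interactions, model-comparison criteria
  or forecasting; single-city fits only.
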