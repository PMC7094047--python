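# serpens

Bayesian time-series analysis of snakebite surveillance counts.

Snakebites are a neglected tropical disease; in the western Brazilian Amazon
(Rondônia) their incidence is strongly seasonal and plausibly driven by
climate. `serpens` is a package for analysts of notifiable-disease
surveillance data who want to (i) describe a snakebite case line list
(category proportions, median age, monthly/annual incidence per 100,000) and
(ii) quantify the association between monthly case counts and satellite
climate covariates — rainfall, specific humidity, and day/night land-surface
temperature — while accounting for residual temporal correlation.

## The model

Monthly counts $y_t$ for one municipality follow

$$y_t \sim \mathrm{Poisson}(e_t\,\exp\eta_t), \qquad
\eta_t = \beta_0 + \mathbf{x}_t^\top\boldsymbol\beta + \omega_t + \delta_t,$$

where $e_t$ is an expected-count offset proportional to population (so
$\exp$ of the predictor is a relative risk, RR), $\mathbf{x}_t$ holds
mean-centred climate covariates, $\omega$ is a first-order random-walk
(RW1) temporal field with precision $\tau_\omega$
($\omega_t \mid \omega_{t-1} \sim N(\omega_{t-1}, \tau_\omega^{-1})$), and
$\delta$ is iid Gaussian noise with precision $\tau_\delta$.  Both fields
are constrained to sum to zero.  Priors: $\beta_j \sim N(0, 1000)$ and
diffuse $\mathrm{Gamma}(1, 5\times10^{-5})$ priors on the precisions.
$\exp(\beta_j)$ is the RR per natural covariate unit (1 mm, 1 g/kg, 1 °C)
and $\exp(\omega_t)$ is the temporal RR trend.

Fitting is by a nested Laplace approximation written from first principles
(Newton-Raphson Gaussian approximation to the latent field, numerical
integration over a hyperparameter grid), cross-checkable against an
independent Metropolis-within-Gibbs sampler of the same posterior.  A
synthetic-data generator with known ground truth stands in for the real
registry and satellite extracts, which are not redistributable.

## Worked example

```python
import numpy as np
from serpens import ScenarioConfig, simulate_scenario, RW1PoissonModel, rr_table

bundle = simulate_scenario(ScenarioConfig(T=144, seed=8))   # 12 years, known truth
model = RW1PoissonModel.from_series(bundle.series)
fit = model.fit()
print(rr_table(fit))
```

```
                   estimate (95% CrI)
Rainfall             1.00 (1.00-1.00)
Humidity             1.12 (1.07-1.17)
LSTD                 0.93 (0.89-0.96)
LSTN                 1.04 (0.95-1.14)
beta_0            -0.07 (-0.12--0.02)
tau_omega       217.97 (71.47-392.55)
tau_delta  20573.88 (992.04-89694.90)
```

The scenario's true relative risks were 1.10 per g/kg of humidity, 0.95 per
°C of day temperature, and 1.00 for rainfall and night temperature; every
95% credible interval covers its truth.  Humidity's cell reads as "a 1 g/kg
rise in specific humidity multiplies the expected monthly count by 1.12
(1.07–1.17)".  `fit.trend_frame()` gives the monthly RR trend
$\exp(\omega_t)$ with bands, `fit.plot_trend()` draws it, and
`model.fit_mcmc(seed=0)` runs the independent sampler for cross-checking.

Descriptive epidemiology works directly on a raw line-list CSV:

```python
from serpens import read_linelist, describe_linelist
summary = describe_linelist(read_linelist("cases.csv"), population_df)
print(summary.to_text())
```

A CLI wires the same steps together:
`serpens describe|fit|simulate|recover --help`.

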