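"""Synthetic surveillance and climate data with known ground truth.

Stand-in for the real inputs of the analysis (a notifiable-disease case
registry, satellite-derived monthly climate extracts, and annual census
populations), generated with the statistical structure the model assumes so
that parameter recovery can be tested against known truth:

* climate covariates follow one annual sinusoid per variable plus Gaussian
  noise (rainfall floored at zero), with per-city presets calibrated so that
  long-run sample moments match the published city-level means and standard
  deviations where those are published (rainfall for Porto Velho and Cacoal,
  day temperature for Cacoal, night temperature for Vilhena); the remaining
  presets are interpolated, plausible values documented as illustrative;
* the latent temporal fields are a sum-to-zero-centred cumulative-sum RW1
  and centred iid noise with configurable precisions;
* counts are Poisson with a population offset and log-linear predictor;
* the line list expands each month's count into case rows whose categorical
  attributes follow, by default, the published study-area composition
  (2655 venomous cases), so descriptive statistics are reproduced in
  expectation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special, stats

from .gmrf import constrained_rw1_draw

__all__ = [
    "SeasonalPreset", "CITY_CLIMATE_PRESETS", "REFERENCE_COMPOSITION",
    "ScenarioConfig", "TruthBundle",
    "gen_climate", "gen_latent", "gen_counts", "gen_linelist",
    "gen_population", "simulate_scenario", "reference_linelist",
]


@dataclass(frozen=True)
class SeasonalPreset:
    """Annual sinusoid: value = base + amplitude*cos(2*pi*(month-peak)/12) + noise.

    ``floor_at_zero`` censors negative values at 0 (rainfall).  For censored
    presets ``base``/``noise_sd`` should come from :func:`calibrate_censored`
    so the *censored* moments hit their targets.
    """

    base: float
    amplitude: float
    noise_sd: float
    peak_month: int
    floor_at_zero: bool = False

    def seasonal_mean(self, month):
        return self.base + self.amplitude * np.cos(2 * np.pi * (np.asarray(month) - self.peak_month) / 12.0)


def _censored_moments(base, amplitude, sigma, peak=2):
    """Closed-form mean/sd of max(0, sinusoid + N(0, sigma^2)) over 12 months."""
    months = np.arange(1, 13)
    m = base + amplitude * np.cos(2 * np.pi * (months - peak) / 12.0)
    a = m / sigma
    Phi = special.ndtr(a)
    phi = np.exp(-0.5 * a**2) / np.sqrt(2 * np.pi)
    ey = m * Phi + sigma * phi
    ey2 = (m**2 + sigma**2) * Phi + m * sigma * phi
    mean = ey.mean()
    var = ey2.mean() - mean**2
    return mean, np.sqrt(var)


@lru_cache(maxsize=None)
def calibrate_censored(target_mean: float, target_sd: float, amplitude: float,
                       peak: int = 2) -> tuple:
    """Solve for (base, noise_sd) so censored-sinusoid moments hit the targets."""

    def resid(x):
        base, logsig = x
        m, s = _censored_moments(base, amplitude, np.exp(logsig), peak)
        return [m - target_mean, s - target_sd]

    sig0 = max(target_sd**2 - amplitude**2 / 2.0, 1.0) ** 0.5
    sol = optimize.fsolve(resid, [target_mean, np.log(sig0)], full_output=True)
    x, info, ier, _ = sol
    if ier != 1 or max(abs(np.array(resid(x)))) > 1e-6:
        raise RuntimeError("censored-moment calibration failed "
                           f"(targets {target_mean}, {target_sd}, A={amplitude})")
    return float(x[0]), float(np.exp(x[1]))


def _rain(target_mean, target_sd, amplitude, peak=2):
    base, sd = calibrate_censored(target_mean, target_sd, amplitude, peak)
    return SeasonalPreset(base, amplitude, sd, peak, floor_at_zero=True)


# Published moments: rainfall Porto Velho (149.0, 107.0) and Cacoal
# (142.0, 116.0); LSTD Cacoal (32.4, 2.1); LSTN Vilhena (19.9, 1.0).
# All other numbers are illustrative interpolations, not data.
CITY_CLIMATE_PRESETS = {
    "porto_velho": {
        "rainfall": _rain(149.0, 107.0, 130.0),
        "humidity": SeasonalPreset(16.0, 2.2, 0.905, peak_month=3),
        "lstd": SeasonalPreset(31.5, 2.4, 1.058, peak_month=9),
        "lstn": SeasonalPreset(23.0, 1.2, 0.529, peak_month=9),
    },
    "ariquemes": {
        "rainfall": _rain(145.0, 110.0, 132.0),
        "humidity": SeasonalPreset(15.5, 2.2, 0.905, peak_month=3),
        "lstd": SeasonalPreset(32.0, 2.5, 1.134, peak_month=9),
        "lstn": SeasonalPreset(22.5, 1.2, 0.529, peak_month=9),
    },
    "cacoal": {
        "rainfall": _rain(142.0, 116.0, 135.0),
        "humidity": SeasonalPreset(15.0, 2.2, 0.905, peak_month=3),
        "lstd": SeasonalPreset(32.4, 2.5, 1.134, peak_month=9),
        "lstn": SeasonalPreset(22.0, 1.3, 0.604, peak_month=9),
    },
    "vilhena": {
        "rainfall": _rain(140.0, 110.0, 130.0),
        "humidity": SeasonalPreset(14.0, 2.4, 1.058, peak_month=3),
        "lstd": SeasonalPreset(31.0, 2.6, 1.208, peak_month=9),
        "lstn": SeasonalPreset(19.9, 1.2, 0.529, peak_month=9),
    },
}

# Study-area composition of the 2655 venomous cases (2007-2018, four
# municipalities), from the published surveillance counts; levels not broken
# out in print absorb the remainder and are marked illustrative in docs.
REFERENCE_COMPOSITION = {
    "genus": {"bothrops": 2171, "lachesis": 80, "micrurus": 35, "crotalus": 32,
              "unknown": 337},
    "zone": {"rural": 2271, "urban": 300, "periurban": 50, "missing": 34},
    "sex": {"male": 2101, "female": 546, "missing": 8},
    "bite_site": {"foot": 1343, "leg": 671, "toe": 230, "hand": 150, "arm": 80,
                  "other": 100, "missing": 81},
    "severity": {"mild": 992, "moderate": 1101, "severe": 476, "missing": 86},
    "outcome": {"survived": 2515, "died": 2, "missing": 138},
}
N_STUDY_AREA = 2655          # venomous cases in the four municipalities
N_STATE_REPORTS = 6326       # all reports state-wide over the study window
N_NONVENOMOUS = 332          # nonvenomous accidents among state reports


def _probs(counts: dict) -> dict:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


@dataclass
class ScenarioConfig:
    """Ground-truth scenario: one city, T months, known model parameters.

    Defaults emulate the study conditions: a 12-year monthly span
    (2007-2018), a Porto-Velho-sized population with slow growth, an overall
    monthly incidence near 2.4 per 100,000, a humidity relative risk of 1.10
    per g/kg with a mild negative day-temperature effect, and field
    precisions within the ranges reported for the fitted cities.
    """

    T: int = 144
    start: str = "2007-01"
    city: str = "porto_velho"
    population: float = 520_000.0
    pop_growth: float = 0.012                       # annual fraction
    beta0: float = 0.0
    beta: dict = field(default_factory=lambda: {
        "rainfall": 0.0,
        "humidity": float(np.log(1.10)),
        "lstd": float(np.log(0.95)),
        "lstn": 0.0,
    })
    tau_omega: float = 200.0
    tau_delta: float = 200.0
    ref_monthly_rate: float = 2.4e-5                # cases per person-month
    composition: dict = field(default_factory=lambda: {
        var: _probs(cnt) for var, cnt in REFERENCE_COMPOSITION.items()})
    seed: int = 0

    def validate(self):
        if self.T < 3:
            raise ValueError("T must be at least 3")
        for var, probs in self.composition.items():
            s = sum(probs.values())
            if abs(s - 1.0) > 1e-9 or any(p < 0 for p in probs.values()):
                raise ValueError(f"composition probabilities for {var!r} must be "
                                 f"non-negative and sum to 1 (sum={s})")
        if self.tau_omega <= 0 or self.tau_delta <= 0:
            raise ValueError("precisions must be positive")
        if self.T % 12:
            import logging
            logging.getLogger(__name__).warning(
                "T=%d is not a multiple of 12; seasonal balance is broken", self.T)


@dataclass
class TruthBundle:
    """Scenario config plus every realised intermediate quantity."""

    config: ScenarioConfig
    climate: pd.DataFrame
    population: pd.DataFrame
    omega: np.ndarray
    delta: np.ndarray
    e: np.ndarray
    eta: np.ndarray
    y: np.ndarray
    series: pd.DataFrame          # modelling table (uncentred covariates)
    cases: pd.DataFrame | None = None
    centering: dict = field(default_factory=dict)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": np.arange(1, len(self.y) + 1),
                             "omega": self.omega, "delta": self.delta,
                             "e": self.e, "eta": self.eta, "y": self.y})


def _periods(cfg: ScenarioConfig):
    return pd.period_range(cfg.start, periods=cfg.T, freq="M")


def gen_climate(cfg: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Monthly climate table for the scenario city (annual sinusoid + noise)."""
    presets = CITY_CLIMATE_PRESETS[cfg.city]
    periods = _periods(cfg)
    months = np.array([p.month for p in periods])
    out = {"city": cfg.city, "year": [p.year for p in periods], "month": months}
    for name, pr in presets.items():
        x = pr.seasonal_mean(months) + rng.normal(0.0, pr.noise_sd, size=cfg.T)
        if pr.floor_at_zero:
            x = np.maximum(x, 0.0)
        out[name] = x
    return pd.DataFrame(out)


def gen_population(cfg: ScenarioConfig) -> pd.DataFrame:
    """Annual population table with geometric growth."""
    years = sorted({p.year for p in _periods(cfg)})
    y0 = years[0]
    pop = [cfg.population * (1.0 + cfg.pop_growth) ** (y - y0) for y in years]
    return pd.DataFrame({"city": cfg.city, "year": years,
                         "population": np.round(pop).astype(int)})


def gen_latent(cfg: ScenarioConfig, rng: np.random.Generator):
    """Sum-to-zero RW1 field omega and centred iid field delta."""
    omega = constrained_rw1_draw(cfg.T, cfg.tau_omega, rng)
    delta = rng.normal(0.0, 1.0 / np.sqrt(cfg.tau_delta), size=cfg.T)
    delta = delta - delta.mean()
    return omega, delta


def gen_counts(cfg: ScenarioConfig, climate: pd.DataFrame, latent,
               rng: np.random.Generator) -> TruthBundle:
    """Poisson counts from the log-linear predictor with population offset.

    Covariates enter centred by the generator's own sample means (stored in
    ``TruthBundle.centering``), so the true coefficients are per natural unit
    and the intercept is the log rate ratio at average climate.
    """
    omega, delta = latent
    periods = _periods(cfg)
    poptab = gen_population(cfg)
    pop_by_year = poptab.set_index("year")["population"]
    pop_m = np.array([pop_by_year.loc[p.year] for p in periods], dtype=float)
    e = pop_m * cfg.ref_monthly_rate
    eta = cfg.beta0 + omega + delta
    centering = {}
    for name, b in cfg.beta.items():
        x = climate[name].to_numpy(dtype=float)
        centering[name] = float(x.mean())
        eta = eta + b * (x - centering[name])
    y = rng.poisson(e * np.exp(eta))
    series = pd.DataFrame({
        "t": np.arange(1, cfg.T + 1), "city": cfg.city, "period": periods,
        "year": [p.year for p in periods], "month": [p.month for p in periods],
        "y": y, "pop": pop_m,
    })
    for name in ("rainfall", "humidity", "lstd", "lstn"):
        series[name] = climate[name].to_numpy()
    return TruthBundle(config=cfg, climate=climate, population=poptab,
                       omega=omega, delta=delta, e=e, eta=eta, y=y,
                       series=series, centering=centering)


def gen_linelist(cfg: ScenarioConfig, counts: pd.DataFrame,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Expand monthly counts into a raw case line list.

    Each month's ``y`` becomes that many rows dated in the month, with
    categorical attributes drawn independently from the configured
    composition and ages from N(34, 15^2) clipped to [0, 95] (median 34,
    matching the published median).  Returns the raw CSV dialect that
    :func:`serpens.linelist.read_linelist` consumes.
    """
    rows_y = counts["y"].to_numpy()
    n = int(rows_y.sum())
    dates = np.repeat(
        [f"{int(yy):04d}-{int(mm):02d}" for yy, mm in zip(counts["year"], counts["month"])],
        rows_y)
    out = {"date": dates, "municipality": cfg.city}
    for var, probs in cfg.composition.items():
        levels = list(probs)
        p = np.array([probs[k] for k in levels])
        col = "bite_site" if var == "bite_site" else var
        out[col] = rng.choice(levels, size=n, p=p / p.sum())
    ages = np.clip(np.round(rng.normal(34.0, 15.0, size=n)), 0, 95).astype(int)
    out["age"] = ages
    df = pd.DataFrame(out)
    return df[["date", "municipality", "genus", "zone", "sex", "age",
               "bite_site", "severity", "outcome"]]


def simulate_scenario(cfg: ScenarioConfig | None = None, outdir=None) -> TruthBundle:
    """End-to-end scenario: climate, latent fields, counts, line list.

    Deterministic given ``cfg.seed``.  With ``outdir`` the five CSV artefacts
    (cases, climate, population, truth, scenario echo) are written there.
    """
    cfg = cfg or ScenarioConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    climate = gen_climate(cfg, rng)
    latent = gen_latent(cfg, rng)
    bundle = gen_counts(cfg, climate, latent, rng)
    bundle.cases = gen_linelist(cfg, bundle.series[["year", "month", "y"]], rng)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        bundle.cases.to_csv(outdir / "cases.csv", index=False)
        bundle.climate.to_csv(outdir / "climate.csv", index=False)
        bundle.population.to_csv(outdir / "population.csv", index=False)
        bundle.truth_frame().to_csv(outdir / "truth.csv", index=False)
        echo = dataclasses.asdict(cfg)
        with open(outdir / "scenario.yaml", "w") as fh:
            yaml.safe_dump(echo, fh, sort_keys=False)
    return bundle


def reference_linelist() -> pd.DataFrame:
    """Deterministic state-wide raw line list with the published composition.

    Synthetic reconstruction from published aggregate counts (no individual
    records): 2655 venomous cases spread over the four study municipalities
    carrying the exact published category counts, 332 nonvenomous accidents
    and 3339 venomous cases elsewhere in the state, 6326 rows in all.
    Attribute columns are built independently, so only the marginal counts
    (what the descriptive tables use) are meaningful.
    """
    n = N_STUDY_AREA

    def expand(counts):
        return np.repeat(list(counts.keys()), list(counts.values()))

    cities = np.tile(["Porto Velho", "Ariquemes", "Cacoal", "Vilhena"],
                     n // 4 + 1)[:n]
    periods = pd.period_range("2007-01", "2018-12", freq="M")
    dates = np.tile([str(p) for p in periods], n // len(periods) + 1)[:n]
    ages = np.tile([20, 34, 48], n // 3 + 1)[:n]        # median exactly 34
    study = pd.DataFrame({
        "date": dates, "municipality": cities,
        "genus": expand(REFERENCE_COMPOSITION["genus"]),
        "zone": expand(REFERENCE_COMPOSITION["zone"]),
        "sex": expand(REFERENCE_COMPOSITION["sex"]),
        "age": ages,
        "bite_site": expand(REFERENCE_COMPOSITION["bite_site"]),
        "severity": expand(REFERENCE_COMPOSITION["severity"]),
        "outcome": expand(REFERENCE_COMPOSITION["outcome"]),
    })
    n_rest = N_STATE_REPORTS - N_STUDY_AREA - N_NONVENOMOUS
    rest = pd.DataFrame({
        "date": np.tile([str(p) for p in periods], n_rest // len(periods) + 1)[:n_rest],
        "municipality": "other", "genus": "bothrops", "zone": "rural",
        "sex": "male", "age": 34, "bite_site": "foot", "severity": "mild",
        "outcome": "survived",
    })
    nonven = pd.DataFrame({
        "date": np.tile([str(p) for p in periods], N_NONVENOMOUS // len(periods) + 1)[:N_NONVENOMOUS],
        "municipality": "other", "genus": "Boa constrictor", "zone": "rural",
        "sex": "male", "age": 34, "bite_site": "foot", "severity": "mild",
        "outcome": "survived",
    })
    return pd.concat([study, rest, nonven], ignore_index=True)
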