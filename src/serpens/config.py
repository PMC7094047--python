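"""Run configuration: one YAML file drives every pipeline command.

Structure (all blocks optional; CLI flags override config values):

.. code-block:: yaml

    paths: {cases: cases.csv, climate: climate.csv, population: pop.csv, out: out/}
    window: {start: "2007-01", end: "2018-12"}
    cities: [porto_velho, ariquemes, cacoal, vilhena]
    units: {humidity: kg/kg, lstd: K, lstn: K}     # source-unit declarations
    model:
      covariates: [rainfall, humidity, lstd, lstn]
      beta_prior_variance: 1000.0
      tau_prior: {shape: 1.0, rate: 5.0e-5}
      grid: {size: 9, span: 3.0}
      newton: {tol: 1.0e-8, maxiter: 50}
    scenario: {T: 144, city: porto_velho, ...}     # ScenarioConfig fields
    seed: 1
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import ModelSpec
from .simulate import ScenarioConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    paths: dict = field(default_factory=dict)
    window: tuple = ("2007-01", "2018-12")
    cities: list = field(default_factory=lambda: ["porto_velho", "ariquemes",
                                                  "cacoal", "vilhena"])
    units: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)
    seed: int = 1

    def model_spec(self) -> ModelSpec:
        m = self.model
        tau = m.get("tau_prior", {})
        return ModelSpec(
            covariates=tuple(m.get("covariates", ("rainfall", "humidity",
                                                  "lstd", "lstn"))),
            beta_prior_variance=float(m.get("beta_prior_variance", 1000.0)),
            tau_prior_shape=float(tau.get("shape", 1.0)),
            tau_prior_rate=float(tau.get("rate", 5e-5)),
            include_trend=bool(m.get("include_trend", True)),
            include_iid=bool(m.get("include_iid", True)),
        )

    def fit_options(self) -> dict:
        grid = self.model.get("grid", {})
        newton = self.model.get("newton", {})
        return {"grid_size": int(grid.get("size", 9)),
                "grid_span": float(grid.get("span", 3.0)),
                "newton_tol": float(newton.get("tol", 1e-8)),
                "newton_maxiter": int(newton.get("maxiter", 50))}

    def scenario_config(self) -> ScenarioConfig:
        known = {f.name for f in ScenarioConfig.__dataclass_fields__.values()}
        extra = set(self.scenario) - known
        if extra:
            raise ValueError(f"unknown scenario option(s): {sorted(extra)}")
        kwargs = dict(self.scenario)
        kwargs.setdefault("seed", self.seed)
        return ScenarioConfig(**kwargs)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    window = raw.get("window", {})
    if isinstance(window, dict):
        window = (window.get("start", "2007-01"), window.get("end", "2018-12"))
    return RunConfig(
        paths=raw.get("paths", {}),
        window=tuple(window),
        cities=list(raw.get("cities", ["porto_velho", "ariquemes", "cacoal",
                                       "vilhena"])),
        units=raw.get("units", {}),
        model=raw.get("model", {}),
        scenario=raw.get("scenario", {}),
        seed=int(raw.get("seed", 1)),
    )
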