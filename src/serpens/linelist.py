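"""Case line-list ingestion and descriptive epidemiology.

Reads a surveillance line list of notified snakebites (one row per case,
with notification year-month, municipality, snake genus, zone of occurrence,
sex, age, bite site, clinical severity and outcome), validates it against a
closed category schema, and computes the descriptive statistics used in
surveillance reports: category counts and percentages, median age, and
monthly / annual incidence per 100,000 inhabitants.

Percentage convention: by default the denominator is the full stratum size
(all venomous cases in the study area), *including* records whose value for
the tabulated variable is missing.  This is the convention of the source
registry's published tables; pass ``nonmissing_denominator=True`` to switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up

logger = logging.getLogger(__name__)

__all__ = [
    "MUNICIPALITIES", "GENERA", "ZONES", "SEXES", "SITES", "SEVERITIES", "OUTCOMES",
    "CaseRecord", "SchemaConfig", "ParseReport", "LineList",
    "read_linelist", "linelist_from_frame", "filter_venomous", "restrict_to_cities",
    "category_proportions", "median_age", "monthly_incidence",
    "incidence_interval", "describe_linelist", "DescriptiveSummary",
]

MUNICIPALITIES = ("porto_velho", "ariquemes", "cacoal", "vilhena", "other")
STUDY_CITIES = MUNICIPALITIES[:4]
GENERA = ("bothrops", "lachesis", "micrurus", "crotalus", "nonvenomous", "unknown")
ZONES = ("rural", "urban", "periurban", "missing")
SEXES = ("male", "female", "missing")
SITES = ("foot", "leg", "toe", "hand", "arm", "other", "missing")
SEVERITIES = ("mild", "moderate", "severe", "missing")
OUTCOMES = ("survived", "died", "missing")

_CATEGORICALS = {
    "municipality": MUNICIPALITIES,
    "genus": GENERA,
    "zone": ZONES,
    "sex": SEXES,
    "bite_site": SITES,
    "severity": SEVERITIES,
    "outcome": OUTCOMES,
}

# common raw-registry spellings -> canonical levels
DEFAULT_GENUS_MAP = {
    "boa": "nonvenomous", "boa constrictor": "nonvenomous",
    "nao peconhenta": "nonvenomous", "non-venomous": "nonvenomous",
    "lachesis": "lachesis", "laquesis": "lachesis",
    "bothrops": "bothrops", "micrurus": "micrurus", "crotalus": "crotalus",
    "ignorado": "unknown", "ignored": "unknown", "": "unknown",
}
_SYNONYMS = {
    "municipality": {"porto velho": "porto_velho"},
    "sex": {"m": "male", "f": "female", "masculino": "male", "feminino": "female"},
    "zone": {"periurbana": "periurban", "urbana": "urban"},
    "bite_site": {"feet": "foot", "legs": "leg", "toes": "toe", "hands": "hand",
                  "arms": "arm"},
    "severity": {"leve": "mild", "moderada": "moderate", "grave": "severe"},
    "outcome": {"cura": "survived", "obito": "died", "death": "died"},
}


@dataclass(frozen=True)
class CaseRecord:
    """One notified snakebite with its categorical attributes."""

    notify_month: pd.Period
    municipality: str
    genus: str
    zone: str
    sex: str
    age_years: float          # NaN when missing
    bite_site: str
    severity: str
    outcome: str


@dataclass
class SchemaConfig:
    """Column mapping, study window and value mappings for the raw CSV."""

    columns: dict = field(default_factory=lambda: {
        "notify_month": "date", "municipality": "municipality", "genus": "genus",
        "zone": "zone", "sex": "sex", "age_years": "age",
        "bite_site": "bite_site", "severity": "severity", "outcome": "outcome",
    })
    window: tuple = ("2007-01", "2018-12")
    genus_map: dict = field(default_factory=lambda: dict(DEFAULT_GENUS_MAP))


@dataclass
class ParseReport:
    n_input: int = 0
    n_parsed: int = 0
    n_rejected: int = 0
    rejected_rows: list = field(default_factory=list)   # (row number, reason)
    warnings: list = field(default_factory=list)
    n_removed_nonvenomous: int = 0

    def warn(self, msg: str):
        self.warnings.append(msg)
        logger.warning(msg)


class LineList:
    """Validated case collection; wraps a typed DataFrame."""

    def __init__(self, df: pd.DataFrame, report: ParseReport | None = None):
        self.df = df.reset_index(drop=True)
        self.report = report or ParseReport(n_input=len(df), n_parsed=len(df))

    def __len__(self):
        return len(self.df)

    @property
    def records(self) -> Iterator[CaseRecord]:
        for row in self.df.itertuples(index=False):
            yield CaseRecord(row.notify_month, row.municipality, row.genus,
                             row.zone, row.sex, row.age_years, row.bite_site,
                             row.severity, row.outcome)


def _normalise(s: pd.Series) -> pd.Series:
    return s.fillna("").astype(str).str.strip().str.lower().str.replace(" ", "_")


def linelist_from_frame(raw: pd.DataFrame, schema: SchemaConfig | None = None) -> LineList:
    """Validate an in-memory raw table (same semantics as :func:`read_linelist`)."""
    schema = schema or SchemaConfig()
    report = ParseReport(n_input=len(raw))
    missing_cols = [src for src in schema.columns.values() if src not in raw.columns]
    if missing_cols:
        raise ValueError(f"line list is missing required column(s): {missing_cols}")
    df = raw.rename(columns={v: k for k, v in schema.columns.items()}).copy()

    months = pd.to_datetime(df["notify_month"].astype(str), format="mixed",
                            errors="coerce").dt.to_period("M")
    bad_date = months.isna()
    lo, hi = (pd.Period(schema.window[0], "M"), pd.Period(schema.window[1], "M"))
    out_window = (~bad_date) & ((months < lo) | (months > hi))
    for idx in df.index[bad_date]:
        report.rejected_rows.append((int(idx), "unparseable date"))
    for idx in df.index[out_window]:
        report.rejected_rows.append(
            (int(idx), f"date {months[idx]} outside window {schema.window[0]}..{schema.window[1]}"))
    keep = ~(bad_date | out_window)
    if report.rejected_rows:
        report.warn(f"rejected {len(report.rejected_rows)} row(s) "
                    f"(bad or out-of-window dates)")
    df = df.loc[keep].copy()
    df["notify_month"] = months[keep]

    for col, levels in _CATEGORICALS.items():
        vals = _normalise(df[col])
        if col == "genus":
            mapped = vals.map(lambda x: schema.genus_map.get(x.replace("_", " "),
                                                             schema.genus_map.get(x, x)))
        else:
            syn = _SYNONYMS.get(col, {})
            mapped = vals.map(lambda x: syn.get(x.replace("_", " "), syn.get(x, x)))
        fallback = "unknown" if col == "genus" else "missing"
        bad = ~mapped.isin(levels)
        if bad.any():
            report.warn(f"{col}: {int(bad.sum())} unrecognised value(s) "
                        f"{sorted(set(mapped[bad]))[:5]} mapped to '{fallback}'")
            mapped = mapped.where(~bad, fallback)
        df[col] = pd.Categorical(mapped, categories=levels)

    age = pd.to_numeric(df["age_years"], errors="coerce")
    neg = age < 0
    if neg.any():
        report.warn(f"age: {int(neg.sum())} negative value(s) set to missing")
        age = age.where(~neg)
    df["age_years"] = age

    dup = df.duplicated()
    if dup.any():
        report.warn(f"{int(dup.sum())} exact duplicate row(s) present (kept)")

    report.n_parsed = len(df)
    report.n_rejected = len(report.rejected_rows)
    cols = ["notify_month", "municipality", "genus", "zone", "sex", "age_years",
            "bite_site", "severity", "outcome"]
    return LineList(df[cols], report)


def read_linelist(path, schema: SchemaConfig | None = None) -> LineList:
    """Read and validate a case line-list CSV.

    Rows with unparseable dates or dates outside the study window are
    rejected with row-numbered diagnostics in ``.report``; unknown category
    strings map to the missing level with a logged warning.  A missing
    required column is a hard error.
    """
    raw = pd.read_csv(path, dtype=str)
    return linelist_from_frame(raw, schema)


def filter_venomous(ll: LineList) -> LineList:
    """Drop accidents by nonvenomous species; idempotent; count reported."""
    keep = ll.df["genus"] != "nonvenomous"
    removed = int((~keep).sum())
    report = ParseReport(**{k: v for k, v in asdict(ll.report).items()})
    report.n_removed_nonvenomous = removed
    if removed:
        logger.info("filter_venomous: removed %d nonvenomous record(s)", removed)
    return LineList(ll.df.loc[keep], report)


def restrict_to_cities(ll: LineList, cities: Iterable[str] = STUDY_CITIES) -> LineList:
    """Keep records notified in the given municipalities."""
    keep = ll.df["municipality"].isin(list(cities))
    return LineList(ll.df.loc[keep], ll.report)


def category_proportions(ll: LineList, variable: str, denominator: int | None = None,
                         decimals: int = 1,
                         nonmissing_denominator: bool = False) -> pd.DataFrame:
    """Counts and percentages per level of one categorical variable.

    ``denominator`` defaults to the number of records (missing included);
    percentages are ``100 * count / denominator`` with half-up rounding.
    """
    if variable not in _CATEGORICALS:
        raise KeyError(f"unknown categorical variable {variable!r}")
    counts = ll.df[variable].value_counts().reindex(_CATEGORICALS[variable], fill_value=0)
    if denominator is None:
        if nonmissing_denominator:
            miss = "unknown" if variable == "genus" else "missing"
            denominator = int(counts.drop(miss).sum())
        else:
            denominator = len(ll)
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = [round_half_up(100.0 * c / denominator, decimals) for c in counts]
    return pd.DataFrame({"count": counts.to_numpy(), "percent": pct},
                        index=counts.index.rename(variable))


def median_age(ll: LineList) -> float:
    return float(ll.df["age_years"].median())


def monthly_incidence(ll: LineList, population: pd.DataFrame, city: str,
                      window: tuple = ("2007-01", "2018-12")):
    """Monthly and annual incidence per 100,000 for one municipality.

    ``population`` has columns (city, year, population); the annual figure is
    applied to all 12 months of its year.  Missing population years are an
    error naming the year.  Returns ``(monthly, annual)`` DataFrames; months
    with no notification get a zero count, not a missing value.
    """
    periods = pd.period_range(window[0], window[1], freq="M")
    sub = ll.df[ll.df["municipality"] == city]
    counts = sub.groupby("notify_month", observed=True).size()
    counts = counts.reindex(periods, fill_value=0)
    pop = population[population["city"] == city].set_index("year")["population"]
    years = sorted({p.year for p in periods})
    missing = [y for y in years if y not in pop.index]
    if missing:
        raise ValueError(f"population missing for {city} in year(s) {missing}")
    pop_m = np.array([pop.loc[p.year] for p in periods], dtype=float)
    monthly = pd.DataFrame({
        "city": city, "year": [p.year for p in periods],
        "month": [p.month for p in periods],
        "cases": counts.to_numpy(), "population": pop_m,
        "incidence_per_100k": 1e5 * counts.to_numpy() / pop_m,
    })
    annual = monthly.groupby("year").agg(cases=("cases", "sum"),
                                         population=("population", "first"))
    annual["incidence_per_100k"] = 1e5 * annual["cases"] / annual["population"]
    return monthly, annual.reset_index()


def incidence_interval(total_cases: int, total_person_months: float):
    """Overall monthly rate per 100,000 with a 95% credible interval.

    Posterior of a constant Poisson rate under the Jeffreys Gamma(1/2, 0)
    prior: ``rate | data ~ Gamma(cases + 1/2, person_months)``.  Returns
    ``(posterior mean, (2.5%, 97.5%))`` scaled to cases per 100,000
    person-months.
    """
    if total_person_months <= 0:
        raise ValueError("person-months must be positive")
    if total_cases < 0:
        raise ValueError("case count must be non-negative")
    a = total_cases + 0.5
    scale = 1.0 / total_person_months
    mean = 1e5 * a * scale
    lo, hi = 1e5 * stats.gamma.ppf([0.025, 0.975], a, scale=scale)
    return mean, (float(lo), float(hi))


@dataclass
class DescriptiveSummary:
    """Bundle of descriptive tables for a study-area line list."""

    denominator: int
    n_state_reports: int | None
    tables: dict                       # variable -> counts/percent DataFrame
    median_age_years: float
    incidence: dict                    # city -> (monthly, annual)
    overall_rates: dict                # city -> (rate, (lo, hi))

    def studied_area_percent(self, decimals: int = 0) -> float | None:
        """Share of all state reports that are venomous cases in the study cities."""
        if not self.n_state_reports:
            return None
        return round_half_up(100.0 * self.denominator / self.n_state_reports, decimals)

    def to_text(self) -> str:
        lines = [f"Venomous cases in study area: n={self.denominator}"]
        if self.n_state_reports:
            lines.append(f"All state reports: n={self.n_state_reports} "
                         f"(studied-area share {self.studied_area_percent():g}%)")
        lines.append(f"Median age: {self.median_age_years:.0f} years")
        for var, tab in self.tables.items():
            lines += ["", f"-- {var} --", tab.to_string()]
        for city, (rate, (lo, hi)) in self.overall_rates.items():
            lines.append(f"{city}: overall monthly incidence "
                         f"{rate:.2f} (95% CrI {lo:.2f}-{hi:.2f}) per 100,000")
        return "\n".join(lines)

    def write_csv(self, outdir):
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for var, tab in self.tables.items():
            tab.to_csv(outdir / f"proportions_{var}.csv")
        for city, (monthly, annual) in self.incidence.items():
            monthly.to_csv(outdir / f"incidence_monthly_{city}.csv", index=False)
            annual.to_csv(outdir / f"incidence_annual_{city}.csv", index=False)


def describe_linelist(ll: LineList, population: pd.DataFrame | None = None,
                      window: tuple = ("2007-01", "2018-12"),
                      decimals_map: dict | None = None) -> DescriptiveSummary:
    """Full descriptive pass: venom filter, study-area restriction, tables.

    ``ll`` may contain state-wide reports; the venomous/nonvenomous filter and
    the restriction to the four study municipalities are applied here, and
    the study-area share is computed against all input reports.
    """
    n_state = len(ll)
    ven = filter_venomous(ll)
    area = restrict_to_cities(ven)
    denom = len(area)
    if denom == 0:
        raise ValueError("no venomous cases in the study area after filtering")
    decimals_map = decimals_map or {}
    tables = {}
    for var in ("genus", "zone", "sex", "bite_site", "severity", "outcome"):
        dec = decimals_map.get(var, 1)
        tables[var] = category_proportions(area, var, denominator=denom, decimals=dec)
    incidence = {}
    rates = {}
    if population is not None:
        for city in STUDY_CITIES:
            monthly, annual = monthly_incidence(area, population, city, window)
            incidence[city] = (monthly, annual)
            rates[city] = incidence_interval(int(monthly["cases"].sum()),
                                             float(monthly["population"].sum()))
    return DescriptiveSummary(
        denominator=denom, n_state_reports=n_state, tables=tables,
        median_age_years=median_age(area), incidence=incidence,
        overall_rates=rates)
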