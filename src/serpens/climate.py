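"""Monthly climate covariates: unit conversion, series assembly, centering.

The modelling table for one municipality aligns, month by month, the case
count ``y``, the annual population, and four climate covariates: rainfall
(accumulated mm/month), specific humidity (g/kg), and day/night land-surface
temperature (deg C).  Satellite products are assumed pre-aggregated to
calendar months upstream; this module only converts declared source units
(e.g. Kelvin, kg/kg, scaled MODIS integers) and checks contiguity.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["CLIMATE_COLUMNS", "convert_units", "build_series",
           "aggregate_monthly_counts", "center_covariates"]

CLIMATE_COLUMNS = ("rainfall", "humidity", "lstd", "lstn")

# declared source unit -> conversion to package-native units
_CONVERTERS = {
    "rainfall": {"mm": lambda x: x, "none": lambda x: x},
    "humidity": {"g/kg": lambda x: x, "kg/kg": lambda x: 1000.0 * x,
                 "none": lambda x: x},
    "lstd": {"c": lambda x: x, "k": lambda x: x - 273.15,
             "k_modis_scaled": lambda x: 0.02 * x - 273.15, "none": lambda x: x},
}
_CONVERTERS["lstn"] = _CONVERTERS["lstd"]


def convert_units(climate: pd.DataFrame, conventions: dict | None = None) -> pd.DataFrame:
    """Convert declared source units to mm, g/kg and deg C.

    ``conventions`` maps column name to its source unit, e.g.
    ``{"humidity": "kg/kg", "lstd": "K"}``; unspecified columns pass through.
    An unknown declared unit is an error.
    """
    out = climate.copy()
    for col, unit in (conventions or {}).items():
        if col not in _CONVERTERS:
            raise ValueError(f"no unit conventions defined for column {col!r}")
        key = str(unit).lower()
        if key not in _CONVERTERS[col]:
            raise ValueError(f"unknown unit {unit!r} for column {col!r} "
                             f"(known: {sorted(_CONVERTERS[col])})")
        out[col] = _CONVERTERS[col][key](out[col].astype(float))
    return out


def aggregate_monthly_counts(ll, city: str, window=("2007-01", "2018-12")) -> pd.DataFrame:
    """Zero-filled monthly case counts for one city from a line list."""
    periods = pd.period_range(window[0], window[1], freq="M")
    sub = ll.df[ll.df["municipality"] == city]
    counts = sub.groupby("notify_month", observed=True).size().reindex(periods, fill_value=0)
    return pd.DataFrame({"year": [p.year for p in periods],
                         "month": [p.month for p in periods],
                         "y": counts.to_numpy()})


def _interpolate_short_gaps(s: pd.Series, col: str, max_gap: int = 2) -> pd.Series:
    """Linear interpolation across runs of <= max_gap missing interior months."""
    isna = s.isna()
    if not isna.any():
        return s
    runs = []
    start = None
    for i, na in enumerate(isna):
        if na and start is None:
            start = i
        elif not na and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(s) - 1))
    for a, b in runs:
        if b - a + 1 > max_gap or a == 0 or b == len(s) - 1:
            raise ValueError(
                f"climate column {col!r}: gap of {b - a + 1} month(s) at index {a} "
                f"cannot be interpolated (limit 2, interior only)")
    logger.warning("climate column %r: %d missing month(s) linearly interpolated",
                   col, int(isna.sum()))
    return s.interpolate(method="linear", limit_area="inside")


def build_series(counts: pd.DataFrame, climate: pd.DataFrame, population: pd.DataFrame,
                 city: str, window=("2007-01", "2018-12"),
                 interpolate: bool = False) -> pd.DataFrame:
    """Assemble the per-city modelling table over the study window.

    Returns one row per month with columns ``t`` (1..T, contiguous),
    ``period``, ``year``, ``month``, ``y``, ``pop`` and the four climate
    covariates.  Missing climate months raise an error unless
    ``interpolate=True`` (linear, at most two consecutive interior months,
    logged).  Months absent from ``counts`` become ``y = 0``.
    """
    periods = pd.period_range(window[0], window[1], freq="M")
    frame = pd.DataFrame({"period": periods,
                          "year": [p.year for p in periods],
                          "month": [p.month for p in periods]})

    cnt = counts.copy()
    if "city" in cnt.columns:
        cnt = cnt[cnt["city"] == city]
    cnt = cnt.groupby(["year", "month"], as_index=False)["y"].sum()
    frame = frame.merge(cnt, on=["year", "month"], how="left")
    frame["y"] = frame["y"].fillna(0).astype(int)

    clim = climate.copy()
    if "city" in clim.columns:
        clim = clim[clim["city"] == city]
    cols = [c for c in CLIMATE_COLUMNS if c in clim.columns]
    if len(cols) < len(CLIMATE_COLUMNS):
        missing = set(CLIMATE_COLUMNS) - set(cols)
        raise ValueError(f"climate table missing column(s): {sorted(missing)}")
    frame = frame.merge(clim[["year", "month", *cols]], on=["year", "month"], how="left")
    for col in cols:
        if frame[col].isna().any():
            if not interpolate:
                gaps = frame.loc[frame[col].isna(), ["year", "month"]].to_records(index=False)
                raise ValueError(f"missing climate month(s) for {col!r}: {list(gaps)[:6]} "
                                 f"(pass interpolate=True to fill short gaps)")
            frame[col] = _interpolate_short_gaps(frame[col], col)

    pop = population[population["city"] == city].set_index("year")["population"]
    missing_years = [y for y in sorted(frame["year"].unique()) if y not in pop.index]
    if missing_years:
        raise ValueError(f"population missing for {city} in year(s) {missing_years}")
    frame["pop"] = frame["year"].map(pop).astype(float)

    if (frame["humidity"] <= 0).any():
        raise ValueError("specific humidity must be strictly positive")
    if (frame["lstd"] < frame["lstn"]).any():
        logger.warning("%s: %d month(s) with LSTD < LSTN (kept; sanity warning only)",
                       city, int((frame["lstd"] < frame["lstn"]).sum()))
    frame.insert(0, "t", np.arange(1, len(frame) + 1))
    frame.insert(1, "city", city)
    return frame


def center_covariates(series: pd.DataFrame, covariates=CLIMATE_COLUMNS):
    """Mean-centre covariates (not scaled: coefficients stay per natural unit).

    Returns ``(centred copy, constants)`` where ``constants[name]`` is the
    subtracted mean; the fitted intercept can be mapped back to the
    uncentred model via ``beta0_uncentred = beta0 - sum_j beta_j * mean_j``.
    A constant column triggers a warning (unidentifiable against the
    intercept) but is kept.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 months to centre covariates")
    out = series.copy()
    constants = {}
    for col in covariates:
        x = out[col].astype(float)
        if float(x.std(ddof=0)) == 0.0:
            logger.warning("covariate %r is constant: coefficient not identifiable "
                           "with an intercept", col)
        constants[col] = float(x.mean())
        out[col] = x - constants[col]
    return out, constants
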