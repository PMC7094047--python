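import numpy as np
import pandas as pd
import pytest
from scipy import stats

from serpens.linelist import (
    LineList, SchemaConfig, category_proportions, describe_linelist,
    filter_venomous, incidence_interval, linelist_from_frame, median_age,
    monthly_incidence, read_linelist, restrict_to_cities,
)
from serpens.simulate import reference_linelist


def test_read_linelist_parses_wellformed_rows(raw_cases, tmp_path):
    path = tmp_path / "cases.csv"
    raw_cases.to_csv(path, index=False)
    ll = read_linelist(path)
    assert len(ll) == 3
    assert ll.report.n_rejected == 0
    recs = list(ll.records)
    assert recs[0].municipality == "porto_velho"
    assert recs[0].notify_month == pd.Period("2007-03", "M")


def test_genus_mapping_table_sends_boa_to_nonvenomous(raw_cases):
    ll = linelist_from_frame(raw_cases)
    assert list(ll.df["genus"]) == ["bothrops", "lachesis", "nonvenomous"]


def test_out_of_window_row_rejected_with_warning(raw_cases):
    raw = raw_cases.copy()
    raw.loc[1, "date"] = "2019-03"
    ll = linelist_from_frame(raw)
    assert len(ll) == 2
    assert ll.report.n_rejected == 1
    assert any("2019-03" in reason for _, reason in ll.report.rejected_rows)


def test_unparseable_date_rejected_and_missing_column_fatal(raw_cases):
    raw = raw_cases.copy()
    raw.loc[0, "date"] = "not-a-date"
    ll = linelist_from_frame(raw)
    assert len(ll) == 2 and ll.report.n_rejected == 1
    with pytest.raises(ValueError, match="missing required column"):
        linelist_from_frame(raw_cases.drop(columns=["genus"]))


def test_unknown_category_maps_to_missing_not_dropped(raw_cases):
    raw = raw_cases.copy()
    raw.loc[0, "zone"] = "floresta"
    ll = linelist_from_frame(raw)
    assert len(ll) == 3
    assert ll.df.loc[0, "zone"] == "missing"
    assert any("zone" in w for w in ll.report.warnings)


def test_filter_venomous_counts_and_idempotence():
    ll = linelist_from_frame(reference_linelist())
    assert len(ll) == 6326
    ven = filter_venomous(ll)
    assert len(ven) == 5994
    assert ven.report.n_removed_nonvenomous == 332
    again = filter_venomous(ven)
    assert len(again) == 5994 and again.report.n_removed_nonvenomous == 0
    empty = filter_venomous(LineList(ll.df.iloc[0:0]))
    assert len(empty) == 0


def test_category_proportions_fixed_denominator_convention():
    area = restrict_to_cities(filter_venomous(linelist_from_frame(reference_linelist())))
    assert len(area) == 2655
    tab = category_proportions(area, "genus", denominator=2655, decimals=1)
    assert tab.loc["bothrops", "count"] == 2171
    assert tab.loc["bothrops", "percent"] == 81.8


def test_category_proportions_edge_cases(raw_cases):
    ll = linelist_from_frame(raw_cases)
    tab = category_proportions(ll, "genus", denominator=2655, decimals=1)
    assert tab.loc["crotalus", "percent"] == 0.0
    two = linelist_from_frame(raw_cases.iloc[:2])
    sex = category_proportions(two, "sex", decimals=1)
    assert sex.loc["male", "percent"] == 50.0 and sex.loc["female", "percent"] == 50.0
    assert sex["percent"].sum() == 100.0
    with pytest.raises(ValueError):
        category_proportions(ll, "sex", denominator=0)


@pytest.mark.parametrize("variable", ["genus", "zone", "sex", "bite_site",
                                      "severity", "outcome"])
def test_percentages_over_full_partition_sum_to_100(variable):
    area = restrict_to_cities(filter_venomous(linelist_from_frame(reference_linelist())))
    tab = category_proportions(area, variable, decimals=2)
    assert tab["count"].sum() <= len(area)
    assert abs(tab["percent"].sum() - 100.0) < 0.05  # rounding slack


def test_monthly_incidence_matches_direct_arithmetic(population_table):
    rng = np.random.default_rng(5)
    periods = pd.period_range("2007-01", "2008-12", freq="M")
    counts = rng.integers(0, 10, size=24)
    rows = []
    for p, c in zip(periods, counts):
        rows += [{"date": str(p), "municipality": "cacoal", "genus": "bothrops",
                  "zone": "rural", "sex": "male", "age": 30, "bite_site": "foot",
                  "severity": "mild", "outcome": "survived"}] * c
    ll = linelist_from_frame(pd.DataFrame(rows))
    monthly, annual = monthly_incidence(ll, population_table, "cacoal",
                                        window=("2007-01", "2008-12"))
    np.testing.assert_allclose(monthly["incidence_per_100k"],
                               1e5 * counts / 85_000.0)
    assert annual.loc[0, "cases"] == counts[:12].sum()
    # equivariance: scaling population by c scales incidence by 1/c
    pop2 = population_table.copy()
    pop2["population"] *= 10
    monthly2, _ = monthly_incidence(ll, pop2, "cacoal", window=("2007-01", "2008-12"))
    np.testing.assert_allclose(monthly2["incidence_per_100k"],
                               monthly["incidence_per_100k"] / 10)


def test_monthly_incidence_simple_rate_and_zero(population_table):
    rows = [{"date": "2007-06", "municipality": "porto_velho", "genus": "bothrops",
             "zone": "rural", "sex": "male", "age": 30, "bite_site": "foot",
             "severity": "mild", "outcome": "survived"}] * 12
    ll = linelist_from_frame(pd.DataFrame(rows))
    monthly, _ = monthly_incidence(ll, population_table, "porto_velho",
                                   window=("2007-01", "2007-12"))
    june = monthly[monthly["month"] == 6].iloc[0]
    assert june["incidence_per_100k"] == pytest.approx(2.4)
    assert (monthly[monthly["month"] != 6]["incidence_per_100k"] == 0.0).all()


def test_monthly_incidence_missing_population_year_names_year(population_table):
    pop = population_table[population_table["year"] != 2010]
    rows = [{"date": "2007-06", "municipality": "porto_velho", "genus": "bothrops",
             "zone": "rural", "sex": "male", "age": 30, "bite_site": "foot",
             "severity": "mild", "outcome": "survived"}]
    ll = linelist_from_frame(pd.DataFrame(rows))
    with pytest.raises(ValueError, match="2010"):
        monthly_incidence(ll, pop, "porto_velho", window=("2007-01", "2011-12"))


def test_incidence_interval_matches_gamma_quantile_oracle():
    rate, (lo, hi) = incidence_interval(400, 1.2e7)
    a, scale = 400.5, 1.0 / 1.2e7
    assert rate == pytest.approx(1e5 * a * scale)
    assert lo == pytest.approx(1e5 * stats.gamma.ppf(0.025, a, scale=scale))
    assert hi == pytest.approx(1e5 * stats.gamma.ppf(0.975, a, scale=scale))


def test_incidence_interval_edge_behaviour():
    _, (lo, _) = incidence_interval(0, 1e6)
    assert round(lo, 2) == 0.0
    r1, (lo1, hi1) = incidence_interval(100, 1e6)
    r2, (lo2, hi2) = incidence_interval(200, 2e6)
    assert (hi2 - lo2) / r2 < (hi1 - lo1) / r1  # relative width narrows
    with pytest.raises(ValueError):
        incidence_interval(10, 0.0)


def test_describe_linelist_reference_medians_and_share(population_table):
    ll = linelist_from_frame(reference_linelist())
    summary = describe_linelist(ll, population_table)
    assert summary.denominator == 2655
    assert summary.median_age_years == 34
    assert summary.studied_area_percent() == 42
    assert summary.tables["outcome"].loc["died", "count"] == 2
    text = summary.to_text()
    assert "n=2655" in text and "42%" in text
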