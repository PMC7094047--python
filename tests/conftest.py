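import numpy as np
import pandas as pd
import pytest

from serpens import ScenarioConfig, simulate_scenario


@pytest.fixture()
def raw_cases():
    """Three well-formed raw line-list rows."""
    return pd.DataFrame({
        "date": ["2007-03", "2010-11", "2018-12"],
        "municipality": ["Porto Velho", "cacoal", "vilhena"],
        "genus": ["Bothrops", "lachesis", "Boa"],
        "zone": ["rural", "urban", "rural"],
        "sex": ["male", "female", "male"],
        "age": ["34", "21", "55"],
        "bite_site": ["foot", "leg", "hand"],
        "severity": ["mild", "severe", "moderate"],
        "outcome": ["survived", "survived", "died"],
    })


@pytest.fixture()
def population_table():
    years = range(2007, 2019)
    rows = []
    for city, base in [("porto_velho", 500_000), ("ariquemes", 100_000),
                       ("cacoal", 85_000), ("vilhena", 90_000)]:
        for y in years:
            rows.append({"city": city, "year": y, "population": base})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_bundle():
    """A T=60 synthetic scenario shared by model-level tests."""
    return simulate_scenario(ScenarioConfig(T=60, seed=11))
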