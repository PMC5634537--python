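import numpy as np
import pandas as pd
import pytest

from crvital.filters import FLAG_COLUMNS


def make_incident(record_id, mechanism="firearm", injury_date="2015-06-01",
                  death_year=2015, **flags):
    row = {
        "record_id": record_id,
        "given_name": "Avan",
        "surname": "Torell",
        "age": 30,
        "gender": "man",
        "race_ethnicity": "white",
        "injury_date": pd.Timestamp(injury_date),
        "death_year": death_year,
        "state": "S01",
        "county_id": "S01C001",
        "mechanism": mechanism,
        "external_confirmation": bool(flags.pop("external_confirmation", False)),
    }
    for f in FLAG_COLUMNS:
        row[f] = bool(flags.get(f, False))
    return row


@pytest.fixture
def raw_case_table():
    """1,146 raw cases engineered to the published exclusion tallies.

    27 vehicle-struck outside pursuit, 6 domestic violence, 23 custody
    deaths without a qualifying mechanism, 3 deaths in the following year,
    1 friendly fire, and 1,086 clean cases.
    """
    rows = []
    i = 0

    def add(n, **kw):
        nonlocal i
        for _ in range(n):
            i += 1
            rows.append(make_incident(f"R{i:05d}", **kw))

    add(27, mechanism="motor_vehicle")
    add(6, domestic_violence=True)
    add(23, mechanism="other_custody", in_custody=True)
    add(3, death_year=2016)
    add(1, friendly_fire=True)
    add(1086)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def paper_cells():
    """Published aggregate two-list cells (media-only, vital-only, both)."""
    return pd.DataFrame([{"stratum": "2015", "n10": 599, "n01": 36, "n11": 487}])


@pytest.fixture(scope="session")
def noisy_cohort():
    """A 1,000-death synthetic cohort with identifier noise, shared across tests."""
    from crvital.synthetic import IdentifierNoise, SyntheticConfig, simulate

    config = SyntheticConfig(
        true_total=1000,
        seed=424242,
        identifier_noise=IdentifierNoise(surname_typo_prob=0.1, birth_year_error_prob=0.1),
    )
    return simulate(config)
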