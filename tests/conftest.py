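import numpy as np
import pandas as pd
import pytest

from affectprice.prep import (
    BEVERAGE_COLUMNS,
    COVARIATE_COLUMNS,
    NEUROTICISM_COLUMNS,
    PHQ4_COLUMNS,
)


def make_raw_records(rows: list[dict]) -> pd.DataFrame:
    """Hand-built raw records with every required column defaulted clean."""
    base = {
        "participant_id": 0,
        "wave": 0,
        "income_band": 3,
        "drink_frequency": "1-2_per_week",
        "neurological_condition": 0,
        "alcohol_dependence": 0,
    }
    for c in BEVERAGE_COLUMNS:
        base[c] = 1
    for c in PHQ4_COLUMNS:
        base[c] = 1
    for c in NEUROTICISM_COLUMNS:
        base[c] = 0
    for c in COVARIATE_COLUMNS:
        base[c] = 1.0
    return pd.DataFrame([{**base, **r} for r in rows])


@pytest.fixture
def toy_records():
    """10 clean single-wave participants."""
    return make_raw_records([{"participant_id": i} for i in range(10)])


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    from affectprice.synthetic import SimulationConfig, generate_cohort

    return generate_cohort(SimulationConfig(n_participants=1500, seed=11))
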