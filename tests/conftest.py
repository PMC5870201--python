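"""Shared fixtures: small synthetic datasets and tiny hand-built tables."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

from carenet.config import SynthConfig
from carenet.synthetic import generate_dataset

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


#: Study conditions for planted-recovery checks: 4 communities of 30
#: providers each at 5% leakage.
RECOVERY_CONFIG = SynthConfig(
    n_communities=4,
    providers_per_community=30,
    patients_per_community=200,
    leakage_rate=0.05,
    seed=424242,
)


@pytest.fixture(scope="session")
def recovery_dataset():
    return generate_dataset(RECOVERY_CONFIG)


@pytest.fixture(scope="session")
def small_dataset():
    """A fast 2-community dataset for unit-level checks."""
    return generate_dataset(
        SynthConfig(
            n_communities=2,
            providers_per_community=10,
            patients_per_community=40,
            leakage_rate=0.1,
            seed=7,
        )
    )


@pytest.fixture()
def tiny_visits():
    """Hand-built visit table: 2 patients over 3 providers."""
    return pd.DataFrame(
        {
            "patient_id": ["p1", "p1", "p1", "p2", "p2"],
            "npi": ["A", "A", "B", "A", "B"],
            "start_date": ["2014-01-05", "2014-02-01", "2014-03-01",
                           "2014-01-10", "2014-04-01"],
            "spend": [10.0, 20.0, 30.0, 5.0, 15.0],
        }
    )
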