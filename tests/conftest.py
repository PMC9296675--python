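"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pimohet.config import SimulationConfig
from pimohet.synthgen import generate_cohort

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Ten patients with rendered sections; shared read-only across tests."""
    return generate_cohort(SimulationConfig(n_patients=10, seed=42))


@pytest.fixture(scope="session")
def tableonly_cohort():
    """Thirty fully paired patients without images (fast tabular fixture)."""
    return generate_cohort(
        SimulationConfig(n_patients=30, fraction_paired=1.0, seed=7), render_images=False
    )


@pytest.fixture()
def sample_sheet_pairs():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4", "s5"],
            "patient_id": ["p1", "p1", "p2", "p2", "p3"],
            "order_label": ["T1", "T2", "T1", "T2", "T1"],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
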