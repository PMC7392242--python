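"""Shared fixtures: reference networks, hypothesis model, small synthetic
tables and chain networks used across the suite."""

import numpy as np
import pandas as pd
import pytest

from odornet.datasets import (
    PcorNetwork,
    load_hypothesis_model,
    load_odor_profiles,
    load_reference_networks,
)
from odornet.synthetic import GeneratorConfig, simulate_study, uniform_profiles


@pytest.fixture(scope="session")
def uoea():
    return load_reference_networks()[0]


@pytest.fixture(scope="session")
def poea():
    return load_reference_networks()[1]


@pytest.fixture(scope="session")
def hypothesis_model():
    return load_hypothesis_model()


@pytest.fixture(scope="session")
def odor_profiles():
    return load_odor_profiles()


@pytest.fixture(scope="session")
def small_study():
    """A 20-participant study with homogeneous profiles (fast, deterministic)."""
    cfg = GeneratorConfig(n_participants=20, profiles=uniform_profiles(), seed=11)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """A full default-condition study (52 participants, packaged profiles)."""
    return simulate_study(GeneratorConfig(seed=5))


@pytest.fixture()
def chain4():
    """4-node chain network with partial correlation 0.4 per link."""
    w = np.zeros((4, 4))
    for i in range(3):
        w[i, i + 1] = w[i + 1, i] = 0.4
    return PcorNetwork(("a", "b", "c", "d"), w)


@pytest.fixture()
def tiny_ratings():
    """Hand-made ratings: 10 participants x 2 odors, constant except one cell."""
    rows = []
    for pid in range(1, 11):
        rows.append((pid, 1, 1.0, 0.5, 0.0 if pid == 7 else 50.0, 60.0))
        rows.append((pid, 2, -1.0, -0.5, 40.0, 55.0))
    return pd.DataFrame(rows, columns=["participant_id", "odor_id", "valence",
                                       "arousal", "intensity", "familiarity"])
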