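import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from dyadgaze import AnalysisConfig
from dyadgaze.synthetic import (CohortSpec, default_profiles,
                                generate_cohort, with_off_face)


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-group cohort with a speaking/listening face-looking gap,
    shared across tests that only read from it."""
    profiles = default_profiles()
    speaking = with_off_face(profiles["western"], 0.45)
    listening = with_off_face(profiles["western"], 0.15)
    spec = CohortSpec(n_per_group=3, session_duration_s=30.0,
                      loss_rate=0.08, motion_amplitude_px=30.0, seed=42)
    return generate_cohort(spec, {"speaking": speaking,
                                  "listening": listening},
                           {"speaking": speaking, "listening": listening})
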