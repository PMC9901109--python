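from pathlib import Path

import numpy as np
import pytest

from wcesurv import ArmParams, EventTypeCatalog, read_trial_table, simulate_arm

DATA = Path(__file__).parent / "data"

# generator conditions used throughout: trial-derived treatment-arm targets
# with the calibrated incident-rate coefficient and no-event sojourn
TREATMENT = ArmParams((0.06, 0.05, 0.04, 0.03), no_event_mean=16.28, rate_coefficient=2.045)
CONTROL = ArmParams((0.03, 0.04, 0.05, 0.06), no_event_mean=16.28, rate_coefficient=2.045)
FOLLOWUP = 30.0


@pytest.fixture(scope="session")
def catalog():
    return EventTypeCatalog.mace_default()


@pytest.fixture(scope="session")
def fixture25(catalog):
    """The packaged synthetic 25-subject trial table."""
    arms = read_trial_table(DATA / "trial25_synthetic.csv", catalog, FOLLOWUP)
    (histories,) = arms.values()
    assert len(histories) == 25
    return histories


@pytest.fixture(scope="session")
def sim_arm(catalog):
    """One simulated treatment arm of 400 subjects (fixed seed)."""
    return simulate_arm(TREATMENT, catalog, "treatment", 400, base_seed=17, arm_position=0)


@pytest.fixture(scope="session")
def sim_trial(catalog):
    """Small two-arm trial, 300 subjects per arm."""
    return {
        "treatment": simulate_arm(TREATMENT, catalog, "treatment", 300, 23, 0),
        "control": simulate_arm(CONTROL, catalog, "control", 300, 23, 1),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20230206)
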