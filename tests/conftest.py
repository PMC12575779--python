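import numpy as np
import pytest

from jawfl import (
    GeneratorConfig,
    MusclePrep,
    build_fl_curve,
    fit_buckle_calibration,
    make_muscle_truth,
    simulate_calibration_pair,
    simulate_ergometry_session,
)


@pytest.fixture(scope="session")
def truth():
    """One default-population ground-truth muscle."""
    return make_muscle_truth(GeneratorConfig(), seed=1)


@pytest.fixture(scope="session")
def prep(truth):
    return MusclePrep(pcsa_cm2=truth.pcsa, fixed_end_compliance_mm=truth.series_compliance)


@pytest.fixture(scope="session")
def tetanic_session(truth):
    return simulate_ergometry_session(truth, protocol="tetanic", noise=0.0, seed=1)


@pytest.fixture(scope="session")
def twitch_session(truth):
    return simulate_ergometry_session(truth, protocol="twitch", noise=0.0, seed=1)


@pytest.fixture(scope="session")
def tetanic_curve(tetanic_session, prep):
    return build_fl_curve(tetanic_session, prep, "tetanic")


@pytest.fixture(scope="session")
def calibration_model(truth):
    trials = simulate_calibration_pair(truth, 5, noise=1.0, seed=11)
    pairs = [(t.channel("buckle_voltage"), t.channel("force")) for t in trials]
    windows = [t.truth["rise_window"] for t in trials]
    return fit_buckle_calibration(pairs, windows)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
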