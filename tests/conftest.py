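"""Shared fixtures: synthetic sessions reused across test modules.

Heavy session-scope fixtures are built once; tests must not mutate them.
"""

from __future__ import annotations

import pytest

from bhcvr.echo_combine import combination_weights
from bhcvr.pipeline import analyze_session, session_t2star_fit
from bhcvr.synthetic import (
    NoiseModel,
    PhantomConfig,
    combined_truth_amplitude as _truth_amplitude,
    generate_phantom,
    simulate_session,
)
from bhcvr.task_design import BHParadigm

PHANTOM_SEED = 11
NOISE_SEED = 23
QUIET_PHANTOM_SEED = 7


@pytest.fixture(scope="session")
def paradigm() -> BHParadigm:
    return BHParadigm()


@pytest.fixture(scope="session")
def default_truth():
    return generate_phantom(seed=PHANTOM_SEED)


@pytest.fixture(scope="session")
def default_session(default_truth, paradigm):
    """Default study conditions: realistic amplitudes, thermal noise on."""
    return simulate_session(
        default_truth, paradigm, None, NoiseModel(seed=NOISE_SEED)
    )


@pytest.fixture(scope="session")
def default_analysis(default_session):
    return analyze_session(default_session)


@pytest.fixture(scope="session")
def quiet_session(paradigm):
    """Small-amplitude, zero-noise session for linear-regime recovery checks."""
    truth = generate_phantom(
        seed=QUIET_PHANTOM_SEED, config=PhantomConfig(amplitude_scale=0.1)
    )
    noise = NoiseModel(sigma_thermal=0.0, resp_amp=0.0, drift_coeffs=())
    return simulate_session(truth, paradigm, None, noise)


@pytest.fixture(scope="session")
def quiet_analysis(quiet_session):
    return analyze_session(quiet_session)


def combined_truth_amplitude(session, fit):
    """Ground-truth peak amplitude of the combined series for a T2* fit."""
    return _truth_amplitude(session, combination_weights(fit))
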