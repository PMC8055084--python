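import numpy as np
import pytest

from freqtrack import ForwardModel, generate_session, simulate_recording

SMALL_SESSION_CFG = {"formal_per_condition": 10, "catch_per_condition": 0,
                     "n_blocks": 1}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_session():
    """Ten formal trials per condition, no catch trials."""
    return generate_session("fixture", SMALL_SESSION_CFG, rng_seed=7)


@pytest.fixture(scope="session")
def full_session():
    """The full default design (50 formal + 10 catch per condition)."""
    return generate_session("fixture-full", rng_seed=11)


@pytest.fixture(scope="session")
def small_forward():
    return ForwardModel(n_locations=8, srate=300.0, seed=0)


@pytest.fixture(scope="session")
def p_large_recording(small_session, small_forward):
    """P-cycle, N-large recording at the default synthetic SNR."""
    return simulate_recording(small_session, small_forward, tmin=0.0, tmax=6.0,
                              conditions=[("P", "large")],
                              rng=np.random.default_rng(5))


@pytest.fixture(scope="session")
def u_large_recording(small_session, small_forward):
    """U-cycle, N-large recording (p aperiodic, decodable)."""
    return simulate_recording(small_session, small_forward, tmin=0.0, tmax=6.0,
                              conditions=[("U", "large")],
                              rng=np.random.default_rng(6))
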