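import numpy as np
import pytest

from iopgaze.simulate import CohortSpec, SimulationParams, build_protocol


@pytest.fixture
def silent_params() -> SimulationParams:
    """All stochastic and transient terms off: pure plateau signal."""
    return SimulationParams(
        noise_sd=0.0, drift_sd=0.0, pulse_amp=0.0, spike_amp=0.0,
        eyelid_spike_amp=0.0, eyelid_tau=0.0, spike_tau=0.0,
    )


@pytest.fixture
def one_block_schedule():
    """Single eccentricity block (25 deg), one repetition."""
    return build_protocol(eccentricities=(25.0,), n_repetitions=1)


@pytest.fixture
def homogeneous_spec() -> CohortSpec:
    """Cohort with no between-patient variation."""
    return CohortSpec(
        offset_dispersion=0.0, response_gain_sd=0.0, baseline_sd=0.0,
        eyelid_offset_sd=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
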