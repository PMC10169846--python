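import numpy as np
import pytest

from cntpore.synthetic_data import SimulationConfig, simulate_trace


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def study_trace():
    """300 s recording at the translocation study conditions.

    70 pA baseline, 2 pA noise, 150 events/min, depth 0.442, exponential
    dwell mean 1 ms, 100 kHz sampling, 5 kHz Bessel corner. Session-scoped:
    simulated once and shared by the recovery tests.
    """
    config = SimulationConfig(
        baseline_current_pa=70.0,
        noise_sigma_pa=2.0,
        event_rate_per_min=150.0,
        blockade_depth=0.442,
        dwell_mean_ms=1.0,
        duration_s=300.0,
        sampling_rate_hz=100_000.0,
        filter_cutoff_hz=5_000.0,
        seed=1,
    )
    trace, truth = simulate_trace(config)
    return config, trace, truth
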