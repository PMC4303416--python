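import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from edrs import SimConfig, simulate_session

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.function_scoped_fixture,  # files are overwritten per example
    ],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ps_noise_free():
    """Noise-free PS session with spontaneous effort, 10 breaths."""
    cfg = SimConfig(noise_sd_paw=0.0, noise_sd_flow=0.0, n_breaths=10, seed=3)
    record, truth = simulate_session(cfg)
    return cfg, record, truth


@pytest.fixture(scope="session")
def nava_noise_free():
    """Noise-free NAVA session with spontaneous effort, 10 breaths."""
    cfg = SimConfig(mode="NAVA", noise_sd_paw=0.0, noise_sd_flow=0.0,
                    n_breaths=10, seed=3)
    record, truth = simulate_session(cfg)
    return cfg, record, truth


@pytest.fixture(scope="session")
def passive_session():
    """Machine-triggered passive patient (no effort), E = 30 cmH2O/L."""
    cfg = SimConfig(e_lung=25.0, e_chest=5.0, pmus_amplitude_mean=0.0,
                    noise_sd_paw=0.0, noise_sd_flow=0.0, n_breaths=6, seed=5)
    record, truth = simulate_session(cfg)
    return cfg, record, truth


@pytest.fixture
def square_wave_record():
    """Square-wave flow: +0.5 L/s for 1 s, -0.5 L/s for 1 s, 5 cycles, 100 Hz."""
    from edrs import WaveformRecord

    dt = 0.01
    cycle = np.concatenate([np.full(100, 0.5), np.full(100, -0.5)])
    flow = np.tile(cycle, 5)
    n = flow.size
    return WaveformRecord(
        patient_id="sq", mode="PS", sample_interval=dt,
        time=np.arange(n) * dt, paw=np.full(n, 5.0), flow=flow,
    ).validate()
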