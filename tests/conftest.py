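import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def quiet_short_recording():
    """Noise-free healthy recording with an idealized (blur-free) forward
    model: 30 s of baseline ventilation at 40 Hz, everything open."""
    import eitvent as ev

    cfg = ev.healthy_preset(
        noise_sd=0.0, psf_sigma_px=0.0, opening_rate=0.0, closing_rate=0.0,
        lag_tau=0.02, seed=7,
    )
    rng = np.random.default_rng(7)
    truth = ev.make_phantom(cfg, rng)
    trace = ev.pressure_waveform(ev.baseline_program(duration=30.0), 40.0)
    seq = ev.simulate_sequence(truth, trace, cfg, rng)
    return cfg, truth, trace, seq
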