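import numpy as np
import pytest

from achdyn import simulate as sim


@pytest.fixture(scope="session")
def small_config() -> sim.SynthConfig:
    """A short default-parameter session for cheap end-to-end checks."""
    return sim.SynthConfig(session_duration=120.0)


@pytest.fixture(scope="session")
def rendered_session(small_config):
    """One fully rendered session (raw photometry + ground truth)."""
    rng = np.random.default_rng(42)
    labels = sim.simulate_behavior(small_config, rng)
    pose, speed = sim.simulate_trajectory(labels, small_config, rng)
    latent = sim.simulate_latent(speed, labels, small_config, seed=rng)
    raw, truth = sim.render_photometry(latent, small_config, rng)
    truth.true_speed = speed
    return raw, truth, labels, pose


@pytest.fixture(scope="session")
def model_cohort(small_config):
    """A small cohort at the model readout level (latent + white noise)."""
    sessions, truth = sim.simulate_aligned_cohort(
        small_config, 3, 4, seed=7, response="model"
    )
    return sessions, truth
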