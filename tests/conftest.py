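import numpy as np
import pytest

from cycif.synth import SimConfig, simulate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_experiment():
    """A modest noiseless 3-cycle experiment reused across modules."""
    cfg = SimConfig(
        image_height=192,
        image_width=192,
        n_cells=15,
        n_cycles=3,
        channels_per_cycle=[["mA", "mB"], ["mC"], ["mD"]],
        drift_sigma=2.0,
        noise_sigma=0.0,
        loss_rate_early=0.0,
        loss_rate_late=0.0,
        seed=7,
    )
    return cfg, *simulate_experiment(cfg)


@pytest.fixture(scope="session")
def noisy_experiment():
    """Same geometry with realistic noise (SNR >= 10 on every channel)."""
    cfg = SimConfig(
        image_height=192,
        image_width=192,
        n_cells=15,
        n_cycles=3,
        channels_per_cycle=[["mA", "mB"], ["mC"], ["mD"]],
        drift_sigma=2.0,
        noise_sigma=15.0,
        loss_rate_early=0.0,
        loss_rate_late=0.0,
        seed=7,
    )
    return cfg, *simulate_experiment(cfg)
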