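import numpy as np
import pytest

from cevalid import Electropherogram, SimulationConfig


@pytest.fixture
def noiseless_config() -> SimulationConfig:
    """Simulator config with every noise source switched off."""
    return SimulationConfig(noise_sd=0.0, migration_jitter_sd=0.0, baseline_noise_sd=0.0)


def gaussian_eg(
    apexes=(3.2,),
    heights=(10.0,),
    sigma=0.02,
    rate=600.0,
    length=5.0,
    baseline_level=0.0,
    drift=0.0,
    noise_sd=0.0,
    seed=0,
) -> Electropherogram:
    """Hand-built electropherogram: Gaussians on a linear baseline."""
    t = np.arange(int(round(length * rate)) + 1) / rate
    y = baseline_level + drift * t
    for apex, h in zip(apexes, heights):
        y = y + h * np.exp(-0.5 * ((t - apex) / sigma) ** 2)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    return Electropherogram(time=t, signal=y, metadata={"sample_label": "fixture"})
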