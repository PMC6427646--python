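import numpy as np
import pytest

from spiketempo.data import Dataset, SpikeTrain, Trial
from spiketempo.lif import LIFParams
from spiketempo.synth import SynthConfig, generate_synthetic


def random_trial(rng, n_channels=5, duration=1.0, rate=20.0, label=None):
    """Homogeneous-Poisson trial used as generic test input."""
    trains = []
    for c in range(n_channels):
        n = rng.poisson(rate * duration)
        times = np.unique(rng.uniform(0.0, duration, size=n))
        trains.append(SpikeTrain(c, times))
    return Trial(trains=tuple(trains), duration=duration, label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def params():
    return LIFParams(tau=0.1, tau_s=0.025)


@pytest.fixture
def small_trial(rng):
    return random_trial(rng)


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default-condition dataset: 11 channels, 4 classes, 20 trials/class."""
    return generate_synthetic(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def two_class_clean():
    """Jitter-free, background-free latency code: trivially separable."""
    cfg = SynthConfig(
        n_channels=11, n_classes=2, trials_per_class=10, duration=5.0,
        base_rate=0.0, template_spikes_per_channel=6, jitter_sd=0.0,
        rate_contrast=0.0, seed=5,
    )
    return generate_synthetic(cfg)


def make_dataset(trials, n_channels, classes=(), duration=0.0):
    return Dataset(
        trials=tuple(trials), n_channels=n_channels,
        classes=tuple(classes), duration=duration,
    )
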