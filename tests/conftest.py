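import numpy as np
import pytest

from sprtbci import EpochSet, SegmentationScheme, SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Mid-difficulty two-class dataset at the generator defaults."""
    epochs, truth = generate_dataset(SyntheticConfig(seed=3))
    return epochs, truth


@pytest.fixture(scope="session")
def quick_config():
    """Small, fast mu-only configuration for unit tests."""
    return SyntheticConfig(
        sampling_rate=32.0,
        n_trials_per_class=16,
        trial_duration=6.0,
        cue_time=2.0,
        band_amplitudes={"mu": 1.0, "beta": 0.0},
        erd_depth={("R", "C3", "mu"): 0.4, ("L", "C4", "mu"): 0.4},
        noise_sigma=1.0,
        amplitude_cv=0.2,
        seed=7,
    )


@pytest.fixture(scope="session")
def quick_dataset(quick_config):
    return generate_dataset(quick_config)


@pytest.fixture(scope="session")
def recovery_config():
    """Strong-effect configuration with an identifiable planted direction."""
    return SyntheticConfig(
        sampling_rate=64.0,
        n_trials_per_class=60,
        trial_duration=6.0,
        cue_time=2.0,
        band_amplitudes={"mu": 1.0, "beta": 0.0},
        erd_depth={("L", "C3", "mu"): 0.3, ("R", "C4", "mu"): 0.3},
        noise_sigma=1.0,
        amplitude_cv=0.1,
        phase_locking=0.9,
        seed=100,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epochs(n_trials=4, n_channels=2, n_samples=32, fs=16.0, cue=1.0, labels=None):
    """Tiny deterministic EpochSet for plumbing tests."""
    data = np.arange(n_trials * n_channels * n_samples, dtype=float).reshape(
        n_trials, n_channels, n_samples
    )
    names = tuple(f"ch{i}" for i in range(n_channels))
    return EpochSet(
        data=data, sampling_rate=fs, cue_time=cue, labels=labels, channel_names=names
    )
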