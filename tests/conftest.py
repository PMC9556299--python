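import numpy as np
import pytest

from breathpd import synthetic_data as sd
from breathpd.model_core import ModelConfig, PDBreathingModel


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230301)


@pytest.fixture(scope="session")
def tiny_model():
    """Small untrained model shared by contract tests (read-only)."""
    return PDBreathingModel(ModelConfig(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """8+8 wireless subjects, 2 x 10-min nights each, with qEEG/hypnograms."""
    cfg = sd.SimConfig(n_subjects={"wireless": (8, 8)}, nights_per_subject=2,
                       night_s=600.0)
    return sd.simulate_cohort(cfg, seed=11)


def breathing_like(n_samples: int, f_b: float = 10.0, rate: float = 0.25,
                   noise: float = 0.05, seed: int = 0) -> np.ndarray:
    """A clean quasi-sinusoidal breathing trace for I/O and screening tests."""
    g = np.random.default_rng(seed)
    t = np.arange(n_samples) / f_b
    return np.sin(2 * np.pi * rate * t) + noise * g.normal(size=n_samples)
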