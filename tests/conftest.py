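import numpy as np
import pytest

from wakewatch.synthetic_data import SceneConfig, generate_wake_video


@pytest.fixture(scope="session")
def birds_only_scene():
    """Noiseless 3-bird scene reused by detection and tracking tests."""
    cfg = SceneConfig(n_birds=3, n_foam_patches=0, glint_rate=0.0,
                      duration=3.0, fps=10.0, seed=3)
    seq, gt = generate_wake_video(cfg)
    return cfg, seq, gt


@pytest.fixture(scope="session")
def small_chip_sets():
    """Small labelled train/validation chip sets for classifier tests."""
    from wakewatch.synthetic_data import generate_chip_dataset

    train = generate_chip_dataset(120, seed=21)
    val = generate_chip_dataset(120, seed=22)
    return train, val


@pytest.fixture
def rng():
    return np.random.default_rng(0)
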