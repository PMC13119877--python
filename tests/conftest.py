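import numpy as np
import pytest

from motionfuse.synthgen import GeneratorConfig, generate_dataset
from motionfuse.preprocess import PreprocessConfig, SessionPreprocessor


@pytest.fixture(scope="session")
def small_cfg():
    """Small but structurally complete generator configuration."""
    return GeneratorConfig(n_subjects=10, trials_per_subject=6, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def desk_pre_cfg():
    """Desk-scale preprocessing grid: 16 Hz unified grid, 4 s windows."""
    return PreprocessConfig(grid_rate=16.0, window_seconds=4.0,
                            window_stride_seconds=4.0)


@pytest.fixture(scope="session")
def small_windows(small_dataset, desk_pre_cfg):
    sessions, manifest = small_dataset
    pre = SessionPreprocessor(desk_pre_cfg)
    return pre.fit_transform(sessions)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
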