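import numpy as np
import pytest

from dgcn import (
    EncoderConfig,
    SyntheticSpec,
    TrainConfig,
    generate_dataset,
)
from dgcn.trainer import TrainingState


@pytest.fixture(scope="session")
def tiny_set():
    """24 images, 3 grades, 16 px — fast input for graph/encoder plumbing."""
    spec = SyntheticSpec(n_per_grade=8, image_size=16, grades=(0, 2, 4), seed=7)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_state():
    """Untrained state with a small feature dim for forward-pass tests."""
    cfg = TrainConfig(seed=3, encoder=EncoderConfig(feature_dim=8))
    return TrainingState(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
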