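import numpy as np
import pytest

from ecggen.networks import GANConfig
from ecggen.segmentation import MITBIH_CLASSES, downsample
from ecggen.simulate import BeatTemplateParams, make_imbalanced_dataset, synth_record


@pytest.fixture(scope="session")
def balanced_dataset():
    """250 clean, separable beats (50 per class), z-scored, length 300."""
    return make_imbalanced_dataset(
        {"N": 50, "A": 50, "V": 50, "L": 50, "R": 50}, seed=101
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Short-beat dataset (length 50) for fast training smoke tests."""
    ds = make_imbalanced_dataset(
        {"N": 60, "A": 20, "V": 30, "L": 25, "R": 25}, seed=202
    )
    return downsample(ds, 6)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small network configuration matching the length-50 beats."""
    return GANConfig(seq_len=50, model_width=16, n_heads=2, n_classes=5,
                     dropout=0.0, batch_size=32, learning_rate=1e-3)


@pytest.fixture()
def fixture_record():
    """Annotated synthetic record with all five beat classes, low noise."""
    rng = np.random.default_rng(7)
    seq = list(rng.permutation(["N"] * 20 + ["A", "V", "L", "R"] * 5))
    return synth_record(seq, BeatTemplateParams(noise_sd=0.02), seed=7)


@pytest.fixture()
def noiseless_params():
    return BeatTemplateParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def cmap():
    return MITBIH_CLASSES
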