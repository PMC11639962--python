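import numpy as np
import pytest

from mshts.synthetic import ImagingModel, SampleTruth


@pytest.fixture
def small_model() -> ImagingModel:
    """Minimal-size imaging model (432 x 432, the analysis crop itself)
    with puncta density matched to the default model, for fast tests."""
    return ImagingModel(image_shape=(432, 432), lambda_max=280.0)


@pytest.fixture
def truth_mid() -> SampleTruth:
    return SampleTruth("mid", ec50_true=10.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
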