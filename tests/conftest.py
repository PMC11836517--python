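import numpy as np
import pytest

from anisotex import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_tensile():
    """Noiseless synthetic tensile record with its exact ground truth."""
    spec = synthetic.SyntheticTensileSpec(noise_sd=0.0, seed=1)
    record, specimen, truth = synthetic.gen_tensile_curve(spec)
    return spec, record, specimen, truth


@pytest.fixture
def stripes_image():
    spec = synthetic.SyntheticMicrographSpec(
        shape=(256, 256), texture="stripes", stripe_angle=30.0, seed=0
    )
    image, _, direction = synthetic.gen_fibrous_micrograph(spec)
    return image, direction
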