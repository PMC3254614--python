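import numpy as np
import pytest

from fionmri.synthetic import PhantomSpec, SceneSpec


@pytest.fixture
def acquisition_tes():
    """The four-echo gradient-echo acquisition used for phantom relaxometry."""
    return np.array([4.9, 13.6, 22.3, 57.0])


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def noiseless_phantom_spec():
    return PhantomSpec(noise_sigma=0.0, seed=0)


@pytest.fixture
def default_scene_spec():
    return SceneSpec(seed=7)
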