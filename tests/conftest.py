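import numpy as np
import pytest

from photoacclim.profile import LeafTraits, ProfileParams
from photoacclim.synth import treatment_leaf_params


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def default_profile():
    """Typical fitted profile parameters for a mid-canopy leaf."""
    return ProfileParams.from_p1ka(0.033, 0.10, 0.664)


@pytest.fixture
def tomato_traits():
    return LeafTraits(chl=40.0, car=8.0, lma=40.0)


@pytest.fixture(scope="session")
def cucumber_leaf_params():
    """Optical parameters of the four step-change cucumber leaves, run once
    through the full trait pipeline (deterministic)."""
    return treatment_leaf_params()
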