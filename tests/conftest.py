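import numpy as np
import pytest

import lesionkit as lk


@pytest.fixture(scope="session")
def template():
    """Desk-scale symmetric template: 24^3 voxels at 2 mm isotropic."""
    return lk.make_template(seed=0)


@pytest.fixture(scope="session")
def small_template():
    return lk.make_template(shape=(12, 12, 12), seed=0)


@pytest.fixture(scope="session")
def deficit_region(template):
    return lk.make_lesion(template, (15, 15, 15), 5.0)


@pytest.fixture(scope="session")
def lesion(template):
    return lk.make_lesion(template, (8, 12, 12), 6.0)


@pytest.fixture(scope="session")
def atlas(template):
    return lk.make_tract_atlas(template, n_tracts=3, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
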