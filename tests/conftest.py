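import numpy as np
import pytest

from levelseg.domain import GridDomain, ScalarField
from levelseg.synthetic import make_disk_image


@pytest.fixture(scope="session")
def disk128():
    """Soft-edged disk image on a 128x128 unit-normalized grid."""
    return make_disk_image(size=(128, 128))


@pytest.fixture()
def unit_square_domain():
    return GridDomain(shape=(32, 32), spacing=(1 / 32, 1 / 32))


@pytest.fixture()
def random_field(unit_square_domain):
    rng = np.random.default_rng(42)
    return ScalarField(unit_square_domain, rng.uniform(0, 1, unit_square_domain.shape))
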