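import numpy as np
import pytest

from xldock.restraints import default_registry
from xldock.synthetic import BundleConfig, make_bundle, plant_peptide


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def bundle():
    return make_bundle(BundleConfig())


@pytest.fixture(scope="session")
def planted(bundle):
    """Planted helical 8-mer in the default bundle, with ground truth."""
    return plant_peptide(bundle, "SNREKLLA", pose="helical")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rigid(rng):
    """A uniformly random proper rotation + a translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-20, 20, 3)
    return Q, t
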