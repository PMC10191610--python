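import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from se3refine.synthetic import make_native, perturb, PerturbSpec


def random_rigid(rng: np.random.Generator):
    """A random proper rotation and translation."""
    rot = Rotation.random(random_state=int(rng.integers(0, 2**31 - 1))).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return rot, t


@pytest.fixture(scope="session")
def helix_ala():
    """10-residue poly-alanine ideal helix."""
    return make_native(10, sequence="A" * 10, geometry="helix", seed=1)


@pytest.fixture(scope="session")
def helix_mixed():
    """16-residue mixed-sequence helix."""
    return make_native(16, geometry="helix", seed=5)


@pytest.fixture(scope="session")
def perturbed_pair(helix_mixed):
    """(initial, native) with 0.3 Å jitter."""
    return perturb(helix_mixed, PerturbSpec(cartesian_sigma=0.3, seed=2)), helix_mixed
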