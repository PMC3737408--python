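import numpy as np
import pytest

from chewspace import (
    Ensemble,
    ResidueSubsetSpec,
    SyntheticSpec,
    make_ensemble,
    make_toy_structure,
)


@pytest.fixture(scope="session")
def helix30():
    spec = SyntheticSpec(n_residues=30, n_models=1, tail_length=5, seed=11)
    return make_toy_structure(spec)


@pytest.fixture(scope="session")
def hairpin40():
    spec = SyntheticSpec(
        n_residues=40, n_models=1, tail_length=6, seed=11, geometry="hairpin"
    )
    return make_toy_structure(spec)


@pytest.fixture(scope="session")
def noisy_pair(helix30):
    """Two jittered copies of the helix: rigid core, floppy 5-residue tails."""
    spec = SyntheticSpec(
        n_residues=30, n_models=2, tail_length=5, core_noise=0.2, tail_noise=2.5,
        seed=7,
    )
    ens = make_ensemble(helix30, spec)
    return ens[0], ens[1]


@pytest.fixture(scope="session")
def small_ensemble(helix30):
    spec = SyntheticSpec(
        n_residues=30, n_models=5, tail_length=5, core_noise=0.3, tail_noise=1.5,
        seed=3,
    )
    return make_ensemble(helix30, spec)


@pytest.fixture
def core_spec():
    return ResidueSubsetSpec("core", ((6, 25),), "backbone")


@pytest.fixture
def all_backbone():
    return ResidueSubsetSpec("all", ((1, 30),), "backbone")


@pytest.fixture
def all_heavy():
    return ResidueSubsetSpec("all", ((1, 30),), "all_heavy")


def random_rigid_transform(rng):
    """A uniformly random proper rotation and a random translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    t = rng.normal(scale=5.0, size=3)
    return R.as_matrix(), t
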