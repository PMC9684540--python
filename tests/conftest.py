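import numpy as np
import pytest

from foldsmith.fixtures import Fixture, FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def ideal_helix12():
    return make_fixture(FixtureSpec("ideal-helix", length=12)).chain


@pytest.fixture(scope="session")
def ideal_strand6():
    return make_fixture(FixtureSpec("ideal-strand", length=6)).chain


@pytest.fixture(scope="session")
def hairpin_fixture() -> Fixture:
    return make_fixture(FixtureSpec("hairpin", length=5))


@pytest.fixture(scope="session")
def bundle_fixture() -> Fixture:
    return make_fixture(FixtureSpec("three-helix-bundle", length=14, separation=10.5))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_rotation_translation(rng):
    """A proper random rigid motion (rotation matrix, translation)."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=int(rng.integers(2**16))).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return R, t


def apply_rigid(chain, R, t):
    moved = chain.copy()
    moved.coords = chain.coords @ R.T + t
    return moved
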