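import numpy as np
import pytest

from pda import (
    ElectronConfiguration,
    GaussianMixtureDensity,
    MoleculeGeometry,
    STOrbital,
    SlaterDeterminantDensity,
    build_h2_cas,
    build_h2_hartree_fock,
)


@pytest.fixture(scope="session")
def h2_cas():
    return build_h2_cas(1.4, 1.0)


@pytest.fixture(scope="session")
def h2_rhf():
    return build_h2_hartree_fock(1.4, 1.0)


@pytest.fixture(scope="session")
def gauss1():
    """Single electron, isotropic unit Gaussian at the origin."""
    return GaussianMixtureDensity(
        electrons=[([1.0], [[0.0, 0.0, 0.0]], [1.0])], spins=[0.5]
    )


@pytest.fixture(scope="session")
def two_mode():
    """Single electron, two equal modes 4 a0 apart (sigma = 0.5)."""
    return GaussianMixtureDensity(
        electrons=[([0.5, 0.5], [[0, 0, -2.0], [0, 0, 2.0]], [0.5, 0.5])],
        spins=[0.5],
    )


@pytest.fixture(scope="session")
def slater3():
    """Three-electron single determinant over s-type Slater orbitals."""
    geometry = MoleculeGeometry(
        symbols=["He", "H"],
        positions=np.array([[0.0, 0.0, -1.0], [0.0, 0.0, 1.0]]),
    )
    orb1 = STOrbital(primitives=(((0.0, 0.0, -1.0), 1.7, 1.0),))
    orb2 = STOrbital(primitives=(((0.0, 0.0, 1.0), 0.9, 1.0),))
    return SlaterDeterminantDensity(
        geometry=geometry, orbitals=[orb1, orb2], n_alpha=2, n_beta=1
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_configuration(rng, n, n_alpha=None, scale=1.5):
    """Random off-nucleus electron configuration."""
    n_alpha = n // 2 + n % 2 if n_alpha is None else n_alpha
    spins = np.array([0.5] * n_alpha + [-0.5] * (n - n_alpha))
    return ElectronConfiguration(rng.normal(scale=scale, size=(n, 3)), spins)
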