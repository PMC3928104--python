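import numpy as np
import pytest

from fretmd.fret_model import DonorModel
from fretmd.synthetic import ToyStructureSpec, make_structure


@pytest.fixture(scope="session")
def aedans_donor() -> DonorModel:
    """Single-exponential AEDANS-like donor, tau = 11 ns."""
    return DonorModel(components=((1.0, 11.0),))


@pytest.fixture(scope="session")
def two_component_donor() -> DonorModel:
    return DonorModel(components=((0.6, 5.0), (0.4, 15.0)))


@pytest.fixture(scope="session")
def time_grid() -> np.ndarray:
    """1024 channels at 0.055 ns covering ~5 donor lifetimes."""
    return np.arange(1024) * 0.055


@pytest.fixture(scope="session")
def ideal_helix_12():
    return make_structure(ToyStructureSpec(kind="ideal_helix", n_residues=12))


@pytest.fixture(scope="session")
def extended_chain_12():
    return make_structure(ToyStructureSpec(kind="extended_chain", n_residues=12))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
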