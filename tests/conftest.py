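import numpy as np
import pytest

from voasim import (
    Geometry,
    build_polypeptide,
    guess_bonds,
    surrogate_engine,
    normal_mode_analysis,
)


@pytest.fixture(scope="session")
def alpha4():
    """Protonated 4-residue alpha-helical strand."""
    return build_polypeptide(4, "alpha", protonation="protonated")


@pytest.fixture(scope="session")
def alpha4_props(alpha4):
    return surrogate_engine(alpha4)

@pytest.fixture(scope="session")
def alpha4_modes(alpha4_props):
    return normal_mode_analysis(alpha4_props)


@pytest.fixture(scope="session")
def strand6():
    """Deprotonated 6-residue PPII strand."""
    return build_polypeptide(6, "PPII")


@pytest.fixture(scope="session")
def strand6_bonds(strand6):
    return guess_bonds(strand6)


@pytest.fixture(scope="session")
def water_toy():
    """Bent 3-atom toy in the xy plane."""
    return Geometry(
        elements=["O", "H", "H"],
        masses=[15.999, 1.008, 1.008],
        coords=[[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]],
        residue_index=[0, 0, 0],
        chain_index=[0, 0, 0],
        atom_names=["O", "H1", "H2"],
    )


@pytest.fixture(scope="session")
def chiral_toy():
    """Small chiral 5-atom molecule with all-distinct environments, so every
    normal mode is non-degenerate and per-mode comparisons are stable."""
    return Geometry(
        elements=["C", "N", "O", "H", "C"],
        masses=[12.011, 14.007, 15.999, 1.008, 12.011],
        coords=[
            [0.00, 0.00, 0.00],
            [1.40, 0.15, -0.10],
            [-0.55, 1.05, 0.65],
            [-0.45, -0.25, -0.95],
            [-0.65, -1.15, 0.80],
        ],
        residue_index=[0] * 5,
        chain_index=[0] * 5,
        atom_names=["C1", "N1", "O1", "H1", "C2"],
    )


def rotation_matrix(seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
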