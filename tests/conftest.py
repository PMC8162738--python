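import numpy as np
import pytest

from excitube import (
    BasisMolecule,
    ExtendedDipoleSpec,
    RollingSpec,
    TubeStructure,
    UnitCell2D,
    build_tube,
)
from excitube.config import default_config
from excitube.synthetic import default_extended_dipole, default_unit_cell

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover - hypothesis is a test extra
    pass


@pytest.fixture(scope="session")
def cell() -> UnitCell2D:
    return default_unit_cell()


@pytest.fixture(scope="session")
def dipole_spec() -> ExtendedDipoleSpec:
    return default_extended_dipole()


@pytest.fixture(scope="session")
def square_cell() -> UnitCell2D:
    """Simple square lattice with axis-aligned dipoles, for geometry checks."""
    return UnitCell2D(
        a1=(1.0, 0.0),
        a2=(0.0, 1.0),
        basis=(
            BasisMolecule(fraction=(0.0, 0.0), orientation_deg=0.0),
            BasisMolecule(fraction=(0.5, 0.5), orientation_deg=0.0),
        ),
    )


@pytest.fixture(scope="session")
def small_tube(cell, dipole_spec) -> TubeStructure:
    """A small inner-wall tube used across tests (few hundred sites)."""
    return build_tube(cell, RollingSpec(3.2, 30.0, 8.0), wall="IW")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_ring(n: int, radius: float, dipole=(0.0, 0.0, 1.0)) -> TubeStructure:
    """N sites equally spaced on a circle, all dipoles along ``dipole``."""
    phi = 2 * np.pi * np.arange(n) / n
    positions = np.column_stack(
        [radius * np.cos(phi), radius * np.sin(phi), np.zeros(n)]
    )
    d = np.asarray(dipole, float)
    d = d / np.linalg.norm(d)
    return TubeStructure(
        positions=positions,
        dipoles=np.tile(d, (n, 1)),
        walls=np.full(n, "IW"),
        cell_indices=np.column_stack([np.arange(n), np.zeros((n, 2), int)]),
        wall_radii={"IW": radius},
    )


def make_chain(n: int, spacing: float, axis=(0.0, 0.0, 1.0)) -> TubeStructure:
    """Head-to-tail chain along z: a textbook J-aggregate."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    positions = np.outer(np.arange(n) * spacing, a)
    return TubeStructure(
        positions=positions,
        dipoles=np.tile(a, (n, 1)),
        walls=np.full(n, "IW"),
        cell_indices=np.column_stack([np.arange(n), np.zeros((n, 2), int)]),
        wall_radii={"IW": 0.0},
    )


@pytest.fixture(scope="session")
def base_config() -> dict:
    cfg = default_config()
    cfg["walls"]["tube_length"] = 10.0
    return cfg
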