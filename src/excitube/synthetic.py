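"""Synthetic model systems: a reference unit cell, charge models and
solvated clusters.

The exact crystallographic cell of the C8S3 herringbone lattice is not
publicly tabulated; the reference cell shipped here is a documented
placeholder with realistic packing (two molecules per ~1.6 nm^2 cell,
pi-stacking along a1, long molecular axis roughly along a2) calibrated
so that the ideal double-walled tube reproduces the aggregate-level
observables of the C8S3 system: strongly negative per-molecule coupling
sums of order -3.5e3 cm^-1, an exciton bandwidth of order 6e3 cm^-1 and
parallel-polarized low-energy bands.  All parameters are plain config
values and can be overridden.

The atomic charge models are synthetic stand-ins for quantum-chemically
derived charge sets (which are not redistributable): a polymethine-like
charge dumbbell whose excited state redistributes charge toward the
bridge center, three-point water and a sodium ion, each with literature
atomic polarizabilities.
"""

from __future__ import annotations

import numpy as np

from .electrostatics import AtomicChargeModel, PolarizableEnvironment
from .lattice import (
    IW,
    OW,
    BasisMolecule,
    ExtendedDipoleSpec,
    RollingSpec,
    UnitCell2D,
)

__all__ = [
    "default_unit_cell",
    "default_extended_dipole",
    "default_rolling",
    "dye_charge_model",
    "water_molecule",
    "sodium_ion",
    "solvated_cluster",
]

#: Default wall radii (nm); the 2.5 nm gap is inside the stable band.
DEFAULT_RADII = {IW: 3.2, OW: 5.7}
#: Default rolling angle (degrees), the optimum for this aggregate.
DEFAULT_ROLLING_ANGLE = 30.0
#: In-plane expansion of the outer-wall lattice relative to the inner.
DEFAULT_OW_SCALE = 1.024

# atomic polarizabilities, nm^3 (Thole-type isotropic values)
_ALPHA_C = 1.334e-3
_ALPHA_O = 0.837e-3
_ALPHA_H = 0.496e-3
_ALPHA_NA = 0.157e-3


def default_unit_cell() -> UnitCell2D:
    """Reference two-molecule herringbone cell (see module docstring).

    a1 runs along the slip direction of the long molecular axis (1.70
    nm period), a2 along the pi-stacking direction (0.92 nm rows); the
    two basis molecules carry mirrored in-plane orientations +-15 deg
    about a1 (herringbone pair) and an 8 deg out-of-plane tilt.  The
    mirror symmetry about a1 makes the two sublattices equivalent, so
    the ideal-structure coupling-sum distribution is narrow.
    """
    return UnitCell2D(
        a1=(1.70, 0.0),
        a2=(0.0, 0.92),
        basis=(
            BasisMolecule(fraction=(0.0, 0.0), orientation_deg=-15.0, tilt_deg=8.0),
            BasisMolecule(fraction=(0.5, 0.5), orientation_deg=15.0, tilt_deg=8.0),
        ),
    )


def default_extended_dipole() -> ExtendedDipoleSpec:
    """Extended dipole of the C8S3 chromophore: +-q on the polymethine
    bridge ends, mu = q*l ~ 0.238 e*nm (~11.4 D)."""
    return ExtendedDipoleSpec(charge=0.34, length=0.70)


def default_rolling(wall: str = IW, tube_length: float = 30.0) -> RollingSpec:
    """Default rolling specification for one wall."""
    return RollingSpec(
        radius=DEFAULT_RADII[wall],
        rolling_angle_deg=DEFAULT_ROLLING_ANGLE,
        tube_length=tube_length,
    )


def dye_charge_model(
    n_atoms: int = 5, length: float = 0.7, label: str = "dye"
) -> AtomicChargeModel:
    """Synthetic polymethine-like charge model along the z axis.

    Ground-state charges alternate along the bridge; the excited state
    moves charge toward the bridge center, so the two state dipole
    moments differ and the molecule picks up a non-trivial solvent
    shift.  Both charge sets are neutral.
    """
    z = np.linspace(-length / 2, length / 2, n_atoms)
    positions = np.column_stack([np.zeros(n_atoms), np.zeros(n_atoms), z])
    alternating = np.array([(-1.0) ** i for i in range(n_atoms)])
    q_ground = 0.24 * alternating
    q_ground -= q_ground.sum() / n_atoms
    center_weight = np.exp(-((z / (0.25 * length)) ** 2))
    q_excited = 0.16 * alternating * center_weight
    q_excited -= q_excited.sum() / n_atoms
    return AtomicChargeModel(
        positions=positions,
        q_ground=q_ground,
        q_excited=q_excited,
        alpha=np.full(n_atoms, _ALPHA_C),
        label=label,
    )


def water_molecule() -> AtomicChargeModel:
    """Three-point water (TIP3P-like charges, Thole polarizabilities)."""
    r_oh = 0.09572
    half = np.radians(104.52 / 2.0)
    positions = np.array(
        [
            [0.0, 0.0, 0.0],
            [r_oh * np.sin(half), 0.0, r_oh * np.cos(half)],
            [-r_oh * np.sin(half), 0.0, r_oh * np.cos(half)],
        ]
    )
    q = np.array([-0.834, 0.417, 0.417])
    return AtomicChargeModel(
        positions=positions,
        q_ground=q,
        q_excited=q.copy(),
        alpha=np.array([_ALPHA_O, _ALPHA_H, _ALPHA_H]),
        label="water",
    )


def sodium_ion() -> AtomicChargeModel:
    return AtomicChargeModel(
        positions=np.zeros((1, 3)),
        q_ground=np.array([1.0]),
        q_excited=np.array([1.0]),
        alpha=np.array([_ALPHA_NA]),
        label="ion",
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def solvated_cluster(
    rng: np.random.Generator,
    n_water: int = 40,
    n_ions: int = 2,
    radius: float = 1.6,
    r_min: float = 0.55,
    clearance: float = 0.25,
    max_tries: int = 200,
) -> tuple[AtomicChargeModel, PolarizableEnvironment]:
    """Random solvation shell around a central dye (point-charge env).

    Waters and counterions are placed with random positions in the
    spherical shell ``[r_min, radius]`` and random orientations,
    rejecting placements whose atoms come within ``clearance`` nm of any
    previously placed atom.  Emulates the carve-out cluster on which
    solvent shifts are evaluated.
    """
    central = dye_charge_model()
    placed_atoms = [central.positions]
    molecules: list[AtomicChargeModel] = []
    sources: list[str] = []

    def try_place(template: AtomicChargeModel, source: str) -> None:
        for _ in range(max_tries):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            dist = (r_min**3 + (radius**3 - r_min**3) * rng.random()) ** (1 / 3)
            candidate = template.rotated(_random_rotation(rng)).translated(
                dist * direction
            )
            all_prev = np.vstack(placed_atoms)
            d = np.linalg.norm(
                candidate.positions[:, None, :] - all_prev[None, :, :], axis=-1
            )
            if d.min() >= clearance:
                placed_atoms.append(candidate.positions)
                molecules.append(candidate)
                sources.append(source)
                return
        raise RuntimeError(
            "could not place molecule without overlap; lower n_water or "
            "increase the shell radius"
        )

    water = water_molecule()
    ion = sodium_ion()
    for _ in range(n_water):
        try_place(water, "water")
    for _ in range(n_ions):
        try_place(ion, "ion")
    return central, PolarizableEnvironment(molecules=molecules, sources=sources)
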