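"""Herringbone lattices and their rolling onto cylindrical tube walls.

Conventions
-----------
* Cartesian coordinates in nm; the tube axis is +z through the origin;
  azimuth is measured from +x.  Angles are degrees in all public
  interfaces and radians internally.
* A planar lattice lives in an abstract 2D plane.  Rolling maps the
  coordinate ``u`` along the rolling (circumferential) direction to the
  azimuth ``phi = u / r`` (arc length is preserved) and the transverse
  coordinate to z.
* Transition-dipole directions are carried as 3D unit vectors.  In the
  plane, a basis molecule with in-plane orientation ``alpha`` (from the
  plane x axis) and out-of-plane tilt ``beta`` has direction

      d_plane = (cos(beta) cos(alpha), cos(beta) sin(alpha), sin(beta)),

  where the third component is along the plane normal.  Rolling rotates
  this rigidly into the local tangent frame of the cylinder at azimuth
  ``phi``:

      d_3D = d_u * t_hat(phi) + d_v * z_hat + d_n * n_hat(phi)

  with tangent t_hat = (-sin phi, cos phi, 0), axial z_hat = (0, 0, 1)
  and outward normal n_hat = (cos phi, sin phi, 0).  A planar dipole
  along the rolling direction at u = 0 therefore becomes (0, 1, 0).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: Wall labels for the double-walled tube.
IW = "IW"
OW = "OW"
WALLS = (IW, OW)

#: Wall-to-wall distances (nm) found to give stable double-walled tubes.
STABLE_WALL_GAP_NM = (2.3, 2.7)


class InvalidCellError(ValueError):
    """Degenerate or malformed 2D unit cell."""


class CommensurationError(ValueError):
    """No lattice vector approximates the requested circumference."""


class InsufficientExtentError(ValueError):
    """Planar lattice does not cover the strip to be rolled."""


class OverlapError(ValueError):
    """Two molecules approach closer than the hard-core endpoint guard."""


@dataclass(frozen=True)
class BasisMolecule:
    """One molecule of the two-molecule herringbone basis.

    Parameters
    ----------
    fraction:
        Fractional in-plane position (f1, f2) on (a1, a2); each in [0, 1).
    orientation_deg:
        In-plane angle of the transition dipole, degrees from the plane
        x axis.  The two basis molecules carry the alternating
        (herringbone) pair of orientations.
    tilt_deg:
        Out-of-plane tilt of the dipole, degrees from the lattice plane.
    """

    fraction: tuple[float, float]
    orientation_deg: float
    tilt_deg: float = 0.0

    def __post_init__(self) -> None:
        f1, f2 = self.fraction
        if not (0.0 <= f1 < 1.0 and 0.0 <= f2 < 1.0):
            raise InvalidCellError(
                f"fractional position {self.fraction} outside [0, 1)"
            )

    def direction(self) -> np.ndarray:
        """Unit dipole direction in plane coordinates (u, v, normal)."""
        a = np.radians(self.orientation_deg)
        b = np.radians(self.tilt_deg)
        return np.array(
            [np.cos(b) * np.cos(a), np.cos(b) * np.sin(a), np.sin(b)]
        )


@dataclass(frozen=True)
class UnitCell2D:
    """2D lattice vectors plus a two-molecule herringbone basis.

    ``a1`` and ``a2`` are 2D lattice vectors in nm.  The basis must hold
    exactly two molecules (herringbone packing).
    """

    a1: tuple[float, float]
    a2: tuple[float, float]
    basis: tuple[BasisMolecule, BasisMolecule]

    def __post_init__(self) -> None:
        a1 = np.asarray(self.a1, float)
        a2 = np.asarray(self.a2, float)
        n1, n2 = np.linalg.norm(a1), np.linalg.norm(a2)
        if n1 <= 0 or n2 <= 0:
            raise InvalidCellError("lattice vectors must have positive length")
        cross = abs(a1[0] * a2[1] - a1[1] * a2[0])
        if cross <= 1e-12 * n1 * n2:
            raise InvalidCellError("a1 and a2 are (anti)parallel")
        if len(self.basis) != 2:
            raise InvalidCellError("herringbone basis requires exactly 2 molecules")

    @property
    def matrix(self) -> np.ndarray:
        """Column matrix [a1 | a2], shape (2, 2)."""
        return np.column_stack([self.a1, self.a2]).astype(float)

    @property
    def area(self) -> float:
        """Unit-cell area in nm^2."""
        m = self.matrix
        return abs(m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0])


def scale_unit_cell(cell: UnitCell2D, factor: float) -> UnitCell2D:
    """Uniformly scale the in-plane lattice constants by ``factor``.

    Fractional basis positions and all angles are unchanged; the cell
    area scales by ``factor**2``.  Used to model the small packing
    density difference between the two tube walls.
    """
    if not factor > 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    a1 = (cell.a1[0] * factor, cell.a1[1] * factor)
    a2 = (cell.a2[0] * factor, cell.a2[1] * factor)
    return replace(cell, a1=a1, a2=a2)


@dataclass(frozen=True)
class RollingSpec:
    """How a planar lattice is wrapped onto a cylinder.

    ``rolling_angle_deg`` is the angle between lattice vector a1 and the
    rolling (circumferential) direction, in [0, 90).
    """

    radius: float
    rolling_angle_deg: float
    tube_length: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if not self.tube_length > 0:
            raise ValueError("tube_length must be positive")
        if not (0.0 <= self.rolling_angle_deg < 90.0):
            raise ValueError("rolling angle must lie in [0, 90) degrees")


@dataclass(frozen=True)
class ExtendedDipoleSpec:
    """Transition dipole as two opposite charges +-q separated by l.

    ``charge`` in elementary charges, ``length`` in nm; the monomer
    transition dipole magnitude is mu = q * l (e*nm).
    """

    charge: float
    length: float

    def __post_init__(self) -> None:
        if not self.charge > 0:
            raise ValueError("charge must be positive")
        if not self.length > 0:
            raise ValueError("length must be positive")

    @property
    def mu(self) -> float:
        """Transition dipole magnitude q*l in e*nm."""
        return self.charge * self.length


@dataclass(frozen=True)
class ChromophoreSite:
    """A single chromophore: position, dipole direction, wall label."""

    index: int
    position: np.ndarray
    dipole_axis: np.ndarray
    wall: str
    cell_indices: tuple[int, int, int]


@dataclass
class PlanarLattice:
    """A finite patch of the 2D herringbone lattice.

    ``positions`` are (N, 2) plane coordinates in nm, ``dipoles`` are
    (N, 3) unit vectors in (u, v, normal) plane components, and
    ``cell_indices`` holds the (i, j, basis) provenance of each site.
    """

    cell: UnitCell2D
    positions: np.ndarray
    dipoles: np.ndarray
    cell_indices: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class TubeStructure:
    """Chromophore sites on one or two coaxial cylinders (axis = +z)."""

    positions: np.ndarray  # (N, 3) nm
    dipoles: np.ndarray  # (N, 3) unit vectors
    walls: np.ndarray  # (N,) strings "IW"/"OW"
    cell_indices: np.ndarray  # (N, 3) int
    wall_radii: dict[str, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.dipoles = np.atleast_2d(np.asarray(self.dipoles, float))
        self.walls = np.asarray(self.walls)
        self.cell_indices = np.atleast_2d(np.asarray(self.cell_indices, int))
        n = len(self.positions)
        if not (len(self.dipoles) == len(self.walls) == len(self.cell_indices) == n):
            raise ValueError("inconsistent array lengths in TubeStructure")
        if n:
            norms = np.linalg.norm(self.dipoles, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("dipole axes must be unit vectors (tol 1e-9)")

    def __len__(self) -> int:
        return len(self.positions)

    def wall_mask(self, wall: str) -> np.ndarray:
        return self.walls == wall

    @property
    def radii(self) -> np.ndarray:
        """Cylindrical radius sqrt(x^2 + y^2) of every site."""
        return np.hypot(self.positions[:, 0], self.positions[:, 1])

    @property
    def sites(self) -> list[ChromophoreSite]:
        """Sites as a list of :class:`ChromophoreSite` objects."""
        return [
            ChromophoreSite(
                index=i,
                position=self.positions[i],
                dipole_axis=self.dipoles[i],
                wall=str(self.walls[i]),
                cell_indices=tuple(self.cell_indices[i]),
            )
            for i in range(len(self))
        ]

    def __iter__(self) -> Iterator[ChromophoreSite]:
        return iter(self.sites)

    def validate_on_cylinder(self, tol: float = 1e-6) -> None:
        """Check the pre-jitter invariant that each site sits on its wall."""
        for wall, r in self.wall_radii.items():
            mask = self.wall_mask(wall)
            if mask.any() and np.max(np.abs(self.radii[mask] - r)) > tol:
                raise ValueError(f"{wall} sites deviate from radius {r} nm")


def build_planar_lattice(cell: UnitCell2D, n1: int, n2: int) -> PlanarLattice:
    """Tile ``n1 x n2`` unit cells of the herringbone lattice.

    Returns ``n1 * n2 * 2`` sites; site (i, j, b) sits at
    ``i*a1 + j*a2 + f1_b*a1 + f2_b*a2`` and carries the b-th basis
    orientation, so the herringbone alternation is preserved across the
    patch.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("n1 and n2 must be >= 1")
    m = cell.matrix
    ii, jj = np.meshgrid(np.arange(n1), np.arange(n2), indexing="ij")
    ij = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)

    positions, dipoles, indices = [], [], []
    for b, mol in enumerate(cell.basis):
        frac = ij + np.asarray(mol.fraction)
        positions.append(frac @ m.T)
        dipoles.append(np.tile(mol.direction(), (len(frac), 1)))
        indices.append(
            np.column_stack([ij.astype(int), np.full(len(frac), b, dtype=int)])
        )
    order = np.lexsort(
        (
            np.concatenate([idx[:, 2] for idx in indices]),
            np.concatenate([idx[:, 1] for idx in indices]),
            np.concatenate([idx[:, 0] for idx in indices]),
        )
    )
    return PlanarLattice(
        cell=cell,
        positions=np.vstack(positions)[order],
        dipoles=np.vstack(dipoles)[order],
        cell_indices=np.vstack(indices)[order],
    )


def commensurate_rolling_vector(
    cell: UnitCell2D,
    spec: RollingSpec,
    max_strain: float = 0.01,
    max_angle_dev_deg: float = 8.0,
) -> dict:
    """Snap the rolling vector to the nearest integer lattice translation.

    The requested circumference ``C = 2*pi*radius`` along the direction at
    ``rolling_angle_deg`` from a1 generally does not hit a lattice point.
    To avoid a seam discontinuity the circumference is rescaled to the
    nearest combination ``R = m*a1 + n*a2``; the applied circumferential
    strain ``|R|/C - 1`` is reported and must stay below ``max_strain``
    (default 1%), and the direction of R must stay within
    ``max_angle_dev_deg`` of the requested rolling direction.

    Returns a dict with keys ``m, n, vector, circumference, radius,
    strain, theta_actual_deg``.
    """
    circ = 2.0 * np.pi * spec.radius
    theta = np.radians(spec.rolling_angle_deg)
    a1 = np.asarray(cell.a1, float)
    a1_hat = a1 / np.linalg.norm(a1)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    u_hat = rot @ a1_hat
    target = circ * u_hat

    mmax = int(np.ceil(circ / min(np.linalg.norm(a1), np.linalg.norm(cell.a2)))) + 3
    rng = np.arange(-mmax, mmax + 1)
    mm, nn = np.meshgrid(rng, rng, indexing="ij")
    mn = np.column_stack([mm.ravel(), nn.ravel()])
    vecs = mn @ cell.matrix.T
    lengths = np.linalg.norm(vecs, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_dev = np.clip(vecs @ u_hat / np.where(lengths > 0, lengths, 1.0), -1, 1)
    angle_dev = np.degrees(np.arccos(cos_dev))
    strain = lengths / circ - 1.0
    ok = (
        (lengths > 0)
        & (angle_dev <= max_angle_dev_deg)
        & (np.abs(strain) <= max_strain)
    )
    if not ok.any():
        best = np.argmin(np.linalg.norm(vecs - target, axis=1) + 1e9 * (lengths == 0))
        raise CommensurationError(
            "no lattice vector within "
            f"{max_strain:.1%} strain and {max_angle_dev_deg} deg of the "
            f"rolling direction (closest: m,n={tuple(mn[best])}, "
            f"strain={strain[best]:+.2%}, deviation={angle_dev[best]:.1f} deg); "
            "adjust the radius or rolling angle"
        )
    cand = np.flatnonzero(ok)
    best = cand[np.argmin(np.linalg.norm(vecs[cand] - target, axis=1))]
    vec = vecs[best]
    theta_actual = np.degrees(
        np.arccos(np.clip(vec @ a1_hat / lengths[best], -1, 1))
    )
    result = {
        "m": int(mn[best, 0]),
        "n": int(mn[best, 1]),
        "vector": vec,
        "circumference": float(lengths[best]),
        "radius": float(lengths[best] / (2.0 * np.pi)),
        "strain": float(strain[best]),
        "theta_actual_deg": float(theta_actual),
    }
    logger.info(
        "commensurate rolling vector (m=%d, n=%d): strain %+.3f%%, "
        "actual theta %.2f deg (requested %.2f)",
        result["m"], result["n"], 100 * result["strain"],
        theta_actual, spec.rolling_angle_deg,
    )
    return result


def required_supercell(cell: UnitCell2D, spec: RollingSpec, margin: int = 3) -> tuple[int, int]:
    """Number of unit cells (n1, n2) guaranteed to cover the rolled strip."""
    roll = commensurate_rolling_vector(cell, spec)
    length = roll["circumference"]
    # corners of the strip in the rotated frame, mapped back to fractional
    psi = np.arctan2(roll["vector"][1], roll["vector"][0])
    rot = np.array([[np.cos(psi), -np.sin(psi)], [np.sin(psi), np.cos(psi)]])
    corners = np.array(
        [[0, 0], [length, 0], [0, spec.tube_length], [length, spec.tube_length]]
    ) @ rot.T
    frac = np.linalg.solve(cell.matrix, corners.T).T
    span = np.ceil(frac.max(axis=0) - frac.min(axis=0)).astype(int)
    return int(span[0]) + 2 * margin, int(span[1]) + 2 * margin


def axial_period_vector(
    cell: UnitCell2D, roll: dict, tube_length: float
) -> dict:
    """Lattice translation closest to ``tube_length`` along the tube axis.

    Among integer combinations ``v = p*a1 + q*a2``, pick the one whose
    component transverse to the (commensurate) rolling vector is positive
    and closest to the requested length.  Rolled onto the cylinder, v
    becomes a screw operation (rotate by ``dphi``, translate by
    ``period``) under which the tube lattice is exactly periodic.
    """
    psi = np.arctan2(roll["vector"][1], roll["vector"][0])
    c, s = np.cos(-psi), np.sin(-psi)
    rot = np.array([[c, -s], [s, c]])
    a_rot = rot @ cell.matrix  # columns: rotated a1, a2
    mmax = (
        int(np.ceil(tube_length / min(np.linalg.norm(cell.a1), np.linalg.norm(cell.a2))))
        + 3
    )
    rng = np.arange(-mmax, mmax + 1)
    pp, qq = np.meshgrid(rng, rng, indexing="ij")
    pq = np.column_stack([pp.ravel(), qq.ravel()])
    vecs = pq @ a_rot.T
    w = vecs[:, 1]
    valid = w > 0.1
    if not valid.any():
        raise InsufficientExtentError("no axial lattice period found")
    best = np.flatnonzero(valid)[np.argmin(np.abs(w[valid] - tube_length))]
    return {
        "p": int(pq[best, 0]),
        "q": int(pq[best, 1]),
        "period": float(w[best]),
        "dphi": float(vecs[best, 0] / roll["radius"]),
    }


def roll_to_cylinder(
    planar: PlanarLattice,
    spec: RollingSpec,
    wall: str = IW,
    max_strain: float = 0.01,
    periodic_axial: bool = False,
) -> TubeStructure:
    """Roll a planar lattice patch onto a single cylindrical wall.

    The planar coordinate along the (commensurate) rolling vector maps to
    the azimuth ``phi = u / r`` and the transverse coordinate to z; dipole
    directions are rotated rigidly with the local tangent frame.  Exactly
    one circumference is kept (half-open interval, no duplicated seam
    row) and sites with z outside [0, tube_length] are dropped.

    With ``periodic_axial=True`` the tube length is snapped to the
    nearest axial lattice period and the z interval becomes half-open as
    well; the resulting screw operation (stored in
    ``metadata["screw"]``) lets the exciton Hamiltonian add periodic
    images along the axis, suppressing open-end effects in ideal-tube
    spectra.

    The planar patch must extend beyond the strip
    ``[0, 2*pi*r) x [0, tube_length]`` in the rotated frame; use
    :func:`required_supercell` (or :func:`build_tube`) to size it.
    """
    if wall not in WALLS:
        raise ValueError(f"wall must be one of {WALLS}")
    roll = commensurate_rolling_vector(planar.cell, spec, max_strain=max_strain)
    circ = roll["circumference"]
    radius = roll["radius"]
    screw = None
    length = spec.tube_length
    if periodic_axial:
        screw = axial_period_vector(planar.cell, roll, spec.tube_length)
        length = screw["period"]
    psi = np.arctan2(roll["vector"][1], roll["vector"][0])
    # rotate the plane so the rolling vector lies along +u
    c, s = np.cos(-psi), np.sin(-psi)
    rot = np.array([[c, -s], [s, c]])
    pos = planar.positions @ rot.T
    dip = planar.dipoles.copy()
    dip[:, :2] = dip[:, :2] @ rot.T

    # center the strip inside the patch, then clip to one circumference
    lo, hi = pos.min(axis=0), pos.max(axis=0)
    if hi[0] - lo[0] < circ - 1e-9 or hi[1] - lo[1] < length - 1e-9:
        raise InsufficientExtentError(
            f"planar extent {hi - lo} nm cannot cover the "
            f"{circ:.2f} x {length:.2f} nm strip; enlarge the patch"
        )
    shift = 0.5 * (lo + hi) - 0.5 * np.array([circ, length])
    pos = pos - shift
    tol = 1e-7
    z_keep = (
        (pos[:, 1] >= -tol) & (pos[:, 1] < length - tol)
        if periodic_axial
        else (pos[:, 1] >= -tol) & (pos[:, 1] <= length + tol)
    )
    keep = (pos[:, 0] >= -tol) & (pos[:, 0] < circ - tol) & z_keep
    pos, dip = pos[keep], dip[keep]
    idx = planar.cell_indices[keep]

    phi = pos[:, 0] / radius
    t_hat = np.column_stack([-np.sin(phi), np.cos(phi), np.zeros_like(phi)])
    n_hat = np.column_stack([np.cos(phi), np.sin(phi), np.zeros_like(phi)])
    z_hat = np.array([0.0, 0.0, 1.0])
    xyz = np.column_stack(
        [radius * np.cos(phi), radius * np.sin(phi), pos[:, 1]]
    )
    d3 = (
        dip[:, [0]] * t_hat
        + dip[:, [1]] * z_hat
        + dip[:, [2]] * n_hat
    )
    d3 /= np.linalg.norm(d3, axis=1, keepdims=True)

    order = np.lexsort((idx[:, 2], pos[:, 1], phi))
    structure = TubeStructure(
        positions=xyz[order],
        dipoles=d3[order],
        walls=np.full(len(xyz), wall),
        cell_indices=idx[order],
        wall_radii={wall: radius},
        metadata={
            "rolling": roll,
            "requested_radius": spec.radius,
            "tube_length": length,
            "screw": screw,
        },
    )
    structure.validate_on_cylinder()
    return structure


def build_tube(
    cell: UnitCell2D,
    spec: RollingSpec,
    wall: str = IW,
    max_strain: float = 0.01,
    periodic_axial: bool = False,
) -> TubeStructure:
    """Construct a single-walled tube directly from a unit cell."""
    n1, n2 = required_supercell(cell, spec)
    planar = build_planar_lattice(cell, n1, n2)
    return roll_to_cylinder(
        planar, spec, wall=wall, max_strain=max_strain,
        periodic_axial=periodic_axial,
    )


def assemble_double_wall(iw: TubeStructure, ow: TubeStructure) -> TubeStructure:
    """Concatenate inner and outer walls into one double-walled tube.

    Warns when the wall-to-wall distance falls outside the
    2.3-2.7 nm band in which double-walled structures are stable.
    """
    if len(iw) == 0 or len(ow) == 0:
        raise ValueError("cannot assemble a double wall from an empty wall")
    if IW not in iw.wall_radii or OW not in ow.wall_radii:
        raise ValueError("inputs must carry IW and OW wall labels respectively")
    r_iw = iw.wall_radii[IW]
    r_ow = ow.wall_radii[OW]
    gap = r_ow - r_iw
    if gap <= 0:
        raise ValueError(
            f"outer-wall radius ({r_ow:.2f} nm) must exceed inner-wall "
            f"radius ({r_iw:.2f} nm)"
        )
    if not (STABLE_WALL_GAP_NM[0] <= gap <= STABLE_WALL_GAP_NM[1]):
        warnings.warn(
            f"wall-to-wall distance {gap:.2f} nm lies outside the stable "
            f"band {STABLE_WALL_GAP_NM[0]}-{STABLE_WALL_GAP_NM[1]} nm",
            stacklevel=2,
        )
    return TubeStructure(
        positions=np.vstack([iw.positions, ow.positions]),
        dipoles=np.vstack([iw.dipoles, ow.dipoles]),
        walls=np.concatenate([iw.walls, ow.walls]),
        cell_indices=np.vstack([iw.cell_indices, ow.cell_indices]),
        wall_radii={IW: r_iw, OW: r_ow},
        metadata={
            "wall_to_wall_nm": gap,
            "iw": iw.metadata,
            "ow": ow.metadata,
        },
    )


def site_charge_positions(
    site: ChromophoreSite, spec: ExtendedDipoleSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Endpoints of the extended dipole of one site: (+q point, -q point)."""
    half = 0.5 * spec.length * site.dipole_axis
    return site.position + half, site.position - half


def charge_endpoints(
    structure: TubeStructure, spec: ExtendedDipoleSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized endpoints for all sites: arrays of +q and -q positions."""
    half = 0.5 * spec.length * structure.dipoles
    return structure.positions + half, structure.positions - half


def min_intermolecular_endpoint_distance(
    structure: TubeStructure, spec: ExtendedDipoleSpec
) -> float:
    """Smallest distance between charge endpoints of different molecules."""
    plus, minus = charge_endpoints(structure, spec)
    pts = np.vstack([plus, minus])
    mol = np.tile(np.arange(len(structure)), 2)
    tree = cKDTree(pts)
    best = np.inf
    # query a few nearest neighbours; same-molecule pairs are excluded
    k = min(len(pts), 6)
    dist, idx = tree.query(pts, k=k)
    for col in range(1, k):
        other = mol[idx[:, col]]
        valid = other != mol
        if valid.any():
            best = min(best, dist[valid, col].min())
    return float(best)


def check_endpoint_guard(
    structure: TubeStructure,
    spec: ExtendedDipoleSpec,
    guard: float,
) -> None:
    """Raise :class:`OverlapError` if any two molecules overlap."""
    if len(structure) < 2:
        return
    dmin = min_intermolecular_endpoint_distance(structure, spec)
    if dmin < guard:
        raise OverlapError(
            f"charge endpoints of different molecules approach to "
            f"{dmin:.4f} nm (< guard {guard} nm)"
        )
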