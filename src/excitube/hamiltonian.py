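"""Frenkel exciton Hamiltonian with extended-dipole couplings.

The one-exciton Hamiltonian of an aggregate of N two-level chromophores
is the N x N symmetric matrix

    H_nn = E0 + delta_n        (site excitation energies, cm^-1)
    H_nm = J_nm                (excitation-transfer couplings, cm^-1)

with couplings evaluated in the extended dipole model: the transition
dipole of each molecule is represented by two opposite transition
charges +-q separated by a length l along the molecular dipole axis, and
J_nm is the four-term Coulomb sum over endpoint pairs.  Vibronic
coupling is not included (strong-coupling J-aggregate regime).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .constants import E0_MONOMER_CM1, ENDPOINT_GUARD_NM, K_COULOMB
from .lattice import ExtendedDipoleSpec, OverlapError, TubeStructure

__all__ = [
    "ExcitonHamiltonian",
    "ExcitonStates",
    "coupling_extended_dipole",
    "coupling_point_dipole",
    "build_hamiltonian",
    "diagonalize",
    "collective_dipoles",
    "solve_structure",
    "coupling_sum_per_site",
    "coupling_sum_stats",
    "exciton_bandwidth",
    "participation_sizes",
    "delocalization_size",
]


@dataclass
class ExcitonHamiltonian:
    """Dense symmetric exciton Hamiltonian (cm^-1) plus site metadata."""

    matrix: np.ndarray  # (N, N), cm^-1
    walls: np.ndarray  # (N,) wall labels
    e0: float  # gas-phase monomer energy on the diagonal, cm^-1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("Hamiltonian must be a square matrix")
        if not np.isfinite(self.matrix).all():
            raise ValueError("Hamiltonian contains non-finite entries")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("Hamiltonian must be symmetric")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    @property
    def site_energies(self) -> np.ndarray:
        return np.diag(self.matrix)

    @property
    def couplings(self) -> np.ndarray:
        """Off-diagonal part J_nm (diagonal zeroed)."""
        off = self.matrix.copy()
        np.fill_diagonal(off, 0.0)
        return off


@dataclass
class ExcitonStates:
    """Eigenstates of an exciton Hamiltonian.

    ``coeffs[k, n]`` is the amplitude of site n in state k; rows are
    orthonormal.  ``dipoles`` (filled by :func:`collective_dipoles`) are
    the collective transition dipoles mu_k = sum_n c_kn mu_n in e*nm.
    """

    energies: np.ndarray  # (N,), ascending, cm^-1
    coeffs: np.ndarray  # (N, N), row k = state k
    dipoles: np.ndarray | None = None  # (N, 3), e*nm
    walls: np.ndarray | None = None  # (N,) site wall labels

    @property
    def n_states(self) -> int:
        return len(self.energies)

    @property
    def oscillator_strengths(self) -> np.ndarray:
        """|mu_k|^2 per state (e^2 nm^2)."""
        if self.dipoles is None:
            raise ValueError("collective dipoles have not been computed")
        return np.einsum("kj,kj->k", self.dipoles, self.dipoles)


def coupling_extended_dipole(
    pos_i: np.ndarray,
    dip_i: np.ndarray,
    pos_j: np.ndarray,
    dip_j: np.ndarray,
    spec: ExtendedDipoleSpec,
    screening: float = 1.0,
    guard: float = ENDPOINT_GUARD_NM,
) -> float:
    """Extended-dipole coupling between two chromophores, cm^-1.

    J = (k/screening) * q^2 * [ 1/r(+,+') + 1/r(-,-')
                                - 1/r(+,-') - 1/r(-,+') ]

    where r(a, b') is the distance between transition-charge endpoint a
    of molecule i and b' of molecule j.  Sign convention: parallel
    side-by-side dipoles give J > 0 (H-type), head-to-tail J < 0
    (J-type).
    """
    pos_i = np.asarray(pos_i, float)
    pos_j = np.asarray(pos_j, float)
    dip_i = np.asarray(dip_i, float)
    dip_j = np.asarray(dip_j, float)
    half_i = 0.5 * spec.length * dip_i
    half_j = 0.5 * spec.length * dip_j
    pp = np.linalg.norm((pos_i + half_i) - (pos_j + half_j))
    mm = np.linalg.norm((pos_i - half_i) - (pos_j - half_j))
    pm = np.linalg.norm((pos_i + half_i) - (pos_j - half_j))
    mp = np.linalg.norm((pos_i - half_i) - (pos_j + half_j))
    dmin = min(pp, mm, pm, mp)
    if dmin < guard:
        raise OverlapError(
            f"endpoint distance {dmin:.4f} nm below guard {guard} nm"
        )
    q2 = spec.charge**2
    return K_COULOMB / screening * q2 * (1 / pp + 1 / mm - 1 / pm - 1 / mp)


def coupling_point_dipole(
    pos_i: np.ndarray,
    dip_i: np.ndarray,
    pos_j: np.ndarray,
    dip_j: np.ndarray,
    mu: float,
    screening: float = 1.0,
) -> float:
    """Point-dipole coupling, the far-field limit of the extended dipole.

    J = (k/screening) * mu^2 * [ d_i.d_j - 3 (d_i.r_hat)(d_j.r_hat) ] / r^3
    """
    r = np.asarray(pos_j, float) - np.asarray(pos_i, float)
    dist = np.linalg.norm(r)
    if dist == 0:
        raise ValueError("coincident sites in point-dipole coupling")
    r_hat = r / dist
    d_i = np.asarray(dip_i, float)
    d_j = np.asarray(dip_j, float)
    angular = d_i @ d_j - 3.0 * (d_i @ r_hat) * (d_j @ r_hat)
    return K_COULOMB / screening * mu**2 * angular / dist**3


def _screw_transform(
    positions: np.ndarray, dipoles: np.ndarray, dphi: float, dz: float
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the screw operation (rotate about z by dphi, shift z by dz)."""
    c, s = np.cos(dphi), np.sin(dphi)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return positions @ rot.T + np.array([0.0, 0.0, dz]), dipoles @ rot.T


def _coupling_block(
    pos_a, dip_a, pos_b, dip_b, spec, pref, cutoff, guard, row_offset=None
):
    """Extended-dipole couplings between two site sets (vectorized).

    ``row_offset`` marks pos_a as the row block pos_b[offset:offset+len],
    so same-molecule entries are excluded from the guard and zeroed.
    """
    half_a = 0.5 * spec.length * dip_a
    half_b = 0.5 * spec.length * dip_b
    dpp = cdist(pos_a + half_a, pos_b + half_b)
    dmm = cdist(pos_a - half_a, pos_b - half_b)
    dpm = cdist(pos_a + half_a, pos_b - half_b)
    dmp = cdist(pos_a - half_a, pos_b + half_b)
    offdiag = np.ones(dpp.shape, dtype=bool)
    if row_offset is not None:
        rows = np.arange(pos_a.shape[0])
        offdiag[rows, rows + row_offset] = False
    dmin = np.stack([dpp, dmm, dpm, dmp]).min(axis=0)
    if (dmin[offdiag] < guard).any():
        raise OverlapError(
            f"endpoint distance {dmin[offdiag].min():.4f} nm below guard "
            f"{guard} nm"
        )
    with np.errstate(divide="ignore"):
        blk = pref * (1 / dpp + 1 / dmm - 1 / dpm - 1 / dmp)
    blk[~offdiag] = 0.0
    if cutoff is not None:
        blk[cdist(pos_a, pos_b) > cutoff] = 0.0
    return blk


def build_hamiltonian(
    structure: TubeStructure,
    spec: ExtendedDipoleSpec,
    e0: float = E0_MONOMER_CM1,
    shifts: Sequence[float] | np.ndarray | None = None,
    cutoff: float | None = None,
    screening: float = 1.0,
    guard: float = ENDPOINT_GUARD_NM,
    axial_images: int = 0,
    block: int = 512,
) -> ExcitonHamiltonian:
    """Assemble the exciton Hamiltonian for a tube structure.

    Diagonal entries are ``e0 + shifts``; off-diagonal couplings use the
    extended dipole model for all pairs whose centre distance is within
    ``cutoff`` (default: no cutoff, all pairs).  ``cutoff=0`` yields a
    diagonal matrix.

    ``axial_images > 0`` adds couplings to that many screw-periodic
    images of the tube on either side along the axis (the structure must
    have been built with ``periodic_axial=True``).  This emulates an
    infinitely long ideal tube and removes the open-end contribution to
    band positions.
    """
    n = len(structure)
    if shifts is None:
        shifts = np.zeros(n)
    shifts = np.asarray(shifts, float)
    if shifts.shape != (n,):
        raise ValueError(f"shifts must have length {n}")
    if not np.isfinite(shifts).all():
        raise ValueError("non-finite site-energy shift")

    pref = K_COULOMB / screening * spec.charge**2
    screw = structure.metadata.get("screw")
    if axial_images > 0 and screw is None:
        raise ValueError(
            "axial_images requires a structure built with periodic_axial=True"
        )

    j = np.zeros((n, n))
    for start in range(0, n, block):
        stop = min(start + block, n)
        rows = slice(start, stop)
        j[rows] = _coupling_block(
            structure.positions[rows], structure.dipoles[rows],
            structure.positions, structure.dipoles,
            spec, pref, cutoff, guard, row_offset=start,
        )

    if axial_images > 0:
        ks = [k for k in range(-axial_images, axial_images + 1) if k != 0]
        for k in ks:
            img_pos, img_dip = _screw_transform(
                structure.positions, structure.dipoles,
                k * screw["dphi"], k * screw["period"],
            )
            for start in range(0, n, block):
                stop = min(start + block, n)
                rows = slice(start, stop)
                j[rows] += _coupling_block(
                    structure.positions[rows], structure.dipoles[rows],
                    img_pos, img_dip,
                    spec, pref, cutoff, guard,
                )

    j = 0.5 * (j + j.T)  # enforce exact symmetry against rounding
    np.fill_diagonal(j, e0 + shifts)
    return ExcitonHamiltonian(
        matrix=j,
        walls=structure.walls.copy(),
        e0=e0,
        metadata={
            "cutoff": cutoff,
            "screening": screening,
            "spec": spec,
            "axial_images": axial_images,
        },
    )


def diagonalize(h: ExcitonHamiltonian) -> ExcitonStates:
    """Eigenstates by dense symmetric diagonalization (ascending energies)."""
    energies, vecs = np.linalg.eigh(h.matrix)
    return ExcitonStates(energies=energies, coeffs=vecs.T, walls=h.walls)


def collective_dipoles(
    states: ExcitonStates,
    structure: TubeStructure,
    mu_monomer: float,
) -> np.ndarray:
    """Collective transition dipoles mu_k = sum_n c_kn * mu * d_n.

    Fills ``states.dipoles`` and returns the (N, 3) array.  The sum rule
    sum_k |mu_k|^2 = N * mu^2 holds by orthonormality.
    """
    site_dipoles = mu_monomer * structure.dipoles
    states.dipoles = states.coeffs @ site_dipoles
    return states.dipoles


def solve_structure(
    structure: TubeStructure,
    spec: ExtendedDipoleSpec,
    e0: float = E0_MONOMER_CM1,
    shifts: np.ndarray | None = None,
    cutoff: float | None = None,
    screening: float = 1.0,
    axial_images: int = 0,
) -> tuple[ExcitonHamiltonian, ExcitonStates]:
    """Convenience: build, diagonalize and attach collective dipoles."""
    h = build_hamiltonian(
        structure, spec, e0=e0, shifts=shifts, cutoff=cutoff,
        screening=screening, axial_images=axial_images,
    )
    states = diagonalize(h)
    collective_dipoles(states, structure, spec.mu)
    return h, states


def coupling_sum_per_site(h: ExcitonHamiltonian) -> np.ndarray:
    """Per-molecule sum of excitonic couplings sum_{j != i} J_ij (cm^-1).

    For a J-aggregate these sums are negative; their mean per wall is
    indicative of the red-shift of that wall's parallel absorption band.
    """
    return h.couplings.sum(axis=1)


def coupling_sum_stats(h: ExcitonHamiltonian) -> dict[str, dict[str, float]]:
    """Mean and standard deviation of the coupling sums, per wall."""
    sums = coupling_sum_per_site(h)
    out: dict[str, dict[str, float]] = {}
    for wall in np.unique(h.walls):
        vals = sums[h.walls == wall]
        out[str(wall)] = {
            "mean": float(vals.mean()),
            "std": float(vals.std()),
            "n": int(len(vals)),
        }
    return out


def exciton_bandwidth(states: ExcitonStates) -> float:
    """Exciton band width W = max(E_k) - min(E_k), cm^-1."""
    if states.n_states == 0:
        raise ValueError("no states")
    return float(states.energies[-1] - states.energies[0])


def participation_sizes(states: ExcitonStates) -> np.ndarray:
    """Inverse-participation-ratio size 1 / sum_n c_kn^4 per state."""
    return 1.0 / np.sum(states.coeffs**4, axis=1)


def delocalization_size(
    states: ExcitonStates,
    weights: np.ndarray | None = None,
    window: tuple[float, float] | None = None,
) -> float:
    """Weighted average delocalization size over the low-energy band.

    Per state, the delocalization size is the IPR-based count
    N_deloc(k) = 1 / sum_n c_kn^4.  The summary value averages N_deloc
    over states inside ``window`` with the given ``weights`` (default:
    oscillator strengths).  The default window is centred on the
    brightest state and spans the weighted FWHM (2.355 sigma) of the
    stick spectrum.
    """
    sizes = participation_sizes(states)
    if weights is None:
        weights = states.oscillator_strengths
    weights = np.asarray(weights, float)
    if window is None:
        k_bright = int(np.argmax(weights))
        wsum = weights.sum()
        if wsum <= 0:
            return float(sizes.mean())
        mean_e = float(weights @ states.energies / wsum)
        sigma = float(
            np.sqrt(weights @ (states.energies - mean_e) ** 2 / wsum)
        )
        half = max(0.5 * 2.355 * sigma, 1e-9)
        center = states.energies[k_bright]
        window = (center - half, center + half)
    mask = (states.energies >= window[0]) & (states.energies <= window[1])
    if not mask.any() or weights[mask].sum() <= 0:
        return float(sizes[int(np.argmax(weights))])
    return float(weights[mask] @ sizes[mask] / weights[mask].sum())
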