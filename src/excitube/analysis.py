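"""Structural diagnostics and parameter scans.

Pair angle-distance maps quantify local packing order; coupling-sum
histograms quantify the emergent off-diagonal disorder; the rolling-angle
and density scans reproduce the structure-selection reasoning (the
parallel band is insensitive to the rolling angle while the
perpendicular band is not, and the inner-outer wall splitting tracks the
packing-density ratio of the two walls).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import (
    build_double_wall_from_config,
    build_wall_from_config,
    cell_from_config,
    dipole_spec_from_config,
    rolling_from_config,
)
from .disorder import SnapshotEnsemble
from .hamiltonian import (
    build_hamiltonian,
    coupling_sum_per_site,
    solve_structure,
)
from .lattice import (
    IW,
    OW,
    TubeStructure,
    assemble_double_wall,
    build_tube,
    scale_unit_cell,
)
from .spectra import broaden_spectrum, peak_metrics, stick_spectrum

__all__ = [
    "PairMap",
    "pair_angle_distance_map",
    "scan_rolling_angle",
    "scan_density_splitting",
    "factor_for_splitting",
    "coupling_sum_histogram",
    "wall_peak_splitting",
]


@dataclass
class PairMap:
    """2D histogram over pair distance and inter-dipole angle.

    ``counts`` is normalized to the number of binned pairs (sums to 1
    when any pairs exist); the angle uses the axis convention
    phi = arccos(|d_i . d_j|) in [0, 90] degrees, because dipole
    orientation enters the couplings only up to sign.
    """

    r_edges: np.ndarray  # nm
    phi_edges: np.ndarray  # degrees
    counts: np.ndarray  # (n_r, n_phi), normalized
    n_pairs: int
    wall: str | None = None


def pair_angle_distance_map(
    structure: TubeStructure,
    r_max: float = 3.0,
    r_bin: float = 0.05,
    phi_bin: float = 2.0,
    wall: str | None = None,
) -> PairMap:
    """Histogram of (r_ij, phi_ij) over unordered site pairs within r_max."""
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    if wall is not None:
        mask = structure.wall_mask(wall)
        positions = structure.positions[mask]
        dipoles = structure.dipoles[mask]
    else:
        positions = structure.positions
        dipoles = structure.dipoles
    r_edges = np.arange(0.0, r_max + r_bin, r_bin)
    phi_edges = np.arange(0.0, 90.0 + phi_bin, phi_bin)
    tree = cKDTree(positions)
    pairs = tree.query_pairs(r_max, output_type="ndarray")
    if len(pairs) == 0:
        warnings.warn("no site pairs within r_max", stacklevel=2)
        return PairMap(
            r_edges=r_edges,
            phi_edges=phi_edges,
            counts=np.zeros((len(r_edges) - 1, len(phi_edges) - 1)),
            n_pairs=0,
            wall=wall,
        )
    i, j = pairs[:, 0], pairs[:, 1]
    r = np.linalg.norm(positions[i] - positions[j], axis=1)
    cosphi = np.abs(np.einsum("ij,ij->i", dipoles[i], dipoles[j]))
    phi = np.degrees(np.arccos(np.clip(cosphi, 0.0, 1.0)))
    counts, _, _ = np.histogram2d(r, phi, bins=[r_edges, phi_edges])
    return PairMap(
        r_edges=r_edges,
        phi_edges=phi_edges,
        counts=counts / counts.sum(),
        n_pairs=int(len(pairs)),
        wall=wall,
    )


#: Number of screw-periodic images used for ideal-tube band positions.
AXIAL_IMAGES = 3


def _single_wall_metrics(
    cfg: dict, theta: float, fwhm: float, wall: str = IW
) -> dict:
    """Peak diagnostics of one ideal wall at rolling angle ``theta``.

    Ideal-tube band positions are computed with axial screw periodicity,
    so they measure bulk lattice properties rather than open-end effects.
    """
    cell = cell_from_config(cfg)
    spec = dipole_spec_from_config(cfg)
    roll = rolling_from_config(cfg, wall)
    roll = type(roll)(
        radius=roll.radius,
        rolling_angle_deg=theta,
        tube_length=roll.tube_length,
    )
    tube = build_tube(cell, roll, wall=wall, periodic_axial=True)
    _, states = solve_structure(
        tube,
        spec,
        e0=float(cfg["exciton"]["e0_cm1"]),
        screening=float(cfg["exciton"]["screening"]),
        cutoff=cfg["exciton"]["cutoff_nm"],
        axial_images=AXIAL_IMAGES,
    )
    sticks = stick_spectrum(states)
    par_peak = float(sticks.energies[np.argmax(sticks.parallel)])
    perp_peak = float(sticks.energies[np.argmax(sticks.perpendicular)])
    ratio = float(sticks.parallel.sum() / max(sticks.perpendicular.sum(), 1e-300))
    return {
        "theta_deg": theta,
        "theta_actual_deg": tube.metadata["rolling"]["theta_actual_deg"],
        "n_sites": len(tube),
        "parallel_peak_cm1": par_peak,
        "perpendicular_peak_cm1": perp_peak,
        "par_perp_ratio": ratio,
    }


def scan_rolling_angle(
    cfg: dict, thetas: list[float] | None = None, wall: str = IW
) -> pd.DataFrame:
    """Peak metrics of an ideal single wall as a function of rolling angle.

    Peak positions are read off the stick spectrum (brightest parallel /
    perpendicular sticks), which is broadening-independent.
    """
    if thetas is None:
        thetas = cfg["scan"]["rolling_angles_deg"]
    if len(thetas) == 0:
        raise ValueError("at least one rolling angle required")
    fwhm = float(cfg["broadening"]["fwhm_cm1"])
    rows = [_single_wall_metrics(cfg, float(t), fwhm, wall=wall) for t in thetas]
    return pd.DataFrame(rows)


def wall_peak_splitting(cfg: dict, ow_factor: float | None = None) -> float:
    """IW-OW splitting: difference of the brightest parallel stick
    energies of the two ideal walls (cm^-1, positive when OW above IW)."""
    cell = cell_from_config(cfg)
    spec = dipole_spec_from_config(cfg)
    e0 = float(cfg["exciton"]["e0_cm1"])
    screening = float(cfg["exciton"]["screening"])
    cutoff = cfg["exciton"]["cutoff_nm"]
    if ow_factor is None:
        ow_factor = float(cfg["walls"]["ow_scale_factor"])
    peaks = {}
    for wall, factor in ((IW, 1.0), (OW, ow_factor)):
        wall_cell = scale_unit_cell(cell, factor) if factor != 1.0 else cell
        tube = build_tube(
            wall_cell, rolling_from_config(cfg, wall), wall=wall,
            periodic_axial=True,
        )
        _, states = solve_structure(
            tube, spec, e0=e0, screening=screening, cutoff=cutoff,
            axial_images=AXIAL_IMAGES,
        )
        sticks = stick_spectrum(states)
        peaks[wall] = float(sticks.energies[np.argmax(sticks.parallel)])
    return peaks[OW] - peaks[IW]


def scan_density_splitting(
    cfg: dict, factors: list[float] | None = None
) -> pd.DataFrame:
    """IW-OW splitting vs outer-wall lattice expansion factor."""
    if factors is None:
        factors = cfg["scan"]["ow_scale_factors"]
    if any(f <= 0 for f in factors):
        raise ValueError("scale factors must be positive")
    rows = [
        {"ow_scale_factor": float(f), "splitting_cm1": wall_peak_splitting(cfg, float(f))}
        for f in factors
    ]
    return pd.DataFrame(rows)


def factor_for_splitting(table: pd.DataFrame, target: float) -> float:
    """Inverse lookup: expansion factor giving a target splitting, by
    linear interpolation of a monotone scan table."""
    f = np.asarray(table["ow_scale_factor"], float)
    s = np.asarray(table["splitting_cm1"], float)
    order = np.argsort(s)
    s, f = s[order], f[order]
    if not (s[0] <= target <= s[-1]):
        raise ValueError(
            f"target splitting {target} cm^-1 not bracketed by the scan "
            f"range [{s[0]:.1f}, {s[-1]:.1f}]"
        )
    return float(np.interp(target, s, f))


def coupling_sum_histogram(
    ensemble: SnapshotEnsemble,
    spec,
    e0: float = 0.0,
    screening: float = 1.0,
    cutoff: float | None = None,
    bins: int = 60,
) -> dict[str, dict]:
    """Pooled per-wall histograms of the coupling sums across snapshots."""
    pooled: dict[str, list[np.ndarray]] = {}
    for structure, _ in ensemble:
        h = build_hamiltonian(
            structure, spec, e0=e0, cutoff=cutoff, screening=screening
        )
        sums = coupling_sum_per_site(h)
        for wall in np.unique(structure.walls):
            pooled.setdefault(str(wall), []).append(sums[structure.walls == wall])
    out: dict[str, dict] = {}
    for wall, chunks in pooled.items():
        vals = np.concatenate(chunks)
        if np.ptp(vals) < 1e-9:  # delta-like ideal distribution
            center = float(vals[0])
            counts, edges = np.histogram(
                vals, bins=1, range=(center - 0.5, center + 0.5)
            )
        else:
            counts, edges = np.histogram(vals, bins=bins)
        out[wall] = {
            "values": vals,
            "counts": counts,
            "edges": edges,
            "mean": float(vals.mean()),
            "std": float(vals.std()),
        }
    return out
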