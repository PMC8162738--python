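"""Absorption spectra: sticks, broadening, ensemble averages, peak metrics.

Spectra are computed on an energy grid (cm^-1); the wavelength view is a
pure reindexing lambda = 1e7 / E (no Jacobian by default).  Intensities
are decomposed by polarization relative to the tube axis (parallel = z,
perpendicular = x, y) and, diagnostically, by wall via the eigenvector
weight each state carries on IW and OW sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_widths

from .hamiltonian import ExcitonStates

__all__ = [
    "StickSpectrum",
    "AbsorptionSpectrum",
    "PeakMetrics",
    "stick_spectrum",
    "broaden_spectrum",
    "ensemble_average_spectrum",
    "peak_metrics",
]


@dataclass
class StickSpectrum:
    """Per-eigenstate intensities before broadening."""

    energies: np.ndarray  # (M,), cm^-1
    parallel: np.ndarray  # (M,), mu_k,z^2
    perpendicular: np.ndarray  # (M,), mu_k,x^2 + mu_k,y^2
    wall_weights: dict[str, np.ndarray]  # weight of each state on a wall

    @property
    def total(self) -> np.ndarray:
        return self.parallel + self.perpendicular


@dataclass
class AbsorptionSpectrum:
    """Broadened absorption on an energy grid, with channel decompositions."""

    energy: np.ndarray  # (G,), cm^-1
    total: np.ndarray
    parallel: np.ndarray
    perpendicular: np.ndarray
    walls: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def wavelength(self) -> np.ndarray:
        """Wavelength view in nm (reindexing only; no Jacobian)."""
        return 1e7 / self.energy

    def normalized(self, mode: str = "max") -> "AbsorptionSpectrum":
        """Return a copy scaled so that max(total) == 1 ('max') or the
        integrated total equals 1 ('area')."""
        if mode == "max":
            scale = self.total.max()
        elif mode == "area":
            scale = np.trapezoid(self.total, self.energy)
        else:
            raise ValueError(f"unknown normalization mode {mode!r}")
        if scale <= 0:
            return self
        return AbsorptionSpectrum(
            energy=self.energy.copy(),
            total=self.total / scale,
            parallel=self.parallel / scale,
            perpendicular=self.perpendicular / scale,
            walls={k: v / scale for k, v in self.walls.items()},
            metadata=dict(self.metadata),
        )

    def to_frame(self) -> pd.DataFrame:
        data = {
            "energy_cm-1": self.energy,
            "wavelength_nm": self.wavelength,
            "total": self.total,
            "parallel": self.parallel,
            "perpendicular": self.perpendicular,
        }
        for wall, vals in self.walls.items():
            data[wall] = vals
        return pd.DataFrame(data)


def stick_spectrum(states: ExcitonStates) -> StickSpectrum:
    """Polarization-resolved stick spectrum from eigenstates.

    Parallel intensity of state k is mu_k,z^2 and perpendicular intensity
    mu_k,x^2 + mu_k,y^2.  The wall weight of state k on wall w is
    sum_{n in w} c_kn^2 (sums to 1 over walls for each state).
    """
    if states.dipoles is None:
        raise ValueError("states carry no collective dipoles")
    mu = states.dipoles
    parallel = mu[:, 2] ** 2
    perpendicular = mu[:, 0] ** 2 + mu[:, 1] ** 2
    wall_weights: dict[str, np.ndarray] = {}
    if states.walls is not None:
        probs = states.coeffs**2
        for wall in np.unique(states.walls):
            wall_weights[str(wall)] = probs[:, states.walls == wall].sum(axis=1)
    return StickSpectrum(
        energies=states.energies.copy(),
        parallel=parallel,
        perpendicular=perpendicular,
        wall_weights=wall_weights,
    )


def _lorentzian(grid: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    half = 0.5 * fwhm
    return (half / np.pi) / ((grid - center) ** 2 + half**2)


def _gaussian(grid: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((grid - center) / sigma) ** 2) / (
        sigma * np.sqrt(2.0 * np.pi)
    )


_LINESHAPES = {"lorentzian": _lorentzian, "gaussian": _gaussian}


def default_grid(
    sticks: StickSpectrum, fwhm: float, n_points: int = 2000, margin: float = 10.0
) -> np.ndarray:
    """Energy grid covering all sticks plus ``margin`` linewidths."""
    weight = sticks.total
    active = weight > 1e-12 * max(weight.max(), 1e-300)
    energies = sticks.energies[active] if active.any() else sticks.energies
    lo = energies.min() - margin * fwhm
    hi = energies.max() + margin * fwhm
    return np.linspace(lo, hi, n_points)


def broaden_spectrum(
    sticks: StickSpectrum,
    fwhm: float,
    grid: np.ndarray | None = None,
    lineshape: str = "lorentzian",
    fwhm_perpendicular: float | None = None,
    n_points: int = 2000,
) -> AbsorptionSpectrum:
    """Convolve a stick spectrum with a homogeneous lineshape.

    The broadening is phenomenological: every stick is replaced by a
    unit-area Lorentzian (default) or Gaussian of the given FWHM, scaled
    by the stick weight, so the integrated spectrum equals the total
    stick weight.  An optional different FWHM may be applied to the
    perpendicular channel.
    """
    if fwhm <= 0:
        raise ValueError("broadening width must be positive")
    try:
        shape = _LINESHAPES[lineshape]
    except KeyError:
        raise ValueError(f"unknown lineshape {lineshape!r}") from None
    if grid is None:
        grid = default_grid(sticks, fwhm, n_points=n_points)
    else:
        grid = np.asarray(grid, float)
        weight = sticks.total
        active = weight > 1e-12 * max(weight.max(), 1e-300)
        if active.any():
            lo, hi = sticks.energies[active].min(), sticks.energies[active].max()
            if grid.min() > lo - 5 * fwhm or grid.max() < hi + 5 * fwhm:
                warnings.warn(
                    "energy grid does not cover all sticks +- 5 linewidths; "
                    "integrated intensity will be truncated",
                    stacklevel=2,
                )

    fwhm_perp = fwhm if fwhm_perpendicular is None else fwhm_perpendicular
    par = np.zeros_like(grid)
    perp = np.zeros_like(grid)
    walls = {w: np.zeros_like(grid) for w in sticks.wall_weights}
    for k in range(len(sticks.energies)):
        if sticks.parallel[k] > 0:
            line = shape(grid, sticks.energies[k], fwhm)
            par += sticks.parallel[k] * line
        if sticks.perpendicular[k] > 0:
            line_p = shape(grid, sticks.energies[k], fwhm_perp)
            perp += sticks.perpendicular[k] * line_p
        tot_k = sticks.parallel[k] + sticks.perpendicular[k]
        if tot_k > 0 and walls:
            line = shape(grid, sticks.energies[k], fwhm)
            for w, ww in sticks.wall_weights.items():
                walls[w] += ww[k] * tot_k * line
    return AbsorptionSpectrum(
        energy=grid,
        total=par + perp,
        parallel=par,
        perpendicular=perp,
        walls=walls,
        metadata={"lineshape": lineshape, "fwhm": fwhm, "n_snapshots": 1},
    )


def ensemble_average_spectrum(
    spectra: list[AbsorptionSpectrum],
) -> AbsorptionSpectrum:
    """Average per-snapshot spectra channel by channel (common grid)."""
    if not spectra:
        raise ValueError("no spectra to average")
    grid = spectra[0].energy
    for s in spectra[1:]:
        if s.energy.shape != grid.shape or not np.allclose(s.energy, grid):
            raise ValueError("spectra must share a common energy grid")
    n = len(spectra)
    walls: dict[str, np.ndarray] = {}
    for w in spectra[0].walls:
        walls[w] = sum(s.walls[w] for s in spectra) / n
    meta = dict(spectra[0].metadata)
    meta["n_snapshots"] = n
    return AbsorptionSpectrum(
        energy=grid.copy(),
        total=sum(s.total for s in spectra) / n,
        parallel=sum(s.parallel for s in spectra) / n,
        perpendicular=sum(s.perpendicular for s in spectra) / n,
        walls=walls,
        metadata=meta,
    )


@dataclass
class PeakMetrics:
    """Peak positions/heights/widths of one spectrum channel."""

    positions: np.ndarray  # cm^-1, ascending
    heights: np.ndarray
    fwhms: np.ndarray  # cm^-1
    splitting: float | None  # E2 - E1 of the two lowest peaks, cm^-1
    area_ratio: float | None  # integrated area lowest / second-lowest


def peak_metrics(
    spectrum: AbsorptionSpectrum,
    channel: str = "parallel",
    prominence_frac: float = 0.02,
    window_fwhm: float = 1.5,
) -> PeakMetrics:
    """Locate peaks and report positions, FWHMs, splitting and area ratio.

    Peaks come from a local-maximum search with quadratic (three-point
    parabola) refinement of the position.  The splitting is the energy
    difference of the two lowest-energy peaks; the area ratio integrates
    each of those peaks over a window of ``window_fwhm`` FWHMs.
    """
    y = getattr(spectrum, channel) if channel != "IW" and channel != "OW" else spectrum.walls[channel]
    x = spectrum.energy
    if y.max() <= 0:
        warnings.warn("channel carries no intensity; no peaks found", stacklevel=2)
        return PeakMetrics(np.array([]), np.array([]), np.array([]), None, None)
    idx, _ = find_peaks(y, prominence=prominence_frac * y.max())
    if len(idx) == 0:
        warnings.warn("no peaks found in channel", stacklevel=2)
        return PeakMetrics(np.array([]), np.array([]), np.array([]), None, None)

    widths, _, _, _ = peak_widths(y, idx, rel_height=0.5)
    dx = x[1] - x[0]
    positions = []
    heights = []
    for i in idx:
        if 0 < i < len(x) - 1:
            y0, y1, y2 = y[i - 1], y[i], y[i + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            positions.append(x[i] + delta * dx)
            heights.append(y1 - 0.25 * (y0 - y2) * delta)
        else:
            positions.append(x[i])
            heights.append(y[i])
    positions = np.asarray(positions)
    heights = np.asarray(heights)
    fwhms = widths * dx

    order = np.argsort(positions)
    positions, heights, fwhms = positions[order], heights[order], fwhms[order]

    splitting = None
    area_ratio = None
    if len(positions) >= 2:
        splitting = float(positions[1] - positions[0])
        areas = []
        for p, w in zip(positions[:2], fwhms[:2]):
            lo, hi = p - window_fwhm * w, p + window_fwhm * w
            mask = (x >= lo) & (x <= hi)
            areas.append(np.trapezoid(y[mask], x[mask]) if mask.sum() > 1 else 0.0)
        if areas[1] > 0:
            area_ratio = float(areas[0] / areas[1])
    return PeakMetrics(
        positions=positions,
        heights=heights,
        fwhms=fwhms,
        splitting=splitting,
        area_ratio=area_ratio,
    )
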