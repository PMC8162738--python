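"""Writers for structures, Hamiltonians and spectra (plain-text + HDF5)."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .hamiltonian import ExcitonHamiltonian
from .lattice import ExtendedDipoleSpec, TubeStructure, charge_endpoints
from .spectra import AbsorptionSpectrum

__all__ = [
    "write_xyz",
    "write_pdb",
    "write_hamiltonian_h5",
    "write_hamiltonian_tsv",
    "write_spectrum_tsv",
]


def write_xyz(
    structure: TubeStructure,
    path: str | Path,
    spec: ExtendedDipoleSpec | None = None,
    comment: str = "tube structure (pseudo-atoms; nm coordinates)",
) -> None:
    """One pseudo-atom per site ('C' IW / 'N' OW); with a dipole spec the
    +q/-q endpoints are written as additional 'P'/'Q' pseudo-atoms."""
    lines = []
    symbols = {"IW": "C", "OW": "N"}
    for i in range(len(structure)):
        x, y, z = structure.positions[i]
        lines.append(f"{symbols.get(str(structure.walls[i]), 'X')} {x:.6f} {y:.6f} {z:.6f}")
    if spec is not None:
        plus, minus = charge_endpoints(structure, spec)
        for p in plus:
            lines.append(f"P {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
        for q in minus:
            lines.append(f"Q {q[0]:.6f} {q[1]:.6f} {q[2]:.6f}")
    with open(path, "w") as fh:
        fh.write(f"{len(lines)}\n{comment}\n")
        fh.write("\n".join(lines) + "\n")


def write_pdb(structure: TubeStructure, path: str | Path) -> None:
    """Sites as HETATM pseudo-atoms, wall label in the chain ID.

    Coordinates are converted to Angstrom per the PDB convention.
    """
    chain = {"IW": "A", "OW": "B"}
    with open(path, "w") as fh:
        fh.write("REMARK   generated by excitube; one pseudo-atom per chromophore\n")
        for i in range(len(structure)):
            x, y, z = structure.positions[i] * 10.0
            wall = str(structure.walls[i])
            serial = (i + 1) % 100000
            resseq = (i + 1) % 10000
            fh.write(
                f"HETATM{serial:5d}  C   CHR {chain.get(wall, 'X')}{resseq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


def write_hamiltonian_h5(h: ExcitonHamiltonian, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("matrix", data=h.matrix)
        fh.create_dataset("walls", data=np.asarray(h.walls, dtype="S2"))
        fh.attrs["e0_cm1"] = h.e0


def write_hamiltonian_tsv(h: ExcitonHamiltonian, path: str | Path) -> None:
    """Dense TSV export, intended for small matrices only."""
    np.savetxt(path, h.matrix, delimiter="\t", fmt="%.8g")


def write_spectrum_tsv(spectrum: AbsorptionSpectrum, path: str | Path) -> None:
    spectrum.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")
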