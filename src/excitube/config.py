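"""Flat YAML configuration: defaults, loading, and object construction."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .constants import E0_MONOMER_CM1
from .disorder import DiagonalDisorderModel, StructuralJitterModel
from .lattice import (
    IW,
    OW,
    BasisMolecule,
    ExtendedDipoleSpec,
    RollingSpec,
    TubeStructure,
    UnitCell2D,
    assemble_double_wall,
    build_tube,
    scale_unit_cell,
)

__all__ = [
    "default_config",
    "load_config",
    "dump_config",
    "cell_from_config",
    "dipole_spec_from_config",
    "rolling_from_config",
    "build_wall_from_config",
    "build_double_wall_from_config",
    "disorder_from_config",
]

_DEFAULTS: dict = {
    "unit_cell": {
        "a1": [1.70, 0.0],
        "a2": [0.0, 0.92],
        "basis": [
            {"fraction": [0.0, 0.0], "orientation_deg": -15.0, "tilt_deg": 8.0},
            {"fraction": [0.5, 0.5], "orientation_deg": 15.0, "tilt_deg": 8.0},
        ],
    },
    "walls": {
        "iw": {"radius": 3.2, "rolling_angle_deg": 30.0},
        "ow": {"radius": 5.7, "rolling_angle_deg": 30.0},
        "tube_length": 30.0,
        "ow_scale_factor": 1.024,
    },
    "extended_dipole": {"charge_e": 0.34, "length_nm": 0.70},
    "exciton": {"e0_cm1": E0_MONOMER_CM1, "screening": 1.0, "cutoff_nm": None},
    "disorder": {
        "mean_cm1": {"IW": 350.0, "OW": 350.0},
        "sigma_cm1": {"IW": 213.0, "OW": 231.0},
        "sigma_pos_nm": 0.05,
        "sigma_orient_deg": 5.0,
        "relaxation_scale": 1.02,
        "n_snapshots": 20,
    },
    "broadening": {"lineshape": "lorentzian", "fwhm_cm1": 150.0},
    "scan": {
        "rolling_angles_deg": [20.0, 30.0, 40.0, 55.0],
        "ow_scale_factors": [1.0, 1.01, 1.02, 1.03, 1.04],
    },
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, deep-merged over the shipped defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    return cfg


def dump_config(cfg: dict) -> str:
    return yaml.safe_dump(cfg, sort_keys=False)


def cell_from_config(cfg: dict) -> UnitCell2D:
    uc = cfg["unit_cell"]
    return UnitCell2D(
        a1=tuple(uc["a1"]),
        a2=tuple(uc["a2"]),
        basis=tuple(
            BasisMolecule(
                fraction=tuple(b["fraction"]),
                orientation_deg=float(b["orientation_deg"]),
                tilt_deg=float(b.get("tilt_deg", 0.0)),
            )
            for b in uc["basis"]
        ),
    )


def dipole_spec_from_config(cfg: dict) -> ExtendedDipoleSpec:
    ed = cfg["extended_dipole"]
    return ExtendedDipoleSpec(charge=float(ed["charge_e"]), length=float(ed["length_nm"]))


def rolling_from_config(cfg: dict, wall: str) -> RollingSpec:
    walls = cfg["walls"]
    entry = walls[wall.lower()]
    return RollingSpec(
        radius=float(entry["radius"]),
        rolling_angle_deg=float(entry["rolling_angle_deg"]),
        tube_length=float(walls["tube_length"]),
    )


def build_wall_from_config(cfg: dict, wall: str) -> TubeStructure:
    """Build one wall; the OW lattice is expanded by ``ow_scale_factor``."""
    cell = cell_from_config(cfg)
    if wall == OW:
        cell = scale_unit_cell(cell, float(cfg["walls"]["ow_scale_factor"]))
    return build_tube(cell, rolling_from_config(cfg, wall), wall=wall)


def build_double_wall_from_config(cfg: dict) -> TubeStructure:
    return assemble_double_wall(
        build_wall_from_config(cfg, IW), build_wall_from_config(cfg, OW)
    )


def disorder_from_config(cfg: dict) -> tuple[StructuralJitterModel, DiagonalDisorderModel]:
    d = cfg["disorder"]
    jitter = StructuralJitterModel(
        sigma_pos=float(d["sigma_pos_nm"]),
        sigma_orient_deg=float(d["sigma_orient_deg"]),
        relaxation_scale=float(d.get("relaxation_scale", 1.0)),
    )
    diag = DiagonalDisorderModel(
        mean={k: float(v) for k, v in d["mean_cm1"].items()},
        sigma={k: float(v) for k, v in d["sigma_cm1"].items()},
    )
    return jitter, diag
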