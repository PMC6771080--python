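"""Run configuration: YAML with explicit SI units in key names.

A run config has sections ``grid``, ``phantom``, ``coil``, ``exposure``,
``suite``, ``dose``, ``solver`` and ``outputs``; :func:`load_config`
validates required keys and reports the missing ones by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .bioheat import BioheatParams, PerfusionModel
from .mnp import REFERENCE_SUITE, FerrofluidDose, FieldExposure, MNPSuite
from .phantom import PhantomConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "default_config_dict"]


class ConfigError(ValueError):
    """A required configuration key is missing or invalid."""


def default_config_dict() -> dict:
    """A complete, runnable demo configuration (small grid, short heating)."""
    return {
        "seed": 1,
        "grid": {"n": 48, "spacing_m": 3.0e-3},
        "phantom": {
            "breast_radius_m": 50.0e-3,
            "skin_thickness_m": 2.0e-3,
            "muscle_thickness_m": 12.0e-3,
            "fat_thickness_m": 5.0e-3,
            "gland_band": [0.51, 0.75],
            "tumour_volume_ml": 2.0,
        },
        "coil": {"radius_m": 110.0e-3, "n_turns": 17, "length_m": 120.0e-3},
        "exposure": {"Hmax_A_per_m": 10.3e3, "f_Hz": 171.0e3},
        "suite": {
            "Ms_A_per_m": REFERENCE_SUITE.Ms,
            "K_J_per_m3": 30.0e3,
            "d_median_m": 15.2e-9,
            "s_ln": 0.19,
            "delta_m": 2.0e-9,
            "eta_Pa_s": 8.94e-4,
            "T_K": 298.0,
            "f0_per_s": 1.0e9,
            "rho_p_kg_per_m3": 5180.0,
        },
        "dose": {"c_ref_kg_per_m3": 5.0, "phi_r": 1.0, "mode": "mobilised"},
        "solver": {
            "eddy_rtol": 1.0e-8,
            "dt_s": 1.0,
            "duration_s": 300.0,
            "Tb_C": 37.0,
            "rho_b_kg_per_m3": 1050.0,
            "c_b_J_per_kg_C": 3617.0,
            "h_conv_W_per_m2_C": 10.0,
            "T_ext_C": 25.0,
        },
        "outputs": {"save_every_s": 60.0},
    }


@dataclass
class RunConfig:
    """Validated run configuration assembled into package objects."""

    seed: int
    phantom: PhantomConfig
    tumour_volume_m3: float
    coil: dict
    exposure: FieldExposure
    suite: MNPSuite
    dose: FerrofluidDose
    bioheat: BioheatParams
    eddy_rtol: float
    duration_s: float
    save_every_s: float | None
    raw: dict = field(repr=False, default_factory=dict)


def _require(d: dict, section: str, key: str):
    if section not in d:
        raise ConfigError(f"missing config section '{section}'")
    if key not in d[section]:
        raise ConfigError(f"missing config key '{section}.{key}'")
    return d[section][key]


def parse_config(data: dict) -> RunConfig:
    """Validate a config dict and build the run objects."""
    if "seed" not in data:
        raise ConfigError("missing config key 'seed'")
    phantom_cfg = PhantomConfig(
        grid=int(_require(data, "grid", "n")),
        spacing=float(_require(data, "grid", "spacing_m")),
        breast_radius=float(_require(data, "phantom", "breast_radius_m")),
        skin_thickness=float(data["phantom"].get("skin_thickness_m", 2.0e-3)),
        muscle_thickness=float(data["phantom"].get("muscle_thickness_m", 12.0e-3)),
        fat_thickness=float(data["phantom"].get("fat_thickness_m", 5.0e-3)),
        gland_band=tuple(data["phantom"].get("gland_band", (0.51, 0.75))),
    )
    suite = MNPSuite(
        Ms=float(_require(data, "suite", "Ms_A_per_m")),
        K=float(_require(data, "suite", "K_J_per_m3")),
        d_median=float(_require(data, "suite", "d_median_m")),
        s_ln=float(_require(data, "suite", "s_ln")),
        delta=float(data["suite"].get("delta_m", 0.0)),
        eta=float(data["suite"].get("eta_Pa_s", 8.94e-4)),
        T=float(data["suite"].get("T_K", 298.0)),
        f0=float(data["suite"].get("f0_per_s", 1.0e9)),
        rho_p=float(data["suite"].get("rho_p_kg_per_m3", 5180.0)),
    )
    exposure = FieldExposure(
        Hmax=float(_require(data, "exposure", "Hmax_A_per_m")),
        f=float(_require(data, "exposure", "f_Hz")),
    )
    dose = FerrofluidDose(
        c_ref=float(_require(data, "dose", "c_ref_kg_per_m3")),
        phi_r=float(data["dose"].get("phi_r", 1.0)),
        mode=str(data["dose"].get("mode", "mobilised")),
    )
    solver = data.get("solver", {})
    bio = BioheatParams(
        Tb=float(solver.get("Tb_C", 37.0)),
        rho_b=float(solver.get("rho_b_kg_per_m3", 1050.0)),
        c_b=float(solver.get("c_b_J_per_kg_C", 3617.0)),
        h_conv=float(solver.get("h_conv_W_per_m2_C", 10.0)),
        T_ext=float(solver.get("T_ext_C", 25.0)),
        dt=float(solver.get("dt_s", 1.0)),
        perfusion=PerfusionModel(),
    )
    return RunConfig(
        seed=int(data["seed"]),
        phantom=phantom_cfg,
        tumour_volume_m3=float(data["phantom"].get("tumour_volume_ml", 2.0)) * 1e-6,
        coil=data.get("coil", {}),
        exposure=exposure,
        suite=suite,
        dose=dose,
        bioheat=bio,
        eddy_rtol=float(solver.get("eddy_rtol", 1e-8)),
        duration_s=float(solver.get("duration_s", 1800.0)),
        save_every_s=(
            float(data["outputs"]["save_every_s"])
            if "outputs" in data and data["outputs"].get("save_every_s") is not None
            else None
        ),
        raw=data,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return parse_config(data)
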