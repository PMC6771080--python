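"""End-to-end treatment-planning pipeline.

Stages: synthetic phantom → applicator field (calibrated to the target
amplitude at the applicator centre) → eddy-current solve and hot spots →
tumour placement at the strongest non-skin hot spot → nanoparticle power →
baseline steady state → transient heating → dose report.  All artefacts are
written to a run directory: NIfTI volumes, CSV tables with units in headers,
a JSON dose report and a provenance record (config, seed, versions).
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__, bioheat, coil, dosimetry, eddy, mnp, phantom as phantom_mod
from .config import RunConfig
from .phantom import Label, VoxelPhantom, embed_tumour, generate_phantom, save_phantom

log = logging.getLogger("mfhplan")

__all__ = ["run_pipeline", "place_tumour_at_hotspot"]


def place_tumour_at_hotspot(
    phantom: VoxelPhantom,
    P_eddy: np.ndarray,
    volume: float,
    max_nudge: int = 40,
) -> tuple[VoxelPhantom, np.ndarray]:
    """Embed a tumour sphere at the strongest non-skin eddy hot spot.

    Hot spots near the skin cannot host the full sphere; the centre is nudged
    towards the breast interior (along the line to the top of the breast-fat
    centroid) one voxel at a time until the sphere fits.

    Returns the phantom with tumour and the chosen centre (m).
    """
    spots = eddy.find_hot_spots(P_eddy, phantom, k=10)
    h = phantom.spacing
    interior = np.isin(phantom.labels, [Label.BREAST_FAT, Label.BREAST_GLAND])
    target = (np.argwhere(interior).mean(axis=0) + 0.5) * h
    last_err = None
    for value, pos in spots:
        centre = (np.asarray(pos) + 0.5) * h
        direction = target - centre
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 0 else np.zeros(3)
        for step in range(max_nudge + 1):
            cand = centre + step * h * direction
            try:
                placed = embed_tumour(phantom, cand, volume)
                return placed, cand
            except phantom_mod.PhantomError as err:
                last_err = err
    raise phantom_mod.PhantomError(
        f"could not place the tumour sphere near any hot spot: {last_err}"
    )


def _save_map(data: np.ndarray, ph: VoxelPhantom, path: Path) -> None:
    affine = np.diag([ph.spacing * 1e3] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.nan_to_num(data).astype(np.float32), affine), str(path))


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> Path:
    """Execute all stages and write artefacts to ``outdir``.

    Deterministic for a fixed config seed.  Raises with a stage-tagged
    message if any stage fails.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "init"
    try:
        stage = "phantom"
        ph = generate_phantom(cfg.phantom, seed=cfg.seed)
        log.info("phantom: grid %s, gland fraction %.3f", ph.shape, ph.glandular_fraction())

        stage = "field"
        extent = cfg.phantom.grid * cfg.phantom.spacing
        breast_centre = (
            extent / 2.0,
            extent / 2.0,
            cfg.phantom.muscle_thickness + cfg.phantom.fat_thickness + 0.4 * cfg.phantom.breast_radius,
        )
        spec = coil.default_coil(
            centre=breast_centre,
            radius=float(cfg.coil.get("radius_m", 110.0e-3)),
            n_turns=int(cfg.coil.get("n_turns", 17)),
            length=float(cfg.coil.get("length_m", 120.0e-3)),
        )
        current = coil.calibrate_current(spec, cfg.exposure.Hmax, np.asarray(spec.centre))
        spec = coil.CoilSpec(
            radius=spec.radius, turn_positions=spec.turn_positions,
            current=current, centre=spec.centre, axis=spec.axis,
        )
        H_map, A_map = coil.field_on_grid(spec, ph)
        log.info("field: calibrated current %.1f A for %.1f kA/m", current, cfg.exposure.Hmax / 1e3)

        stage = "eddy"
        em = eddy.solve_eddy(ph, A_map, cfg.exposure.f, rtol=cfg.eddy_rtol)
        spots = eddy.find_hot_spots(em.P_eddy, ph, k=5)

        stage = "tumour"
        ph, centre = place_tumour_at_hotspot(ph, em.P_eddy, cfg.tumour_volume_m3)
        em = eddy.solve_eddy(ph, A_map, cfg.exposure.f, rtol=cfg.eddy_rtol)  # tumour changes sigma

        stage = "slp"
        slp_mob = mnp.slp(cfg.suite, cfg.exposure, "mobilised")
        slp_imm = mnp.slp(cfg.suite, cfg.exposure, "immobilised")
        slp_used = slp_mob if cfg.dose.mode == "mobilised" else slp_imm
        p_mnp = mnp.volumetric_power(slp_used, cfg.dose)
        log.info("slp: mobilised %.3g W/kg, immobilised %.3g W/kg, dose %.3g kW/m^3",
                 slp_mob, slp_imm, p_mnp / 1e3)

        stage = "bioheat"
        T0 = bioheat.steady_state(ph, cfg.bioheat)
        sources = em.P_eddy + bioheat.mnp_source_map(ph, p_mnp)
        run = bioheat.simulate(
            ph, T0, sources, cfg.bioheat,
            duration=cfg.duration_s, save_every=cfg.save_every_s,
        )

        stage = "dosimetry"
        report = dosimetry.DoseReport.from_run(run, ph, cfg.exposure)

        stage = "outputs"
        save_phantom(ph, outdir / "phantom.nii.gz")
        _save_map(np.linalg.norm(H_map, axis=-1), ph, outdir / "H_magnitude_A_per_m.nii.gz")
        _save_map(em.P_eddy, ph, outdir / "P_eddy_W_per_m3.nii.gz")
        _save_map(run.final, ph, outdir / "T_final_C.nii.gz")
        pd.DataFrame(
            [(r + 1, *pos, val / 1e3) for r, (val, pos) in enumerate(spots)],
            columns=["rank", "i", "j", "k", "P_eddy_kW_per_m3"],
        ).to_csv(outdir / "hot_spots.csv", index=False)
        probe = pd.DataFrame(
            run.probe,
            columns=["time_s", "tumour_centre_C", "tumour_max_C", "tumour_min_C", "skin_max_C"],
        )
        probe.to_csv(outdir / "probe.csv", index=False, float_format="%.6f")
        report_dict = {
            "cem43_tumour_median_min": report.cem43_tumour_median_min,
            "cem43_tumour_min_min": report.cem43_tumour_min_min,
            "isotherm_volumes_m3": report.isotherm_volumes_m3,
            "tumour_coverage": report.tumour_coverage,
            "safety_index": asdict(report.safety),
            "slp_mobilised_W_per_kg": slp_mob,
            "slp_immobilised_W_per_kg": slp_imm,
            "P_mnp_W_per_m3": p_mnp,
            "tumour_centre_m": [float(c) for c in centre],
        }
        (outdir / "dose_report.json").write_text(json.dumps(report_dict, indent=2))
        provenance = {
            "mfhplan_version": __version__,
            "python": platform.python_version(),
            "seed": cfg.seed,
            "coil_current_A": current,
        }
        (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
        (outdir / "config.yaml").write_text(yaml.safe_dump(cfg.raw))
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
    return outdir
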