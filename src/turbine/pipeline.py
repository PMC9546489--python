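"""End-to-end pipeline: simulate -> correct -> reconstruct -> analyze.

Configuration is a plain dict (YAML/JSON friendly); every stage can be
skipped, all randomness flows from explicit seeds, and reruns with the same
config are bit-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import analysis, corrections, io, recon, simulator, trajectory
from .errors import InvalidArgumentError

DEFAULT_CONFIG = {
    "seed": 1234,
    "grid": 96,
    "n_partitions": 8,
    "n_coils": 8,
    "n_volumes": 20,
    "shots_per_volume": 40,
    "noise_sd": 0.002,
    "effect_fraction": 0.02,
    "block_s": 30.0,
    "tr_shot_ms": 58.0,
    "te_ms": 23.0,
    "physio": {"respiratory_amp_rad": 0.3, "respiratory_freq_hz": 0.3,
               "cardiac_amp_rad": 0.1, "cardiac_freq_hz": 1.0,
               "drift_amp_rad": 0.05},
    "ghost": {"constant_phase_rad": 0.3, "linear_shift_samples": 0.8},
    "corrections": {"ghost": True, "k0": True, "reference_shot": 0},
    "recon": {"lambda_t": 1e4, "max_iter": 60, "mode": "slab2d",
              "shots_per_frame": None, "n_virtual_coils": 6},
    "analysis": {"highpass_s": 60.0, "tsnr": True, "glm": True},
}


def _merged(config):
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def build_protocol(cfg) -> trajectory.TurbineProtocol:
    grid = cfg["grid"]
    nz = cfg["n_partitions"]
    return trajectory.TurbineProtocol(
        fov_mm=(192.0, 192.0, 2.0 * nz), matrix=(grid, grid, nz),
        shots_per_volume=cfg["shots_per_volume"], r_inplane=1,
        te_ms=cfg["te_ms"], tr_shot_ms=cfg["tr_shot_ms"],
    )


def simulate_stage(cfg, out_path=None) -> simulator.RawKspace:
    protocol = build_protocol(cfg)
    seed = int(cfg["seed"])
    grid = (cfg["grid"], cfg["grid"], cfg["n_partitions"])
    phantom = simulator.make_phantom(grid, seed=seed)
    coils = simulator.make_coil_sensitivities(grid, cfg["n_coils"], seed=seed + 1)
    blades = trajectory.make_blades(protocol, cfg["n_volumes"] * cfg["shots_per_volume"])
    task = simulator.make_task_timeseries(
        cfg["n_volumes"], trajectory.nominal_volume_tr(protocol),
        cfg["block_s"], cfg["effect_fraction"])
    physio = simulator.PhysioPhaseModel(seed=seed + 2, **cfg["physio"]) if cfg["physio"] else None
    ghost = simulator.GhostModel(**cfg["ghost"]) if cfg["ghost"] else None
    raw = simulator.simulate_acquisition(
        phantom, coils, blades, physio=physio, ghost=ghost,
        noise_sd=cfg["noise_sd"], task=task, protocol=protocol, seed=seed + 3)
    if out_path is not None:
        io.write_raw(out_path, raw)
    return raw


def correct_stage(raw, cfg):
    c = cfg["corrections"]
    return corrections.correct(raw, ghost=c.get("ghost", True), k0=c.get("k0", True),
                               reference_shot=c.get("reference_shot", 0))


def recon_stage(raw, cfg) -> simulator.ImageSeries:
    r = cfg["recon"]
    n_virtual = min(r.get("n_virtual_coils", 12), raw.n_coils)
    compressed, _, _ = recon.compress_coils(raw, n_virtual)
    maps = recon.calibrate_sensitivities(compressed)
    rc = recon.ReconConfig(lambda_t=r["lambda_t"], max_iter=r["max_iter"],
                           mode=r["mode"], shots_per_frame=r["shots_per_frame"],
                           n_virtual_coils=n_virtual)
    return recon.reconstruct(compressed, maps, rc)


def analyze_stage(series, cfg):
    a = cfg["analysis"]
    mag = series.magnitude()
    out = {}
    if series.n_frames < 8:  # too short for spectral DOF / GLM statistics
        return out
    if a.get("tsnr", True):
        mask = mag.mean(axis=-1) > 0.1 * mag.max()
        dof = analysis.effective_dof(mag[mask])
        out["tsnr"] = analysis.adjusted_tsnr(mag, dof=dof, nt=series.n_frames)
    if a.get("glm", True):
        nvol = series.n_frames
        task = simulator.task_boxcar(nvol, series.tr_vol_s, cfg["block_s"])
        out["glm"] = analysis.glm_activation(mag, task, series.tr_vol_s,
                                             highpass_s=a.get("highpass_s", 60.0))
    return out


def run_pipeline(config=None, outdir=None):
    """Run the configured stages in acquisition-pipeline order.

    Returns a dict with the intermediate products; when ``outdir`` is given,
    raw/corrected HDF5, reconstruction NIfTI and statistic maps are written
    there together with a manifest.
    """
    cfg = _merged(config)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    results = {"config": cfg}
    raw = simulate_stage(cfg, out_path=(outdir / "raw.h5") if outdir else None)
    results["raw"] = raw
    corrected = correct_stage(raw, cfg)
    results["corrected"] = corrected
    if outdir is not None:
        io.write_raw(outdir / "corrected.h5", corrected)
    series = recon_stage(corrected, cfg)
    results["recon"] = series
    if outdir is not None:
        io.write_nifti(outdir / "recon.nii.gz", series)
    stats = analyze_stage(series, cfg)
    results.update(stats)
    if outdir is not None:
        if "tsnr" in stats:
            io.write_nifti(outdir / "tsnr.nii.gz", stats["tsnr"].tsnr,
                           series.voxel_size_mm)
        if "glm" in stats:
            io.write_nifti(outdir / "zstat.nii.gz", np.abs(stats["glm"].zstat),
                           series.voxel_size_mm)
        manifest = io.RunManifest(command="run_pipeline", config=_jsonable(cfg),
                                  seeds={"seed": cfg["seed"]},
                                  outputs=sorted(str(p) for p in outdir.iterdir()))
        manifest.write(outdir / "manifest.json")
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
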