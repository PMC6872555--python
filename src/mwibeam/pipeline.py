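"""End-to-end scripted run: simulate -> preprocess -> reconstruct -> metrics.

Mirrors the acquisition-and-postprocessing loop of the physical rig, with the
synthetic-data module standing in for the antenna array and network analyzer.
All randomness flows from the single config-declared seed; rerunning the same
config twice yields byte-identical summaries (timing is logged, never
written into result artifacts).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import io as mwio
from .beamform import das_image, dmas_image
from .correction import CorrectionConfig, icdmas_reconstruct
from .errors import MWIBeamError
from .geometry import (build_cylindrical_array, build_imaging_grid,
                       compute_delay_table, compute_distance_tables)
from .metrics import localization_error, smr, tumor_mask_spheres
from .preprocess import preprocess_dataset
from .simulate import make_phantom, simulate_scatter_dataset

log = logging.getLogger("mwibeam")


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.start = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            elapsed = time.perf_counter() - self.start
            if exc is not None:
                log.error("stage %s: failed after %.2fs: %s", name, elapsed, exc)
                if isinstance(exc, MWIBeamError):
                    exc.args = (f"[stage {name}] {exc.args[0]}",) + exc.args[1:]
            else:
                log.info("stage %s: done in %.2fs", name, elapsed)
            return False

    return _Timer()


def build_scene(cfg: dict):
    """Geometry, grid, phantom and frequency axis from a config mapping."""
    g = cfg["geometry"]
    # YAML readers may hand back numeric-looking strings (e.g. "2.7e9");
    # coerce every numeric field explicitly
    geom = build_cylindrical_array(int(g["n_tx"]), int(g["n_rx"]),
                                   float(g["radius_m"]), int(g["n_phi"]),
                                   float(g["phi_step_deg"]),
                                   float(g["z_plane_m"]))
    gr = cfg["grid"]
    grid = build_imaging_grid(float(gr["extent_m"]), float(gr["spacing_m"]),
                              mode=gr["mode"], z_plane=float(g["z_plane_m"]),
                              array_radius=float(g["radius_m"]))
    ph = cfg["phantom"]
    phantom = make_phantom(ph["preset"], seed=int(cfg["seed"]),
                           noise_sigma=float(ph.get("noise_sigma", 0.0)),
                           array_radius=float(g["radius_m"]),
                           with_interior=bool(ph.get("with_interior", True)))
    fr = cfg["frequencies"]
    freqs = np.linspace(float(fr["start_hz"]), float(fr["stop_hz"]),
                        int(fr["n"]))
    return geom, grid, phantom, freqs


def run_pipeline(cfg: dict, out_dir: str | Path | None = None,
                 write_artifacts: bool = True) -> dict:
    """Run the full chain for one config; returns the machine-readable summary.

    With ``write_artifacts`` the dataset, per-algorithm images (native text +
    PGM raster) and ``summary.json`` land in ``out_dir``.
    """
    out = Path(out_dir) if out_dir is not None else None
    if write_artifacts:
        if out is None:
            raise MWIBeamError("out_dir is required when writing artifacts")
        out.mkdir(parents=True, exist_ok=True)

    with _stage("setup"):
        geom, grid, phantom, freqs = build_scene(cfg)
        truths = np.array([pos for pos, _ in phantom.scatterers], float)

    with _stage("simulate"):
        ds = simulate_scatter_dataset(phantom, geom, freqs)
        if write_artifacts:
            mwio.write_dataset(ds, out / "dataset.csv")

    with _stage("preprocess"):
        pp = cfg["preprocess"]
        td = preprocess_dataset(ds, window=pp["window"],
                                pad_factor=int(pp["pad_factor"]))

    with _stage("delays"):
        delays = compute_delay_table(compute_distance_tables(grid, geom),
                                     eps_b=phantom.background_eps)

    gate = cfg["beamform"].get("gate", "auto")
    if isinstance(gate, (list, tuple)):
        gate = (float(gate[0]), float(gate[1]))
    maps = {}
    icdmas_state = None
    algorithms = cfg.get("algorithms", ["das", "dmas", "icdmas"])
    with _stage("reconstruct"):
        if "das" in algorithms:
            maps["das"] = das_image(td, delays, grid, gate=gate)
        if "dmas" in algorithms or "icdmas" in algorithms:
            maps["dmas"] = dmas_image(td, delays, grid, gate=gate,
                                      pair_mode=cfg["beamform"]["pair_mode"])
        if "icdmas" in algorithms:
            cc = cfg["correction"]
            corr = CorrectionConfig(threshold=float(cc["threshold"]),
                                    max_iter=int(cc["max_iter"]),
                                    path_scale=float(cc["path_scale_m"]))
            maps["icdmas"], icdmas_state = icdmas_reconstruct(
                td, delays, grid, corr, gate=gate)

    with _stage("metrics"):
        summary: dict = {
            "config_hash": mwio.config_hash(cfg),
            "seed": int(cfg["seed"]),
            "phantom": phantom.name,
            "true_positions_m": truths.tolist(),
            "algorithms": {},
        }
        radius = float(cfg["metrics"]["tumor_radius_m"])
        for name in [a for a in ("das", "dmas", "icdmas") if a in maps]:
            m = maps[name]
            entry: dict = {}
            if truths.size:
                mask = tumor_mask_spheres(grid, truths, radius=radius)
                entry["smr_peak_db"] = smr(m, mask, mode="peak").smr_db
                entry["smr_region_mean_db"] = smr(m, mask, mode="region_mean").smr_db
                loc = localization_error(m, truths)
                entry["localization_errors_m"] = [
                    None if np.isnan(e) else float(e) for e in loc.errors]
                entry["n_detections"] = loc.n_detections
            summary["algorithms"][name] = entry
        if icdmas_state is not None:
            summary["icdmas_iterations"] = {
                "n": icdmas_state.n,
                "e_history": icdmas_state.e_history,
                "converged": icdmas_state.converged,
            }

    if write_artifacts:
        with _stage("write"):
            for name, m in maps.items():
                mwio.write_image(m, out / f"image_{name}.txt")
                mwio.write_pgm(m, out / f"image_{name}.pgm")
            (out / "summary.json").write_text(
                json.dumps(summary, sort_keys=True, indent=2) + "\n")
    return summary
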