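"""End-to-end orchestration: world/ingest -> terrain -> segmentation ->
dispersal -> sampling -> fit -> landscape, with file artifacts and a
reproducibility manifest.

Synthetic mode builds the world from a :class:`SimulationConfig`; real mode
ingests pre-projected planar inputs (tracks CSV, DEM and geoid as ESRI ASCII
grids or a constant geoid offset, nests CSV, optional GeoJSON region
polygon).  A single integer seed drives every stochastic stage of a
synthetic run; the manifest records the config hash, seed, library versions,
and per-stage row counts so a rerun can be verified bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dispersal import detect_population, results_to_frame
from .landscape import LandscapeSeries, compute_landscape_series
from .raster import RasterGrid
from .sampling import (
    annotate_and_transform,
    correlation_screen,
    fit_movement_kernels,
    generate_strata,
    steps_from_bouts,
)
from .ssf import build_design, fit_conditional_logit, fit_mixed_conditional_logit, normalized_rmse
from .synthetic import SimulationConfig, read_tracks_csv, simulate_population, write_tracks_csv
from .terrain import TerrainLayers, compute_terrain_layers
from .tracks import (
    compute_flight_altitude,
    compute_ground_speed,
    extract_commuting_bouts,
    fit_behavior_model,
    label_behavior,
    subsample_hourly,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All analysis parameters, with the study defaults."""

    mode: str = "synthetic"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    outdir: str = "flyscape_run"
    seed: int = 1
    # analysis parameters
    n_alternatives: int = 50
    nest_radius_m: float = 7000.0
    min_days: float = 14.0
    radius_overrides: dict = field(default_factory=dict)
    tpi_inner_m: float = 10.0
    tpi_outer_m: float = 200.0
    ridge_sd_threshold: float = 1.0
    target_cell_m: float = 100.0
    flyability_threshold: float = 0.7
    max_week: int = 156
    geoid_constant: float | None = None
    mixed_model: bool = False
    write_maps: bool = False
    landscape_weeks: list | None = None
    # real-mode inputs
    dem_path: str | None = None
    geoid_path: str | None = None
    tracks_path: str | None = None
    nests_path: str | None = None
    region_path: str | None = None

    def to_json(self, path=None) -> str:
        d = dataclasses.asdict(self)
        text = json.dumps(d, indent=2, sort_keys=True, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            d = json.loads(source)
        else:
            d = json.loads(Path(source).read_text())
        sim = d.pop("sim", None)
        cfg = cls(**d)
        if sim is not None:
            cfg.sim = SimulationConfig(**sim)
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class RunResult:
    config: PipelineConfig
    terrain: TerrainLayers
    tracks: pd.DataFrame
    hourly: pd.DataFrame
    strata: pd.DataFrame
    fit: object
    series: LandscapeSeries | None
    manifest: dict


def _load_region(path):
    if path is None:
        return None
    from shapely.geometry import shape

    gj = json.loads(Path(path).read_text())
    if gj.get("type") == "FeatureCollection":
        return shape(gj["features"][0]["geometry"])
    if gj.get("type") == "Feature":
        return shape(gj["geometry"])
    return shape(gj)


def run_pipeline(config: PipelineConfig, write: bool = True) -> RunResult:
    """Execute all stages in order; artifacts and the manifest go to
    ``config.outdir``.  Any stage error halts the run, leaving a partial
    manifest naming the failed stage."""
    out = Path(config.outdir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "flyscape",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "mode": config.mode,
        "versions": {m.__name__: m.__version__ for m in (np, pd)},
        "stages": {},
    }
    t_all = time.time()
    stage = "init"
    try:
        # --- world / ingest ------------------------------------------------
        stage = "world"
        t0 = time.time()
        if config.mode == "synthetic":
            config.sim.seed = int(config.seed)
            world = simulate_population(config.sim)
            dem, terrain = world.dem, world.terrain
            tracks, nests = world.tracks, world.nests
            geoid = config.sim.geoid_offset_m
            if write:
                dem.write_asc(out / "dem.asc")
                nests.to_csv(out / "nests.csv", index=False)
                write_tracks_csv(tracks, out / "tracks.csv")
                (out / "sim_config.json").write_text(config.sim.to_json())
        else:
            for name in ("dem_path", "tracks_path", "nests_path"):
                p = getattr(config, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"real mode requires {name}: {p}")
            dem = RasterGrid.read_asc(config.dem_path)
            tracks = read_tracks_csv(config.tracks_path)
            nests = pd.read_csv(config.nests_path)
            geoid = (
                RasterGrid.read_asc(config.geoid_path)
                if config.geoid_path
                else float(config.geoid_constant or 0.0)
            )
            terrain = None
        manifest["stages"]["world"] = {"n_fixes": len(tracks), "seconds": round(time.time() - t0, 2)}

        # --- terrain -------------------------------------------------------
        stage = "terrain"
        t0 = time.time()
        if terrain is None:
            terrain = compute_terrain_layers(
                dem, config.tpi_inner_m, config.tpi_outer_m,
                config.ridge_sd_threshold, config.target_cell_m,
            )
        if write:
            for name in ("tri", "tpi", "ridge_mask", "dist_ridge", "tri_100", "dist_ridge_100"):
                getattr(terrain, name).write_asc(out / f"{name}.asc")
        manifest["stages"]["terrain"] = {
            "n_ridge_cells": int(np.nansum(terrain.ridge_mask.values)),
            "seconds": round(time.time() - t0, 2),
        }

        # --- segmentation --------------------------------------------------
        stage = "segmentation"
        t0 = time.time()
        tracks = compute_ground_speed(tracks)
        tracks = compute_flight_altitude(tracks, dem, geoid)
        model = fit_behavior_model(tracks)
        tracks = label_behavior(tracks, model)
        hourly = subsample_hourly(tracks)
        hourly, bouts = extract_commuting_bouts(hourly)
        manifest["stages"]["segmentation"] = {
            "n_hourly": len(hourly),
            "n_bouts": len(bouts),
            "speed_means": [round(float(v), 3) for v in model.speed_means],
            "altitude_means": [round(float(v), 3) for v in model.alt_means],
            "seconds": round(time.time() - t0, 2),
        }

        # --- dispersal -----------------------------------------------------
        stage = "dispersal"
        t0 = time.time()
        hourly, disp = detect_population(
            hourly, nests, config.nest_radius_m, config.min_days, config.radius_overrides
        )
        if write:
            results_to_frame(disp).to_csv(out / "dispersal.csv", index=False)
            hourly.to_csv(out / "labeled_hourly.csv", index=False)
        manifest["stages"]["dispersal"] = {
            "n_dispersed": sum(r.dispersed for r in disp.values()),
            "seconds": round(time.time() - t0, 2),
        }

        # --- sampling ------------------------------------------------------
        stage = "sampling"
        t0 = time.time()
        steps = steps_from_bouts(hourly)
        steps = steps[(steps["week"] >= 1) & (steps["week"] <= config.max_week)]
        kernels = fit_movement_kernels(steps)
        rng = np.random.default_rng([int(config.seed), 77])
        strata = generate_strata(steps, kernels, terrain, config.n_alternatives, rng)
        strata, transform = annotate_and_transform(strata, terrain)
        screen = correlation_screen(strata)
        if write:
            strata.to_csv(out / "strata.csv", index=False)
            kernels.to_json(out / "kernels.json")
            transform.to_json(out / "transform.json")
        sizes = strata.groupby("stratum_id").size()
        manifest["stages"]["sampling"] = {
            "n_steps": len(steps),
            "n_strata": int(sizes.size),
            "rows_per_stratum": sorted(sizes.unique().tolist()),
            "correlation_flags": [f"{a}~{b}:{r:.2f}" for a, b, r in screen.flagged],
            "gamma_shape": round(kernels.gamma_shape, 4),
            "gamma_scale": round(kernels.gamma_scale, 2),
            "vm_kappa": round(kernels.vm_kappa, 4),
            "seconds": round(time.time() - t0, 2),
        }

        # --- fit -----------------------------------------------------------
        stage = "fit"
        t0 = time.time()
        design = build_design(strata)
        fit = fit_conditional_logit(design, transform)
        if config.mixed_model:
            fit = fit_mixed_conditional_logit(design, transform)
        nrmse = normalized_rmse(fit, design)
        if write:
            fit.to_json(out / "fit.json")
            fit.coefficients().to_csv(out / "coefficients.csv", index=False)
        manifest["stages"]["fit"] = {
            "method": fit.method,
            "loglik": round(fit.loglik, 4),
            "nrmse": round(nrmse, 6),
            "converged": fit.converged,
            "warnings": fit.warnings,
            "seconds": round(time.time() - t0, 2),
        }

        # --- landscape -----------------------------------------------------
        stage = "landscape"
        t0 = time.time()
        region = _load_region(config.region_path)
        weeks = config.landscape_weeks
        keep = []
        if weeks is None:
            last = int(min(steps["week"].max(), config.max_week))
            weeks = list(range(1, last + 1))
        if config.write_maps:
            keep = [weeks[0], weeks[-1]]
        series = compute_landscape_series(
            fit, terrain, steps, weeks, config.flyability_threshold, region, keep_maps=keep
        )
        if write:
            series.to_frame().to_csv(out / "areas.csv", index=False)
            for w, m in series.maps.items():
                m.write_asc(out / f"flyability_week{w:03d}.asc")
        manifest["stages"]["landscape"] = {
            "weeks": [int(weeks[0]), int(weeks[-1])],
            "area_first_km2": round(float(series.flyable_area_km2[0]), 4),
            "area_last_km2": round(float(series.flyable_area_km2[-1]), 4),
            "fold_change": None
            if not np.isfinite(series.growth.fold_change)
            else round(series.growth.fold_change, 3),
            "growth_flags": series.growth.flags,
            "seconds": round(time.time() - t0, 2),
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        if write:
            out.mkdir(parents=True, exist_ok=True)
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    manifest["total_seconds"] = round(time.time() - t_all, 2)
    if write:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        config.to_json(out / "pipeline_config.json")
    return RunResult(config, terrain, tracks, hourly, strata, fit, series, manifest)
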