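"""Synthetic world: ridged terrain and GPS-like tracks from agents with known
step-selection preferences.

The generator exists so that every downstream stage (segmentation, dispersal
detection, used/available sampling, conditional-logistic fitting, landscape
prediction) can be verified by parameter recovery against a known truth.  It
emulates the structure of raptor bio-logging data:

* a mountainous digital elevation model built from Gaussian-profile ridge
  crests plus smooth low-frequency noise;
* one GPS fix every 20 minutes during a daily activity window, with height
  above ellipsoid = geoid undulation + ground elevation + flight altitude +
  Gaussian altimetry noise;
* a pre-emigration phase of nest-bound wandering followed by permanent
  dispersal;
* alternating commuting / non-commuting behavioral bouts with well-separated
  speed and flight-altitude classes;
* during commuting, hourly movement decisions: candidate endpoints drawn from
  a gamma step-length and von Mises turning-angle kernel, one selected with
  probability proportional to ``exp(beta . z)`` where ``z`` holds z-scored
  terrain ruggedness, ridge distance, step length, and week since emigration.
  Interactions with week implement the ontogenetic attenuation of terrain
  preferences.

Covariates are z-scored with world-level constants frozen at generation time
(raster moments for the terrain layers, kernel moments for step length), so
``true_beta`` has a defined scale that the analysis can target.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import RasterGrid
from .terrain import TerrainLayers, compute_terrain_layers

log = logging.getLogger(__name__)

#: Fixed-effect truth on the z scale, following the qualitative pattern the
#: analysis is designed to detect: preference for rugged terrain near ridge
#: lines and for long steps, with the terrain preferences attenuating and the
#: step-length preference strengthening as the animal ages.
DEFAULT_TRUE_BETA: dict[str, float] = {
    "tri": 0.6,
    "dist_ridge": -0.6,
    "step_length": 0.5,
    "step_length:week": 0.25,
    "tri:week": -0.15,
    "dist_ridge:week": 0.15,
    "tri:step_length": 0.06,
    "dist_ridge:step_length": -0.06,
    "tri:step_length:week": -0.06,
    "dist_ridge:step_length:week": 0.06,
}

SECONDS_PER_HOUR = 3600.0


@dataclass
class SimulationConfig:
    """All knobs of the synthetic world; the defaults are the study conditions.

    The commuting speed class is implied by the movement kernel: fixes are
    interpolated along hourly steps, so fix-to-fix ground speed equals
    step_length / 3600 s.  With ``gamma_shape=36`` and ``gamma_scale_m=1200``
    hourly commuting steps average 43.2 km (sd 7.2 km), i.e. commuting speeds
    ~ N(12, 2) m/s, well separated from the non-commuting N(1, 0.5) m/s class.
    """

    seed: int = 1
    n_individuals: int = 20
    # terrain
    extent_m: float = 250_000.0
    cell_m: float = 100.0
    n_ridges: int = 8
    ridge_amplitude_m: float = 1200.0
    ridge_width_m: float = 1500.0
    noise_amplitude_m: float = 150.0
    noise_scale_m: float = 5000.0
    base_elevation_m: float = 800.0
    #: optional explicit ridge crests [(x0, y0, theta_rad, amplitude_m, width_m)];
    #: randomized when None
    ridges: list | None = None
    # movement / selection
    true_beta: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_BETA))
    gamma_shape: float = 36.0
    gamma_scale_m: float = 1200.0
    vm_kappa: float = 2.0
    n_candidates: int = 300
    # sampling schedule
    fix_interval_min: int = 20
    active_hours_per_day: int = 10
    start_time: str = "2021-03-01T06:00:00"
    # phases
    pre_emigration_days: int = 30
    post_emigration_weeks: int = 156
    nest_radius_m: float = 500.0
    # behavior mixture
    commuting_mean_bout_h: float = 3.0
    noncommuting_mean_bout_h: float = 97.0
    noncommute_speed_mean_ms: float = 1.0
    noncommute_speed_sd_ms: float = 0.5
    commute_altitude_mean_m: float = 300.0
    commute_altitude_sd_m: float = 80.0
    noncommute_altitude_mean_m: float = 20.0
    noncommute_altitude_sd_m: float = 15.0
    altitude_noise_sd_m: float = 5.0
    geoid_offset_m: float = 48.0
    # between-individual heterogeneity (sd of Gaussian slope deviations)
    random_slope_sd_tri: float = 0.0
    random_slope_sd_dist: float = 0.0
    #: world-level z-transform constants, frozen by :func:`simulate_population`
    zscore: dict | None = None

    def __post_init__(self) -> None:
        if self.extent_m <= 0 or self.cell_m <= 0:
            raise ValueError("extent_m and cell_m must be positive")
        if self.gamma_shape <= 0 or self.gamma_scale_m <= 0 or self.vm_kappa <= 0:
            raise ValueError("movement kernel parameters must be positive")
        if 60 % self.fix_interval_min != 0:
            raise ValueError("fix_interval_min must divide 60")
        if not 1 <= self.post_emigration_weeks <= 156:
            raise ValueError("post_emigration_weeks must be in 1..156")
        if self.commute_speed_mean_ms <= self.noncommute_speed_mean_ms:
            raise ValueError("commuting speed class must exceed the non-commuting class")
        if self.commute_altitude_mean_m <= self.noncommute_altitude_mean_m:
            raise ValueError("commuting altitude class must exceed the non-commuting class")

    @property
    def commute_speed_mean_ms(self) -> float:
        return self.gamma_shape * self.gamma_scale_m / SECONDS_PER_HOUR

    @property
    def commute_speed_sd_ms(self) -> float:
        return np.sqrt(self.gamma_shape) * self.gamma_scale_m / SECONDS_PER_HOUR

    def to_json(self, path=None) -> str:
        d = dataclasses.asdict(self)
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SimulationConfig":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        return cls(**d)


def generate_dem(config: SimulationConfig) -> RasterGrid:
    """Elevation = base + Gaussian-profile ridge crests + smooth noise.

    Deterministic given ``config.seed``.  With zero ridge and noise amplitude
    the raster is constant (a flat world).
    """
    n = int(round(config.extent_m / config.cell_m))
    if n < 3:
        raise ValueError("extent too small for the requested cell size")
    rng = np.random.default_rng([int(config.seed), 11])
    if config.ridges is not None:
        ridges = [tuple(r) for r in config.ridges]
    else:
        ridges = []
        for _ in range(config.n_ridges):
            x0, y0 = rng.uniform(0.1, 0.9, size=2) * config.extent_m
            theta = rng.uniform(0, np.pi)
            amp = config.ridge_amplitude_m * rng.uniform(0.7, 1.3)
            ridges.append((x0, y0, theta, amp, config.ridge_width_m))

    xs = (np.arange(n) + 0.5) * config.cell_m
    ys = config.extent_m - (np.arange(n) + 0.5) * config.cell_m
    X, Y = np.meshgrid(xs, ys)
    z = np.full((n, n), float(config.base_elevation_m))
    for x0, y0, theta, amp, width in ridges:
        if amp == 0:
            continue
        # perpendicular distance to the crest line through (x0, y0) at angle theta
        d = (X - x0) * np.sin(theta) - (Y - y0) * np.cos(theta)
        z += amp * np.exp(-0.5 * (d / width) ** 2)

    if config.noise_amplitude_m > 0:
        n_coarse = max(int(np.ceil(config.extent_m / config.noise_scale_m)) + 4, 4)
        coarse = rng.standard_normal((n_coarse, n_coarse))
        zoomed = ndimage.zoom(coarse, n / n_coarse, order=3, mode="nearest")
        zoomed = zoomed[:n, :n]
        if zoomed.shape != (n, n):  # zoom can undershoot by one row/col
            pad_r = n - zoomed.shape[0]
            pad_c = n - zoomed.shape[1]
            zoomed = np.pad(zoomed, ((0, pad_r), (0, pad_c)), mode="edge")
        sd = zoomed.std()
        if sd > 0:
            z += config.noise_amplitude_m * (zoomed - zoomed.mean()) / sd
    return RasterGrid(0.0, config.extent_m, config.cell_m, z)


def make_nests(config: SimulationConfig) -> pd.DataFrame:
    """One nest per individual, placed in the central 60% of the world."""
    rng = np.random.default_rng([int(config.seed), 23])
    xy = rng.uniform(0.2, 0.8, size=(config.n_individuals, 2)) * config.extent_m
    return pd.DataFrame(
        {"individual_id": [f"ind{i:02d}" for i in range(config.n_individuals)],
         "x": xy[:, 0], "y": xy[:, 1]}
    )


def world_zscore_params(config: SimulationConfig, terrain: TerrainLayers) -> dict:
    """World-level z-transform constants: raster moments for the terrain
    covariates, kernel moments for step length, and the 1..W week range."""
    tri = terrain.tri_100.values
    dist = terrain.dist_ridge_100.values
    weeks = np.arange(1, config.post_emigration_weeks + 1, dtype=float)
    mean_len = config.gamma_shape * config.gamma_scale_m
    sd_len = np.sqrt(config.gamma_shape) * config.gamma_scale_m
    return {
        "tri": (float(np.nanmean(tri)), float(np.nanstd(tri))),
        "dist_ridge": (float(np.nanmean(dist)), float(np.nanstd(dist))),
        "step_length": (float(mean_len), float(sd_len)),
        "week": (float(weeks.mean()), float(weeks.std())),
    }


def _selection_eta(beta, zt, zd, zl, zw, slope_dev=(0.0, 0.0)):
    """Linear predictor of the selection kernel on z-scored covariates."""
    bt = beta.get("tri", 0.0) + slope_dev[0]
    bd = beta.get("dist_ridge", 0.0) + slope_dev[1]
    return (
        bt * zt
        + bd * zd
        + beta.get("step_length", 0.0) * zl
        + beta.get("step_length:week", 0.0) * zl * zw
        + beta.get("tri:step_length", 0.0) * zt * zl
        + beta.get("tri:week", 0.0) * zt * zw
        + beta.get("tri:step_length:week", 0.0) * zt * zl * zw
        + beta.get("dist_ridge:step_length", 0.0) * zd * zl
        + beta.get("dist_ridge:week", 0.0) * zd * zw
        + beta.get("dist_ridge:step_length:week", 0.0) * zd * zl * zw
    )


def _behavior_schedule(rng, n_hours, mean_commute_h, mean_noncommute_h, hours_per_day):
    """Alternating non-commuting / commuting bout states, one flag per hour.

    Commuting bouts are truncated at the end of the daily activity window --
    the animal roosts overnight, so a nonstop flight bout cannot span days.
    """
    states = np.empty(n_hours, dtype=bool)
    pos = 0
    commuting = True  # emigration opens with a commuting departure flight
    p_c = min(1.0 / mean_commute_h, 1.0)
    p_n = min(1.0 / mean_noncommute_h, 1.0)
    while pos < n_hours:
        dur = int(rng.geometric(p_c if commuting else p_n))
        if commuting:
            to_day_end = hours_per_day - (pos % hours_per_day)
            dur = min(dur, to_day_end)
        states[pos : pos + dur] = commuting
        pos += dur
        commuting = not commuting
    return states


def simulate_agent(
    config: SimulationConfig,
    dem: RasterGrid,
    terrain: TerrainLayers,
    nest,
    individual_id: str = "ind00",
    rng=None,
    zparams: dict | None = None,
    slope_dev=(0.0, 0.0),
    max_redraws: int = 1000,
):
    """One individual's track: pre-emigration nest attendance, then weekly
    aging agent making step-selection decisions during commuting bouts.

    Returns ``(fixes, steps)``: the 20-min GPS fix table (with ground-truth
    behavior labels) and the hourly commuting decision table.
    """
    if rng is None:
        rng = np.random.default_rng([int(config.seed), 1009])
    if zparams is None:
        zparams = config.zscore or world_zscore_params(config, terrain)
    beta = config.true_beta
    nest = np.asarray(nest, dtype=float)
    t0 = np.datetime64(config.start_time, "s")
    fix_s = config.fix_interval_min * 60
    per_hour = 3600 // fix_s
    margin = 2.0 * dem.cell_size
    lo, hi = margin, config.extent_m - margin

    times: list[np.ndarray] = []
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    commuting_flag: list[np.ndarray] = []

    def emit(t_arr, x_arr, y_arr, is_commuting):
        times.append(t_arr)
        xs.append(np.asarray(x_arr, dtype=float))
        ys.append(np.asarray(y_arr, dtype=float))
        commuting_flag.append(np.full(len(t_arr), is_commuting, dtype=bool))

    day_s = 86_400

    # --- pre-emigration: bounded wander around the nest ------------------
    n_seg_day = config.active_hours_per_day * per_hour
    for day in range(config.pre_emigration_days):
        speeds = np.clip(
            rng.normal(config.noncommute_speed_mean_ms, config.noncommute_speed_sd_ms, n_seg_day),
            0.02,
            None,
        )
        dirs = rng.uniform(-np.pi, np.pi, n_seg_day)
        steps = (speeds * fix_s)[:, None] * np.c_[np.cos(dirs), np.sin(dirs)]
        pos = nest + np.cumsum(steps, axis=0)
        off = pos - nest
        r = np.hypot(off[:, 0], off[:, 1])
        far = r > config.nest_radius_m
        if far.any():  # clamp back inside the natal radius (recursion behavior)
            scale = config.nest_radius_m / r[far]
            pos[far] = nest + off[far] * scale[:, None]
        t_day = t0 + np.timedelta64(day * day_s, "s") + np.arange(1, n_seg_day + 1) * np.timedelta64(fix_s, "s")
        emit(t_day, pos[:, 0], pos[:, 1], False)

    emigration_time = t0 + np.timedelta64(config.pre_emigration_days * day_s, "s")

    # --- post-emigration -------------------------------------------------
    n_hours = config.post_emigration_weeks * 7 * config.active_hours_per_day
    schedule = _behavior_schedule(
        rng, n_hours, config.commuting_mean_bout_h, config.noncommuting_mean_bout_h,
        config.active_hours_per_day,
    )
    (m_tri, s_tri) = zparams["tri"]
    (m_dist, s_dist) = zparams["dist_ridge"]
    (m_len, s_len) = zparams["step_length"]
    (m_wk, s_wk) = zparams["week"]

    pos = nest.copy()
    pos[0] = np.clip(pos[0], lo, hi)
    pos[1] = np.clip(pos[1], lo, hi)
    step_rows: list[tuple] = []

    # flat views for fast covariate lookup inside the decision loop
    tri_grid = terrain.tri_100
    tri_vals = tri_grid.values
    dist_vals = terrain.dist_ridge_100.values
    g_ox, g_oy, g_cell = tri_grid.origin_x, tri_grid.origin_y, tri_grid.cell_size
    g_nr, g_nc = tri_vals.shape

    def hour_start(h: int) -> np.datetime64:
        day, hod = divmod(h, config.active_hours_per_day)
        return emigration_time + np.timedelta64(day * day_s + hod * 3600, "s")

    h = 0
    hours_per_day = config.active_hours_per_day
    while h < n_hours:
        run_end = h
        state = schedule[h]
        while run_end < n_hours and schedule[run_end] == state:
            run_end += 1
        n_run = run_end - h
        if not state:  # non-commuting: slow isotropic wander at fix resolution
            n_seg = n_run * per_hour
            speeds = np.clip(
                rng.normal(config.noncommute_speed_mean_ms, config.noncommute_speed_sd_ms, n_seg),
                0.02,
                None,
            )
            dirs = rng.uniform(-np.pi, np.pi, n_seg)
            steps = (speeds * fix_s)[:, None] * np.c_[np.cos(dirs), np.sin(dirs)]
            walk = pos + np.cumsum(steps, axis=0)
            walk[:, 0] = np.clip(walk[:, 0], lo, hi)
            walk[:, 1] = np.clip(walk[:, 1], lo, hi)
            t_run = np.concatenate(
                [hour_start(hh) + np.arange(1, per_hour + 1) * np.timedelta64(fix_s, "s")
                 for hh in range(h, run_end)]
            )
            emit(t_run, walk[:, 0], walk[:, 1], False)
            pos = walk[-1].copy()
        else:  # commuting bout: one selection decision per hour
            prev_bearing = None  # bout-initial heading is unoriented
            for hh in range(h, run_end):
                ts = hour_start(hh)
                week = int((ts - emigration_time) / np.timedelta64(7 * day_s, "s")) + 1
                zw = (week - m_wk) / s_wk
                M = config.n_candidates
                cx = np.empty(M)
                cy = np.empty(M)
                clen = np.empty(M)
                cbear = np.empty(M)
                ctri = np.empty(M)
                cdist = np.empty(M)
                pending = np.arange(M)
                for _ in range(max_redraws):
                    k = len(pending)
                    lens = rng.gamma(config.gamma_shape, config.gamma_scale_m, k)
                    if prev_bearing is None:
                        bears = rng.uniform(-np.pi, np.pi, k)
                    else:
                        bears = prev_bearing + rng.vonmises(0.0, config.vm_kappa, k)
                    ex = pos[0] + lens * np.cos(bears)
                    ey = pos[1] + lens * np.sin(bears)
                    ok = (ex >= lo) & (ex <= hi) & (ey >= lo) & (ey <= hi)
                    cc = ((ex - g_ox) / g_cell).astype(np.int64)
                    rr = ((g_oy - ey) / g_cell).astype(np.int64)
                    np.clip(cc, 0, g_nc - 1, out=cc)
                    np.clip(rr, 0, g_nr - 1, out=rr)
                    tri_v = tri_vals[rr, cc]
                    dist_v = dist_vals[rr, cc]
                    ok &= np.isfinite(tri_v) & np.isfinite(dist_v)
                    idx = pending[ok]
                    cx[idx] = ex[ok]
                    cy[idx] = ey[ok]
                    clen[idx] = lens[ok]
                    cbear[idx] = bears[ok]
                    ctri[idx] = tri_v[ok]
                    cdist[idx] = dist_v[ok]
                    pending = pending[~ok]
                    if len(pending) == 0:
                        break
                else:
                    raise RuntimeError(
                        f"{individual_id}: could not place candidate endpoints inside the "
                        f"world after {max_redraws} redraw rounds"
                    )
                zt = (ctri - m_tri) / s_tri
                zd = (cdist - m_dist) / s_dist
                zl = (clen - m_len) / s_len
                eta = _selection_eta(beta, zt, zd, zl, zw, slope_dev)
                choice = int(np.argmax(eta + rng.gumbel(size=M)))
                new_pos = np.array([cx[choice], cy[choice]])
                step_rows.append(
                    (individual_id, ts, ts + np.timedelta64(3600, "s"), week,
                     pos[0], pos[1], new_pos[0], new_pos[1],
                     clen[choice], cbear[choice], prev_bearing is None)
                )
                frac = np.arange(1, per_hour + 1) / per_hour
                t_fix = ts + (frac * 3600).astype("timedelta64[s]")
                emit(
                    t_fix,
                    pos[0] + frac * (new_pos[0] - pos[0]),
                    pos[1] + frac * (new_pos[1] - pos[1]),
                    True,
                )
                prev_bearing = float(cbear[choice])
                pos = new_pos
        h = run_end

    t_all = np.concatenate(times)
    x_all = np.concatenate(xs)
    y_all = np.concatenate(ys)
    comm = np.concatenate(commuting_flag)
    ground = np.atleast_1d(dem.sample(x_all, y_all))
    alt = np.where(
        comm,
        rng.normal(config.commute_altitude_mean_m, config.commute_altitude_sd_m, len(t_all)),
        rng.normal(config.noncommute_altitude_mean_m, config.noncommute_altitude_sd_m, len(t_all)),
    )
    alt = np.clip(alt, 0.0, None)
    height = (
        config.geoid_offset_m + ground + alt + rng.normal(0.0, config.altitude_noise_sd_m, len(t_all))
    )
    fixes = pd.DataFrame(
        {
            "individual_id": individual_id,
            "timestamp": pd.to_datetime(t_all),
            "x": x_all,
            "y": y_all,
            "height_ellipsoid": height,
            "true_behavior": np.where(comm, "commuting", "other"),
            "true_flight_altitude": alt,
        }
    )
    steps = pd.DataFrame(
        step_rows,
        columns=["individual_id", "t_start", "t_end", "week", "x0", "y0", "x1", "y1",
                 "step_length", "bearing", "bout_initial"],
    )
    if not steps.empty:
        steps["t_start"] = pd.to_datetime(steps["t_start"])
        steps["t_end"] = pd.to_datetime(steps["t_end"])
    return fixes, steps


@dataclass
class SyntheticWorld:
    """Everything one synthetic run produces, truth included."""

    config: SimulationConfig
    dem: RasterGrid
    terrain: TerrainLayers
    nests: pd.DataFrame
    tracks: pd.DataFrame
    true_steps: pd.DataFrame
    emigration_times: dict
    slope_deviations: pd.DataFrame


def simulate_population(
    config: SimulationConfig,
    dem: RasterGrid | None = None,
    terrain: TerrainLayers | None = None,
) -> SyntheticWorld:
    """Generate the world and all individuals' tracks, freezing the z-score
    constants into ``config.zscore``.  Bit-reproducible given the config."""
    if dem is None:
        dem = generate_dem(config)
    if terrain is None:
        terrain = compute_terrain_layers(dem, target_cell_m=max(100.0, dem.cell_size))
    config.zscore = world_zscore_params(config, terrain)
    nests = make_nests(config)
    rng_dev = np.random.default_rng([int(config.seed), 37])
    dev_tri = rng_dev.normal(0.0, config.random_slope_sd_tri, config.n_individuals)
    dev_dist = rng_dev.normal(0.0, config.random_slope_sd_dist, config.n_individuals)
    all_fixes = []
    all_steps = []
    emig = {}
    for i, row in nests.iterrows():
        rng = np.random.default_rng([int(config.seed), 1000 + int(i)])
        fixes, steps = simulate_agent(
            config, dem, terrain, (row.x, row.y), row.individual_id, rng,
            zparams=config.zscore, slope_dev=(dev_tri[i], dev_dist[i]),
        )
        all_fixes.append(fixes)
        all_steps.append(steps)
        emig[row.individual_id] = np.datetime64(config.start_time, "s") + np.timedelta64(
            config.pre_emigration_days * 86_400, "s"
        )
    tracks = pd.concat(all_fixes, ignore_index=True)
    true_steps = pd.concat(all_steps, ignore_index=True)
    log.info(
        "simulated %d individuals: %d fixes, %d commuting decisions",
        config.n_individuals, len(tracks), len(true_steps),
    )
    return SyntheticWorld(
        config, dem, terrain, nests, tracks, true_steps, emig,
        pd.DataFrame({"individual_id": nests.individual_id, "dev_tri": dev_tri, "dev_dist": dev_dist}),
    )


def write_tracks_csv(tracks: pd.DataFrame, path, include_truth: bool = False) -> None:
    cols = ["individual_id", "timestamp", "x", "y", "height_ellipsoid"]
    if include_truth:
        cols += [c for c in tracks.columns if c.startswith("true_")]
    out = tracks[cols].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def read_tracks_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.tz_localize(None)
    return df.sort_values(["individual_id", "timestamp"], kind="stable").reset_index(drop=True)
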