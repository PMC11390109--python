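"""Track segmentation: flight altitude, ground speed, two-variable EM
clustering into low/high classes, hourly subsampling, and commuting bouts.

Flight altitude above ground is derived per fix as

    altitude_msl    = height_ellipsoid - geoid(x, y)
    flight_altitude = altitude_msl - ground_elevation(x, y)

Behavior is classified at the population level by two independent
two-component 1-D Gaussian EM fits (on ground speed and flight altitude); the
joint low/high corner labels LL/LH/HL/HH replace the bivariate EM-binary
clustering of the original workflow, of which only the high-speed/high-
altitude corner (commuting flight) is consumed downstream.  Commuting bouts
are maximal runs of consecutive hourly HH fixes spanning at least one hour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import RasterGrid

log = logging.getLogger(__name__)


def compute_ground_speed(track: pd.DataFrame) -> pd.DataFrame:
    """Planar fix-to-fix speed (m/s) per individual; the first fix inherits
    the second's value.  Raises on duplicate timestamps."""
    if len(track) < 2:
        raise ValueError("need at least two fixes to compute speed")
    track = track.sort_values(["individual_id", "timestamp"], kind="stable").reset_index(drop=True)
    same = track["individual_id"].eq(track["individual_id"].shift(1)).to_numpy()
    dt = track["timestamp"].diff().dt.total_seconds().to_numpy()
    if np.any(same & ~(dt > 0)):
        bad = track["individual_id"].to_numpy()[same & ~(dt > 0)][0]
        raise ValueError(f"duplicate or non-increasing timestamps for {bad}")
    d = np.hypot(track["x"].diff().to_numpy(), track["y"].diff().to_numpy())
    v = np.where(same, d / dt, np.nan)
    # the first fix of each individual inherits the following speed
    first = ~same
    nxt = np.r_[v[1:], np.nan]
    v[first] = np.where(np.r_[same[1:], False][first], nxt[first], np.nan)
    track["ground_speed"] = v
    return track


def compute_flight_altitude(track: pd.DataFrame, dem: RasterGrid, geoid) -> pd.DataFrame:
    """Attach altitude_msl and flight_altitude; drop (with a warning) fixes
    outside the DEM extent.  ``geoid`` is a RasterGrid or a constant (m)."""
    track = track.copy()
    if isinstance(geoid, RasterGrid):
        undulation = np.atleast_1d(geoid.sample(track["x"].values, track["y"].values))
    else:
        undulation = np.full(len(track), float(geoid))
    ground = np.atleast_1d(dem.sample(track["x"].values, track["y"].values))
    outside = ~np.isfinite(ground)
    if outside.any():
        log.warning("%d fixes outside the DEM extent were excluded", int(outside.sum()))
    track["altitude_msl"] = track["height_ellipsoid"].values - undulation
    track["flight_altitude"] = track["altitude_msl"].values - ground
    return track.loc[~outside].reset_index(drop=True)


def _em_1d_two_gaussian(x: np.ndarray, tol: float = 1e-8, max_iter: int = 500, rng=None):
    """Two-component 1-D Gaussian mixture by EM.

    Initialized at the 25th/75th percentiles; restarts with perturbed
    initialization (max 5) if a component collapses.  Returns
    (weights, means, sds, loglik_trace) with components ordered low/high.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10:
        raise ValueError("too few finite values for EM")
    if rng is None:
        rng = np.random.default_rng(0)
    base_means = np.percentile(x, [25, 75]).astype(float)
    spread = max(x.std(), 1e-6)

    for restart in range(6):
        means = base_means + (rng.normal(0, 0.1 * spread, 2) if restart else 0.0)
        sds = np.full(2, max(spread / 2, 1e-6))
        w = np.array([0.5, 0.5])
        trace = []
        degenerate = False
        prev_ll = -np.inf
        for _ in range(max_iter):
            logpdf = (
                -0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
                - np.log(sds[None, :])
                - 0.5 * np.log(2 * np.pi)
                + np.log(w[None, :])
            )
            m = logpdf.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(logpdf - m).sum(axis=1))
            ll = lse.sum()
            trace.append(ll)
            resp = np.exp(logpdf - lse[:, None])
            nk = resp.sum(axis=0)
            if (nk < 1e-10).any():
                degenerate = True
                break
            w = nk / len(x)
            means = (resp * x[:, None]).sum(axis=0) / nk
            sds = np.sqrt((resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk)
            if (sds < 1e-6).any():
                degenerate = True
                break
            if ll - prev_ll < tol and np.isfinite(prev_ll):
                break
            prev_ll = ll
        if not degenerate:
            order = np.argsort(means)
            return w[order], means[order], sds[order], np.asarray(trace)
    raise RuntimeError("EM degenerated (component collapse) after 5 restarts")


@dataclass
class BehaviorModel:
    """Population-level low/high mixtures for ground speed and flight altitude."""

    speed_weights: np.ndarray
    speed_means: np.ndarray
    speed_sds: np.ndarray
    alt_weights: np.ndarray
    alt_means: np.ndarray
    alt_sds: np.ndarray
    speed_loglik_trace: np.ndarray = field(repr=False, default=None)
    alt_loglik_trace: np.ndarray = field(repr=False, default=None)

    def _posterior_high(self, x, w, means, sds):
        x = np.asarray(x, dtype=float)
        logp = (
            -0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
            - np.log(sds[None, :])
            + np.log(w[None, :])
        )
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        return p[:, 1] / p.sum(axis=1)

    def classify(self, speed, altitude) -> np.ndarray:
        """Joint corner labels; a point sits in the 'high' class only when its
        posterior strictly exceeds 0.5 (exact ties resolve low)."""
        hs = self._posterior_high(speed, self.speed_weights, self.speed_means, self.speed_sds) > 0.5
        ha = self._posterior_high(altitude, self.alt_weights, self.alt_means, self.alt_sds) > 0.5
        lab = np.array(["LL", "LH", "HL", "HH"])
        return lab[(hs.astype(int) << 1) | ha.astype(int)]


def fit_behavior_model(points: pd.DataFrame, tol: float = 1e-8, max_iter: int = 500) -> BehaviorModel:
    """Fit the population-level behavior mixtures on all individuals' fixes.

    Logs a low-separation warning when a variable's component means differ by
    less than twice the larger component SD.
    """
    speed = points["ground_speed"].values
    alt = points["flight_altitude"].values
    ok = np.isfinite(speed) & np.isfinite(alt)
    if ok.sum() < 100:
        raise ValueError("need at least 100 fixes with finite speed and altitude")
    sw, sm, ss, st = _em_1d_two_gaussian(speed[ok], tol, max_iter)
    aw, am, asd, at = _em_1d_two_gaussian(alt[ok], tol, max_iter)
    for name, means, sds in (("ground_speed", sm, ss), ("flight_altitude", am, asd)):
        if means[1] - means[0] < 2 * sds.max():
            log.warning("low separation of the %s mixture (means %.2f / %.2f)", name, *means)
    return BehaviorModel(sw, sm, ss, aw, am, asd, st, at)


def label_behavior(track: pd.DataFrame, model: BehaviorModel) -> pd.DataFrame:
    track = track.copy()
    track["behavior_class"] = model.classify(
        track["ground_speed"].values, track["flight_altitude"].values
    )
    return track


def subsample_hourly(track: pd.DataFrame, tolerance_min: float = 10.0) -> pd.DataFrame:
    """Keep, per individual, the fix nearest each whole hour within the
    tolerance.  Idempotent: hourly data pass through unchanged."""
    parts = []
    for _, g in track.groupby("individual_id", sort=False):
        t = g["timestamp"]
        nearest_hour = t.dt.round("h")
        offset = (t - nearest_hour).abs().dt.total_seconds() / 60.0
        cand = g.assign(_hour=nearest_hour, _off=offset)
        cand = cand[cand["_off"] <= tolerance_min]
        keep = cand.sort_values(["_hour", "_off"], kind="stable").groupby("_hour", sort=True).head(1)
        parts.append(keep.drop(columns=["_hour", "_off"]))
    out = pd.concat(parts, ignore_index=True) if parts else track.iloc[0:0].copy()
    return out.sort_values(["individual_id", "timestamp"], kind="stable").reset_index(drop=True)


@dataclass
class CommutingBout:
    individual_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    n_points: int

    @property
    def duration_h(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0


def extract_commuting_bouts(
    hourly: pd.DataFrame, max_gap_min: float = 75.0, min_points: int = 2
) -> tuple[pd.DataFrame, list[CommutingBout]]:
    """Maximal runs of consecutive hourly HH fixes.

    A run breaks at any non-HH point or any gap above ``max_gap_min`` (the
    bout must be nonstop).  Runs shorter than ``min_points`` hourly fixes
    (i.e. spanning < 1 hr) are discarded.  Returns the hourly frame with a
    ``bout_id`` column (NaN outside bouts) and the bout summaries.
    """
    hourly = hourly.sort_values(["individual_id", "timestamp"], kind="stable").reset_index(drop=True)
    bout_id = np.full(len(hourly), np.nan)
    bouts: list[CommutingBout] = []
    next_id = 0
    for ind, g in hourly.groupby("individual_id", sort=False):
        idx = g.index.to_numpy()
        is_hh = (g["behavior_class"] == "HH").to_numpy()
        gaps = g["timestamp"].diff().dt.total_seconds().to_numpy() / 60.0
        run: list[int] = []
        for k in range(len(idx)):
            joins = is_hh[k] and bool(run) and gaps[k] <= max_gap_min
            if joins:
                run.append(k)
            else:
                if len(run) >= min_points:
                    bout_id[idx[run]] = next_id
                    bouts.append(
                        CommutingBout(
                            ind,
                            g["timestamp"].iloc[run[0]],
                            g["timestamp"].iloc[run[-1]],
                            len(run),
                        )
                    )
                    next_id += 1
                run = [k] if is_hh[k] else []
        if len(run) >= min_points:
            bout_id[idx[run]] = next_id
            bouts.append(
                CommutingBout(ind, g["timestamp"].iloc[run[0]], g["timestamp"].iloc[run[-1]], len(run))
            )
            next_id += 1
    out = hourly.copy()
    out["bout_id"] = bout_id
    log.info("extracted %d commuting bouts (>= %d hourly points)", len(bouts), min_points)
    return out, bouts
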