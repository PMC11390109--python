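"""Stratified used/available step dataset for the step-selection analysis.

Each pair of consecutive hourly fixes inside a commuting bout is one observed
step.  Movement kernels -- a gamma distribution for step lengths and a von
Mises distribution for turning angles -- are fitted to the pooled observed
steps of all individuals.  For every observed step, alternative endpoints are
drawn from those kernels (same start point, previous bearing rotated by a von
Mises turn; bout-initial steps, which have no previous bearing, get uniform
bearings).  The observed step plus its ``n_alternatives`` (50 by default)
form one stratum, the unit of the conditional likelihood.

Covariates (TRI and ridge distance at the end point, step length, week since
emigration) are sampled from the 100 m terrain layers and z-transformed; the
transform constants are kept for prediction-time reuse.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .terrain import TerrainLayers

log = logging.getLogger(__name__)

COVARIATES = ("tri", "dist_ridge", "step_length", "week")


def steps_from_bouts(hourly_with_bouts: pd.DataFrame, entry_gap_min: float = 75.0) -> pd.DataFrame:
    """Observed steps between consecutive hourly fixes of each commuting bout.

    Requires ``bout_id`` and ``week_since_emigration`` columns.  The turning
    angle is counter-clockwise positive, relative to the previous step's
    bearing.  The first step of a bout has no previous in-bout step; its
    reference bearing is taken from the displacement out of the hourly fix
    immediately preceding the bout (the entry into the bout), when that fix
    is within ``entry_gap_min`` minutes.  Truly context-free first steps
    (track starts, long gaps) keep a NaN turning angle.
    """
    full = hourly_with_bouts.sort_values(["individual_id", "timestamp"], kind="stable")
    by_ind = {k: v for k, v in full.groupby("individual_id", sort=False)}
    df = full.dropna(subset=["bout_id"])
    rows = []
    for (ind, bout), g in df.groupby(["individual_id", "bout_id"], sort=False):
        g = g.sort_values("timestamp")
        x = g["x"].to_numpy()
        y = g["y"].to_numpy()
        t = g["timestamp"].to_numpy()
        wk = g["week_since_emigration"].to_numpy()
        dx = np.diff(x)
        dy = np.diff(y)
        lengths = np.hypot(dx, dy)
        bearings = np.arctan2(dy, dx)
        turns = np.full(len(dx), np.nan)
        if len(dx) > 1:
            raw = np.diff(bearings)
            turns[1:] = np.arctan2(np.sin(raw), np.cos(raw))  # wrap to (-pi, pi]
        ind_frame = by_ind[ind]
        before = ind_frame[ind_frame["timestamp"] < g["timestamp"].iloc[0]]
        if len(before):
            prev = before.iloc[-1]
            gap_min = (g["timestamp"].iloc[0] - prev["timestamp"]).total_seconds() / 60.0
            d_entry = np.hypot(x[0] - prev["x"], y[0] - prev["y"])
            if gap_min <= entry_gap_min and d_entry > 0:
                entry_bearing = np.arctan2(y[0] - prev["y"], x[0] - prev["x"])
                raw0 = bearings[0] - entry_bearing
                turns[0] = np.arctan2(np.sin(raw0), np.cos(raw0))
        for i in range(len(dx)):
            rows.append(
                (ind, bout, t[i], t[i + 1], x[i], y[i], x[i + 1], y[i + 1],
                 lengths[i], bearings[i], turns[i], wk[i])
            )
    steps = pd.DataFrame(
        rows,
        columns=["individual_id", "bout_id", "t_start", "t_end", "x0", "y0", "x1", "y1",
                 "step_length", "bearing", "turning_angle", "week"],
    )
    log.info("built %d observed steps from %d bouts", len(steps), df["bout_id"].nunique())
    return steps


@dataclass
class MovementKernels:
    """Population-level movement kernels fitted to the observed steps."""

    gamma_shape: float
    gamma_scale: float
    vm_mu: float
    vm_kappa: float
    n_steps: int

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MovementKernels":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            return cls(**json.loads(source))
        with open(source) as fh:
            return cls(**json.load(fh))


def fit_movement_kernels(steps: pd.DataFrame, kappa_max: float = 500.0) -> MovementKernels:
    """Maximum-likelihood gamma (step lengths) and von Mises (turning angles).

    Lengths of exactly zero cannot enter a gamma likelihood and are excluded;
    more than 50% zero-length steps means the data are effectively stationary
    and an error is raised.  Turning-angle fitting needs at least 30 steps
    with a defined angle (bout-initial steps have none).  A degenerate angle
    concentration is capped at ``kappa_max`` with a warning.
    """
    lengths = steps["step_length"].to_numpy(dtype=float)
    lengths = lengths[np.isfinite(lengths)]
    if len(lengths) == 0:
        raise ValueError("no steps to fit kernels on")
    zero_frac = (lengths == 0).mean()
    if zero_frac > 0.5:
        raise ValueError(f"{zero_frac:.0%} of steps have zero length; data look stationary")
    pos = lengths[lengths > 0]
    shape, _, scale = stats.gamma.fit(pos, floc=0)

    angles = steps["turning_angle"].to_numpy(dtype=float)
    angles = angles[np.isfinite(angles)]
    if len(angles) < 30:
        raise ValueError("need at least 30 steps with defined turning angles")
    kappa, mu, _ = stats.vonmises.fit(angles, fscale=1)
    if kappa > kappa_max:
        log.warning("von Mises kappa %.1f capped at %.1f (near-degenerate angles)", kappa, kappa_max)
        kappa = kappa_max
    mu = float(np.arctan2(np.sin(mu), np.cos(mu)))
    return MovementKernels(float(shape), float(scale), mu, float(kappa), int(len(steps)))


def generate_strata(
    steps: pd.DataFrame,
    kernels: MovementKernels,
    terrain: TerrainLayers,
    n_alternatives: int = 50,
    rng=None,
    max_redraw_rounds: int = 1000,
) -> pd.DataFrame:
    """The stratified dataset: per observed step, ``n_alternatives``
    alternative endpoints sharing the start point, individual, and week.

    Alternative endpoints falling outside the terrain layers (or on nodata)
    are redrawn; a stratum that cannot be filled raises.  Output rows carry
    ``stratum_id``, ``used`` (0/1), endpoint coordinates, step length,
    turning angle, week, and raw covariates tri / dist_ridge.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = len(steps)
    if n == 0:
        raise ValueError("no observed steps")
    S = n_alternatives
    x0 = np.repeat(steps["x0"].to_numpy(dtype=float), S)
    y0 = np.repeat(steps["y0"].to_numpy(dtype=float), S)
    turning = steps["turning_angle"].to_numpy(dtype=float)
    bearing = steps["bearing"].to_numpy(dtype=float)
    prev_bearing = bearing - turning  # bearing of the preceding observed step
    prev = np.repeat(prev_bearing, S)
    has_prev = np.isfinite(prev)

    grid = terrain.tri_100
    lens = np.empty(n * S)
    turns = np.empty(n * S)
    ex = np.empty(n * S)
    ey = np.empty(n * S)
    tri_v = np.empty(n * S)
    dist_v = np.empty(n * S)
    pending = np.arange(n * S)
    for _ in range(max_redraw_rounds):
        k = len(pending)
        L = rng.gamma(kernels.gamma_shape, kernels.gamma_scale, k)
        T = rng.vonmises(kernels.vm_mu, kernels.vm_kappa, k)
        B = np.where(has_prev[pending], prev[pending] + T, rng.uniform(-np.pi, np.pi, k))
        cx = x0[pending] + L * np.cos(B)
        cy = y0[pending] + L * np.sin(B)
        tv = np.atleast_1d(terrain.tri_100.sample(cx, cy))
        dv = np.atleast_1d(terrain.dist_ridge_100.sample(cx, cy))
        ok = grid.contains(cx, cy) & np.isfinite(tv) & np.isfinite(dv)
        idx = pending[ok]
        lens[idx] = L[ok]
        turns[idx] = T[ok]
        ex[idx] = cx[ok]
        ey[idx] = cy[ok]
        tri_v[idx] = tv[ok]
        dist_v[idx] = dv[ok]
        pending = pending[~ok]
        if len(pending) == 0:
            break
    else:
        bad = np.unique(pending // S)
        raise RuntimeError(
            f"could not place alternatives inside the terrain extent for strata {bad[:10]}"
        )
    turns[~has_prev] = np.nan  # no reference bearing for bout-initial steps

    used = steps.reset_index(drop=True)
    used_rows = pd.DataFrame(
        {
            "stratum_id": np.arange(n),
            "individual_id": used["individual_id"],
            "used": 1,
            "x": used["x1"],
            "y": used["y1"],
            "step_length": used["step_length"],
            "turning_angle": used["turning_angle"],
            "week": used["week"],
        }
    )
    alt_rows = pd.DataFrame(
        {
            "stratum_id": np.repeat(np.arange(n), S),
            "individual_id": np.repeat(used["individual_id"].to_numpy(), S),
            "used": 0,
            "x": ex,
            "y": ey,
            "step_length": lens,
            "turning_angle": turns,
            "week": np.repeat(used["week"].to_numpy(dtype=float), S),
        }
    )
    out = pd.concat([used_rows, alt_rows], ignore_index=True)
    out = out.sort_values(["stratum_id", "used"], ascending=[True, False], kind="stable")
    return out.reset_index(drop=True)


@dataclass
class TransformParams:
    """Per-covariate mean/SD of the z-transform, kept for prediction."""

    means: dict
    sds: dict

    def z(self, name: str, values):
        return (np.asarray(values, dtype=float) - self.means[name]) / self.sds[name]

    def to_json(self, path=None) -> str:
        text = json.dumps({"means": self.means, "sds": self.sds}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TransformParams":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        return cls(d["means"], d["sds"])

    @classmethod
    def from_pairs(cls, pairs: dict) -> "TransformParams":
        """Build from ``{name: (mean, sd)}`` (e.g. a generator's frozen constants)."""
        return cls({k: float(v[0]) for k, v in pairs.items()}, {k: float(v[1]) for k, v in pairs.items()})


def annotate_and_transform(
    strata: pd.DataFrame,
    terrain: TerrainLayers,
    params: TransformParams | None = None,
) -> tuple[pd.DataFrame, TransformParams]:
    """Attach raw covariates from the 100 m layers and z-transform them.

    By default the transform constants are the mean/SD over the full
    used+available dataset; pass ``params`` to reuse stored constants (e.g.
    at prediction time, or to express estimates on a generator's scale).
    Strata whose used endpoint lands on nodata are dropped with a warning.
    """
    df = strata.copy()
    df["tri"] = np.atleast_1d(terrain.tri_100.sample(df["x"].values, df["y"].values))
    df["dist_ridge"] = np.atleast_1d(terrain.dist_ridge_100.sample(df["x"].values, df["y"].values))
    bad_used = df.loc[(df["used"] == 1) & ~(np.isfinite(df["tri"]) & np.isfinite(df["dist_ridge"]))]
    if len(bad_used):
        log.warning("dropping %d strata whose used endpoint is on nodata", len(bad_used))
        df = df[~df["stratum_id"].isin(bad_used["stratum_id"])]
    bad_alt = ~(np.isfinite(df["tri"]) & np.isfinite(df["dist_ridge"]))
    if bad_alt.any():
        log.warning("dropping %d alternative rows on nodata", int(bad_alt.sum()))
        df = df[~bad_alt]
    if df.empty:
        raise ValueError("no strata left after nodata filtering")
    if params is None:
        means = {c: float(df[c].mean()) for c in COVARIATES}
        sds = {c: float(df[c].std(ddof=0)) for c in COVARIATES}
        if any(s == 0 for s in sds.values()):
            const = [c for c, s in sds.items() if s == 0]
            raise ValueError(f"constant covariate(s) {const}: z-transform undefined")
        params = TransformParams(means, sds)
    for c in COVARIATES:
        if params.sds[c] <= 0:
            raise ValueError(f"non-positive SD for covariate {c}")
        df[f"{c}_z"] = params.z(c, df[c].values)
    return df.reset_index(drop=True), params


@dataclass
class CorrelationReport:
    matrix: pd.DataFrame
    flagged: list

    def __str__(self) -> str:
        lines = [self.matrix.round(3).to_string()]
        for a, b, r in self.flagged:
            lines.append(f"FLAG |r| >= threshold: {a} ~ {b}: r = {r:.3f}")
        return "\n".join(lines)


def correlation_screen(
    dataset: pd.DataFrame, columns=COVARIATES, threshold: float = 0.5
) -> CorrelationReport:
    """Pearson correlations among predictors; pairs with ``|r|`` at or above
    the threshold are flagged (reported, not fatal)."""
    cols = [c for c in columns if c in dataset.columns]
    if len(cols) < 2:
        raise ValueError("need at least two covariates to screen")
    mat = dataset[cols].corr()
    flagged = [
        (cols[i], cols[j], float(mat.iloc[i, j]))
        for i in range(len(cols))
        for j in range(i + 1, len(cols))
        if abs(mat.iloc[i, j]) >= threshold
    ]
    for a, b, r in flagged:
        log.warning("predictor correlation |r| >= %.2f: %s ~ %s (r = %.3f)", threshold, a, b, r)
    return CorrelationReport(mat, flagged)
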