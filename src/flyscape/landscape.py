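"""Weekly flyability maps and flyable-area dynamics.

Flyability of a cell in a given week is the inverse logit of the fitted
fixed-effects linear predictor evaluated at the cell's terrain covariates,
the week, and that week's mean observed step length (covariates z-scored
with the transform stored on the fit; random effects at the population
mean).  A cell counts as flyable when its flyability strictly exceeds a
threshold (0.7 by default); flyable area is the flyable-cell count times the
cell area.  The weekly area series is summarized by a logistic growth fit
and the first-to-last-week fold change, and spatial hotspots by a 2-D
Gaussian kernel density over flyable cell centers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .raster import RasterGrid
from .ssf import SSFModelFit, term_columns
from .terrain import TerrainLayers

log = logging.getLogger(__name__)

MAX_WEEK = 156


def predict_flyability(
    fit: SSFModelFit,
    terrain: TerrainLayers,
    week: int,
    mean_step_length: float,
    region=None,
) -> RasterGrid:
    """Flyability raster for one week on the 100 m terrain layers.

    ``region`` is an optional shapely polygon; cells whose centers fall
    outside it become nodata.
    """
    if not 1 <= week <= MAX_WEEK:
        raise ValueError(f"week must be in 1..{MAX_WEEK}, got {week}")
    if fit.transform is None:
        raise ValueError("fit carries no transform parameters; cannot z-score the grid")
    tp = fit.transform
    grid = terrain.tri_100
    zt = tp.z("tri", grid.values)
    zd = tp.z("dist_ridge", terrain.dist_ridge_100.values)
    zl = float(tp.z("step_length", mean_step_length))
    zw = float(tp.z("week", week))
    # factored form of the 10-term predictor: cheap on large grids
    b = dict(zip(fit.terms, fit.beta))
    coef_tri = b["tri"] + b["tri:week"] * zw + b["tri:step_length"] * zl + b["tri:step_length:week"] * zl * zw
    coef_dist = (
        b["dist_ridge"] + b["dist_ridge:week"] * zw
        + b["dist_ridge:step_length"] * zl + b["dist_ridge:step_length:week"] * zl * zw
    )
    offset = b["step_length"] * zl + b["step_length:week"] * zl * zw
    eta = coef_tri * zt + coef_dist * zd + offset
    fly = expit(eta)
    fly[~(np.isfinite(zt) & np.isfinite(zd))] = np.nan
    out = grid.like(fly)
    if region is not None:
        from shapely import contains_xy

        X, Y = np.meshgrid(out.centers_x, out.centers_y)
        out.values[~contains_xy(region, X.ravel(), Y.ravel()).reshape(X.shape)] = np.nan
    return out


def flyable_area(flyability: RasterGrid, threshold: float = 0.7) -> float:
    """Area (km^2) of cells with flyability strictly above the threshold.

    Defined on the 100 m analysis grid only (cell area 0.01 km^2)."""
    if abs(flyability.cell_size - 100.0) > 1e-6:
        raise ValueError(f"flyable_area expects 100 m cells, got {flyability.cell_size}")
    v = flyability.values
    n = int(np.count_nonzero(np.isfinite(v) & (v > threshold)))
    return n * 0.01


def mean_step_length_by_week(steps: pd.DataFrame, weeks, min_steps: int = 5) -> dict[int, float]:
    """Mean observed commuting step length per week; weeks with fewer than
    ``min_steps`` observed steps borrow the global mean."""
    overall = float(steps["step_length"].mean())
    by_week = steps.groupby("week")["step_length"].agg(["mean", "size"])
    out = {}
    for w in weeks:
        if w in by_week.index and by_week.loc[w, "size"] >= min_steps:
            out[int(w)] = float(by_week.loc[w, "mean"])
        else:
            out[int(w)] = overall
    return out


@dataclass
class GrowthFit:
    """Logistic growth curve A / (1 + exp(-k (t - t0))) fitted to the
    weekly flyable-area series, plus the first-to-last fold change."""

    asymptote: float | None
    rate: float | None
    midpoint: float | None
    fold_change: float
    fitted: bool
    flags: list = field(default_factory=list)


def area_growth(weeks, areas) -> GrowthFit:
    """Constrained least-squares logistic fit and fold change of the series.

    A zero first-week area leaves the fold change undefined (flagged, not
    fatal); a failed or degenerate fit returns the fold change alone.
    """
    weeks = np.asarray(weeks, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if len(weeks) < 10:
        raise ValueError("need at least 10 weeks of areas")
    flags: list[str] = []
    if areas[0] == 0:
        fold = float("nan")
        flags.append("fold change undefined: first-week area is zero")
    else:
        fold = float(areas[-1] / areas[0])

    def logistic(t, A, k, t0):
        return A / (1.0 + np.exp(-k * (t - t0)))

    try:
        p0 = (max(areas.max(), 1e-9), 0.1, float(np.median(weeks)))
        popt, _ = optimize.curve_fit(
            logistic, weeks, areas, p0=p0,
            bounds=([1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20_000,
        )
        A, k, t0 = (float(v) for v in popt)
        if k < 1e-3:
            flags.append("degenerate growth: rate ~ 0 (constant series?)")
        if t0 > weeks[-1]:
            flags.append(
                "midpoint beyond the observed weeks: growth has not saturated, "
                "asymptote poorly identified"
            )
        return GrowthFit(A, k, t0, fold, True, flags)
    except (RuntimeError, ValueError) as exc:
        flags.append(f"logistic fit failed: {exc}")
        return GrowthFit(None, None, None, fold, False, flags)


@dataclass
class LandscapeSeries:
    """Per-week flyability summaries over the prediction region."""

    weeks: np.ndarray
    mean_step_length: np.ndarray
    flyable_area_km2: np.ndarray
    threshold: float
    growth: GrowthFit
    maps: dict = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"week": self.weeks, "mean_step_length_m": self.mean_step_length,
             "flyable_area_km2": self.flyable_area_km2}
        )


def compute_landscape_series(
    fit: SSFModelFit,
    terrain: TerrainLayers,
    steps: pd.DataFrame,
    weeks=None,
    threshold: float = 0.7,
    region=None,
    keep_maps=(),
) -> LandscapeSeries:
    """Predict weekly flyability maps and the flyable-area series.

    ``keep_maps`` lists weeks whose rasters are retained on the result (all
    others are discarded after their area is measured, to bound memory).
    """
    if weeks is None:
        weeks = np.arange(1, int(steps["week"].max()) + 1)
    weeks = np.asarray(sorted(int(w) for w in weeks))
    msl = mean_step_length_by_week(steps, weeks)
    areas = np.empty(len(weeks))
    maps = {}
    for i, w in enumerate(weeks):
        fly = predict_flyability(fit, terrain, int(w), msl[int(w)], region=region)
        areas[i] = flyable_area(fly, threshold)
        if w in keep_maps:
            maps[int(w)] = fly
    growth = area_growth(weeks, areas) if len(weeks) >= 10 else GrowthFit(
        None, None, None,
        float(areas[-1] / areas[0]) if areas[0] > 0 else float("nan"),
        False, ["series too short for a growth fit"],
    )
    log.info(
        "flyable area: %.2f km^2 (week %d) -> %.2f km^2 (week %d)",
        areas[0], weeks[0], areas[-1], weeks[-1],
    )
    return LandscapeSeries(weeks, np.array([msl[int(w)] for w in weeks]), areas, threshold, growth, maps)


def hotspot_density(
    flyability: RasterGrid,
    threshold: float = 0.7,
    bandwidth=None,
    max_points: int = 5_000,
    max_eval_cells: int = 40_000,
    rng=None,
) -> RasterGrid:
    """2-D Gaussian kernel density of flyable-cell centers, evaluated on the
    grid and normalized to integrate to one over the region.

    ``bandwidth`` follows :class:`scipy.stats.gaussian_kde` semantics
    (default Silverman's rule).  Very large flyable masks are subsampled to
    ``max_points`` centers, and on grids above ``max_eval_cells`` the smooth
    density is evaluated on a strided subgrid and spline-upsampled.
    """
    v = flyability.values
    fly = np.isfinite(v) & (v > threshold)
    if not fly.any():
        raise ValueError("no flyable cells above the threshold")
    r, c = np.nonzero(fly)
    px = flyability.origin_x + (c + 0.5) * flyability.cell_size
    py = flyability.origin_y - (r + 0.5) * flyability.cell_size
    if len(px) > max_points:
        rng = np.random.default_rng(0) if rng is None else rng
        keep = rng.choice(len(px), max_points, replace=False)
        px, py = px[keep], py[keep]
    degenerate = len(px) < 3 or np.std(px) < 1e-12 or np.std(py) < 1e-12
    if degenerate:
        # too few / collinear centers for a covariance-based KDE: isotropic
        # Gaussian kernels of one-cell bandwidth
        X, Y = np.meshgrid(flyability.centers_x, flyability.centers_y)
        h = float(bandwidth) * flyability.cell_size if np.isscalar(bandwidth) and bandwidth else flyability.cell_size
        d2 = (X[..., None] - px) ** 2 + (Y[..., None] - py) ** 2
        dens = np.exp(-0.5 * d2 / h**2).sum(axis=-1) / (2 * np.pi * h**2 * len(px))
    else:
        kde = stats.gaussian_kde(np.vstack([px, py]), bw_method=bandwidth or "silverman")
        nr, nc = v.shape
        stride = int(np.ceil(np.sqrt(nr * nc / max_eval_cells)))
        cx = flyability.centers_x[::stride]
        cy = flyability.centers_y[::stride]
        Xs, Ys = np.meshgrid(cx, cy)
        coarse = kde(np.vstack([Xs.ravel(), Ys.ravel()])).reshape(Xs.shape)
        if stride == 1:
            dens = coarse
        else:
            from scipy import ndimage

            dens = ndimage.zoom(coarse, (nr / coarse.shape[0], nc / coarse.shape[1]), order=1)
            dens = dens[:nr, :nc]
            if dens.shape != v.shape:
                dens = np.pad(dens, ((0, nr - dens.shape[0]), (0, nc - dens.shape[1])), mode="edge")
            dens = np.clip(dens, 0.0, None)
    dens = np.where(np.isfinite(v), dens, np.nan)
    total = np.nansum(dens) * flyability.cell_size**2
    if total > 0:
        dens = dens / total
    return flyability.like(dens)
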