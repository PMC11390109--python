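"""Emigration detection by recursion analysis around the natal nest.

An individual counts as dispersed once it spends more than ``min_days``
consecutive days without any fix inside a ``radius_m`` circle around its
nest (7 km by default; individual overrides, e.g. 30 km for exceptionally
large natal territories, are supported).  The emigration instant is anchored
at the last inside-radius fix preceding the qualifying absence.  Weeks since
emigration are 1-based: week = floor(days since emigration / 7) + 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DAY = np.timedelta64(86_400, "s")

NOT_DISPERSED = "not dispersed"
INSUFFICIENT = "not dispersed (insufficient data)"
DISPERSED = "dispersed"


@dataclass
class DispersalResult:
    individual_id: str
    nest_x: float
    nest_y: float
    radius_m: float
    status: str
    emigration_time: pd.Timestamp | None

    @property
    def dispersed(self) -> bool:
        return self.status == DISPERSED

    def week_of(self, timestamps) -> np.ndarray:
        """Week since emigration (>= 1) for each timestamp; NaN at or before
        the emigration instant or when not dispersed."""
        t = pd.to_datetime(pd.Series(np.asarray(timestamps))).values
        weeks = np.full(len(t), np.nan)
        if self.emigration_time is None:
            return weeks
        dt_days = (t - np.datetime64(self.emigration_time)) / DAY
        post = dt_days > 0
        weeks[post] = np.floor(dt_days[post] / 7.0) + 1
        return weeks


def detect_emigration(
    track: pd.DataFrame,
    nest,
    radius_m: float = 7000.0,
    min_days: float = 14.0,
) -> DispersalResult:
    """Find the first inside-radius fix that is followed by more than
    ``min_days`` without any recursion (any single fix inside counts as a
    recursion).  If the animal never returns after a candidate, the candidate
    qualifies, provided the track extends at least ``min_days`` past it;
    otherwise the decision is flagged as data-limited."""
    ind = str(track["individual_id"].iloc[0]) if len(track) else "?"
    nx, ny = float(nest[0]), float(nest[1])
    t = track["timestamp"].values
    if len(t) == 0:
        return DispersalResult(ind, nx, ny, radius_m, INSUFFICIENT, None)
    if not (np.diff(t) > np.timedelta64(0, "s")).all():
        raise ValueError("track timestamps must be strictly increasing")
    d = np.hypot(track["x"].values - nx, track["y"].values - ny)
    inside_idx = np.flatnonzero(d <= radius_m)
    if len(inside_idx) == 0:
        return DispersalResult(ind, nx, ny, radius_m, NOT_DISPERSED, None)
    gap = np.timedelta64(int(min_days * 86_400), "s")
    t_inside = t[inside_idx]
    t_end = t[-1]
    status = NOT_DISPERSED
    for k, ti in enumerate(t_inside):
        t_next = t_inside[k + 1] if k + 1 < len(t_inside) else None
        if t_next is not None and t_next - ti <= gap:
            continue  # a recursion falls inside the window
        if t_next is None:
            if ti == t_end:
                continue  # no observation after the fix: no departure evidence
            if t_end - ti <= gap:
                status = INSUFFICIENT  # absence started but track ends too early
                break
        return DispersalResult(ind, nx, ny, radius_m, DISPERSED, pd.Timestamp(ti))
    return DispersalResult(ind, nx, ny, radius_m, status, None)


def detect_population(
    tracks: pd.DataFrame,
    nests: pd.DataFrame,
    radius_m: float = 7000.0,
    min_days: float = 14.0,
    radius_overrides: dict | None = None,
) -> tuple[pd.DataFrame, dict[str, DispersalResult]]:
    """Run detection per individual and attach ``week_since_emigration`` to
    the tracks (NaN before emigration; weeks beyond 156 are kept here and
    filtered by the analysis stage)."""
    radius_overrides = radius_overrides or {}
    nest_map = nests.set_index("individual_id")[["x", "y"]]
    results: dict[str, DispersalResult] = {}
    weeks = np.full(len(tracks), np.nan)
    for ind, g in tracks.groupby("individual_id", sort=False):
        if ind not in nest_map.index:
            log.warning("no nest for %s; skipped", ind)
            continue
        r = float(radius_overrides.get(ind, radius_m))
        res = detect_emigration(g, nest_map.loc[ind].values, r, min_days)
        results[ind] = res
        if res.dispersed:
            weeks[g.index.to_numpy()] = res.week_of(g["timestamp"].values)
        else:
            log.info("%s: %s", ind, res.status)
    out = tracks.copy()
    out["week_since_emigration"] = weeks
    return out, results


def results_to_frame(results: dict[str, DispersalResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "individual_id": r.individual_id,
                "nest_x": r.nest_x,
                "nest_y": r.nest_y,
                "radius_m": r.radius_m,
                "status": r.status,
                "emigration_time": r.emigration_time,
            }
            for r in results.values()
        ]
    )
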