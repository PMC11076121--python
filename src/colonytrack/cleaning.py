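"""Fix-level filtering and temporal resampling of UWB tracks.

Three filters are applied to the raw detections, in a fixed order:

1. **boundary** — drop fixes more than ``boundary_buffer_m`` (default 0.5 m,
   the tags' spatial error allowance) outside the fenced colony boundary;
2. **artifact lines** — drop runs of >= ``artifact_min_run`` consecutive
   same-tag fixes sharing a bitwise-identical x coordinate (a receiver
   artifact that draws vertical straight lines);
3. **speed** — greedy forward pass dropping any fix whose apparent speed
   from the last retained fix exceeds ``speed_max_ms`` (default 0.2 m/s,
   faster than a gull chick walks).

The boundary filter runs first so physically impossible positions never
anchor the speed pass.  After cleaning, tracks are resampled to a regular
grid (default 5 min) by taking the nearest raw fix within half an interval
of each grid time — no interpolation, so no fabricated positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking_io import ColonyMap

logger = logging.getLogger("colonytrack")


@dataclass
class CleanConfig:
    """Thresholds for the three fix filters and the resampling grid."""

    boundary_buffer_m: float = 0.5
    speed_max_ms: float = 0.2
    artifact_min_run: int = 3
    resample_interval_s: float = 300.0

    def __post_init__(self) -> None:
        if min(self.boundary_buffer_m, self.speed_max_ms, self.resample_interval_s) <= 0:
            raise ValueError("clean-config thresholds must be strictly positive")
        if self.artifact_min_run <= 0:
            raise ValueError("artifact_min_run must be strictly positive")


def filter_boundary(fixes: pd.DataFrame, colony: ColonyMap, buffer_m: float = 0.5) -> pd.DataFrame:
    """Drop fixes farther than *buffer_m* outside the colony boundary.

    Fixes inside the boundary polygon are always retained; a fix outside is
    retained iff its distance to the polygon is <= *buffer_m*.
    """
    if len(fixes) == 0:
        return fixes.copy()
    import shapely

    boundary = colony.boundary
    pts = shapely.points(fixes[["x", "y"]].to_numpy(dtype=float))
    keep = shapely.covers(boundary, pts)
    outside = ~keep
    if outside.any():
        keep[outside] = shapely.distance(boundary, pts[outside]) <= buffer_m
    removed = fixes.loc[~keep]
    if len(removed):
        for tag, n in removed.groupby("tag_id").size().items():
            logger.info("boundary filter: tag %s, removed %d fixes", tag, n)
    return fixes.loc[keep].reset_index(drop=True)


def filter_artifact_lines(fixes: pd.DataFrame, min_run: int = 3) -> pd.DataFrame:
    """Drop runs of >= *min_run* consecutive same-tag fixes with identical x.

    x values are compared exactly (bitwise), since the artifact repeats the
    receiver's coordinate verbatim.  Removal is iterated to a fixpoint: when
    a removed run separated two shorter runs of the same x, the joined run is
    re-examined, so the filter is idempotent.
    """

    def one_pass(df: pd.DataFrame) -> pd.DataFrame:
        keep = np.ones(len(df), dtype=bool)
        for tag, grp in df.groupby("tag_id", sort=False):
            x = grp["x"].to_numpy()
            new_run = np.ones(len(x), dtype=bool)
            new_run[1:] = x[1:] != x[:-1]
            run_id = np.cumsum(new_run)
            counts = np.bincount(run_id)
            bad = counts[run_id] >= min_run
            keep[grp.index[bad]] = False
            if bad.any():
                logger.info("artifact filter: tag %s, removed %d fixes", tag, int(bad.sum()))
        return df.loc[keep].reset_index(drop=True)

    if len(fixes) == 0:
        return fixes.copy()
    out = one_pass(fixes)
    while True:
        nxt = one_pass(out)
        if len(nxt) == len(out):
            return nxt
        out = nxt


def filter_speed(fixes: pd.DataFrame, vmax: float = 0.2) -> pd.DataFrame:
    """Greedy forward speed filter.

    Per tag, the first fix is retained; each later fix is removed iff its
    distance to the last *retained* fix divided by the elapsed time exceeds
    *vmax*.
    """
    if len(fixes) == 0:
        return fixes.copy()
    keep = np.ones(len(fixes), dtype=bool)
    for tag, grp in fixes.groupby("tag_id", sort=False):
        t = grp["t"].to_numpy(dtype=float)
        x = grp["x"].to_numpy(dtype=float)
        y = grp["y"].to_numpy(dtype=float)
        last = 0
        removed = 0
        for i in range(1, len(t)):
            dt = t[i] - t[last]
            dist = np.hypot(x[i] - x[last], y[i] - y[last])
            if dt <= 0:
                if dist > 0:
                    raise ValueError(
                        f"tag {tag}: zero elapsed time between distinct fixes at t={t[i]}"
                    )
                keep[grp.index[i]] = False
                removed += 1
                continue
            if dist / dt > vmax:
                keep[grp.index[i]] = False
                removed += 1
            else:
                last = i
        if removed:
            logger.info("speed filter: tag %s, removed %d fixes", tag, removed)
    return fixes.loc[keep].reset_index(drop=True)


def clean(fixes: pd.DataFrame, colony: ColonyMap, config: CleanConfig | None = None) -> pd.DataFrame:
    """Apply boundary, artifact-line and speed filters in order."""
    config = config or CleanConfig()
    n0 = len(fixes)
    out = filter_boundary(fixes, colony, config.boundary_buffer_m)
    n1 = len(out)
    out = filter_artifact_lines(out, config.artifact_min_run)
    n2 = len(out)
    out = filter_speed(out, config.speed_max_ms)
    logger.info(
        "clean: %d fixes in; removed %d (boundary), %d (artifact), %d (speed); %d out",
        n0, n0 - n1, n1 - n2, n2 - len(out), len(out),
    )
    return out


def resample(fixes: pd.DataFrame, interval_s: float = 300.0) -> pd.DataFrame:
    """Resample each tag's track to a regular temporal grid.

    Grid times are ``t_first + k * interval_s``.  Each grid time gets the raw
    fix nearest in time within ± half an interval (ties -> the earlier fix);
    grid times with no fix in the window are omitted.  Output timestamps are
    the grid times; coordinates are the chosen raw fixes' (no interpolation).
    """
    if len(fixes) == 0:
        return fixes.copy()
    parts = []
    for tag, grp in fixes.groupby("tag_id", sort=False):
        t = grp["t"].to_numpy(dtype=float)
        k = np.rint((t - t[0]) / interval_s).astype(int)
        grid_t = t[0] + k * interval_s
        err = np.abs(t - grid_t)
        in_window = err <= interval_s / 2
        sub = pd.DataFrame(
            {
                "tag_id": tag,
                "t": grid_t[in_window],
                "x": grp["x"].to_numpy()[in_window],
                "y": grp["y"].to_numpy()[in_window],
                "_err": err[in_window],
            }
        )
        # nearest fix per grid time; stable sort keeps the earlier fix on ties
        sub = sub.sort_values(["t", "_err"], kind="mergesort").drop_duplicates("t", keep="first")
        parts.append(sub.drop(columns="_err"))
    return pd.concat(parts, ignore_index=True)
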