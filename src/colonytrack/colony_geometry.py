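"""Breeding-density and fence covariates derived from colony geometry.

Breeding density is proxied by the mean distance from a nest to its three
nearest neighbouring nests (NN3): pre-natal density uses the chick's origin
nest, post-natal its foster nest.  For the network models a variant
restricted to nests with at least one tracked chick is used, because
associations with untracked chicks cannot be registered.

A nest counts as "near a fence" if it lies strictly closer than a threshold
(default 1.32 m) to any fence segment.  The threshold is the colony-wide
mean step distance plus one SD (0.91 + 0.41 m): one typical move can carry
a chick from the nest to the fence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .tracking_io import ColonyMap


def nn3(focal_xy: tuple[float, float], others: pd.DataFrame, k: int = 3) -> float:
    """Mean distance from *focal_xy* to its *k* nearest nests in *others*.

    *others* must not contain the focal nest itself.  Ties at the k-th
    distance are broken by nest id (index order after a stable sort).
    """
    if len(others) < k:
        raise ValueError(f"nn3 needs >= {k} other nests, got {len(others)}")
    d = np.hypot(
        others["x"].to_numpy(dtype=float) - focal_xy[0],
        others["y"].to_numpy(dtype=float) - focal_xy[1],
    )
    order = np.lexsort((others.index.to_numpy(), d))  # distance, then nest id
    return float(np.mean(d[order[:k]]))


def nn3_table(nests: pd.DataFrame, candidate_ids: pd.Index | None = None) -> pd.Series:
    """NN3 for every nest, optionally restricting neighbours to *candidate_ids*.

    Nests with fewer than three candidate neighbours get NaN (logged).
    """
    import logging

    cand = nests if candidate_ids is None else nests.loc[nests.index.isin(candidate_ids)]
    vals = {}
    short = []
    for nid, row in nests.iterrows():
        others = cand.drop(index=nid, errors="ignore")
        if len(others) < 3:
            vals[nid] = float("nan")
            short.append(nid)
        else:
            vals[nid] = nn3((row["x"], row["y"]), others)
    if short:
        logging.getLogger("colonytrack").warning(
            "nn3_table: %d nest(s) with <3 candidate neighbours set to NaN", len(short)
        )
    return pd.Series(vals, name="nn3_m")


def fence_threshold(mean_step_m: float, sd_step_m: float) -> float:
    """Fence-proximity threshold: mean step distance plus one SD."""
    if mean_step_m <= 0 or sd_step_m < 0:
        raise ValueError("step summary must be positive")
    return mean_step_m + sd_step_m


def near_fence(nest_xy: tuple[float, float], fences, threshold_m: float = 1.32) -> bool:
    """True iff the nest is strictly closer than *threshold_m* to any fence."""
    fences = list(fences)
    if not fences:
        raise ValueError("no fence segments given")
    p = Point(nest_xy)
    return min(seg.distance(p) for seg in fences) < threshold_m


def density_covariates(
    chicks: pd.DataFrame,
    colony: ColonyMap,
    fence_threshold_m: float = 1.32,
    boundary_is_fence: bool = True,
) -> pd.DataFrame:
    """Per-chick density and fence covariates.

    Returns one row per chick with ``nn3_prenatal_m`` (origin nest, all
    nests), ``nn3_postnatal_m`` (foster nest, all nests),
    ``nn3_postnatal_tracked_m`` (foster nest, nests with >= 1 tracked chick)
    and ``near_fence`` (of the foster nest).
    """
    nests = colony.nests
    tracked_nests = pd.Index(chicks["nest_foster"].unique())
    nn3_all = nn3_table(nests)
    nn3_tracked = nn3_table(nests, candidate_ids=tracked_nests)
    fences = list(colony.fences)
    if boundary_is_fence:
        bxy = list(colony.boundary.exterior.coords)
        from shapely.geometry import LineString

        fences = fences + [LineString([bxy[i], bxy[i + 1]]) for i in range(len(bxy) - 1)]
    rows = []
    for _, ch in chicks.iterrows():
        foster = ch["nest_foster"]
        fxy = (nests.loc[foster, "x"], nests.loc[foster, "y"])
        rows.append(
            {
                "chick_id": ch["chick_id"],
                "nn3_prenatal_m": nn3_all[ch["nest_origin"]],
                "nn3_postnatal_m": nn3_all[foster],
                "nn3_postnatal_tracked_m": nn3_tracked[foster],
                "near_fence": near_fence(fxy, fences, fence_threshold_m),
            }
        )
    return pd.DataFrame(rows)
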