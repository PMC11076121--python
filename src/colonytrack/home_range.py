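"""Kernel utilization distribution (KUD) home-range estimation.

The home range of a chick is the area of the smallest region containing a
given probability mass (default 95%) of a bivariate Gaussian kernel density
estimate of its positions, with the classical reference bandwidth

    h_ref = sqrt((var_x + var_y) / 2) * n^(-1/6)

(a single scalar bandwidth on both axes, as in the standard ecology
toolchain).  The density is evaluated on a regular grid covering the points'
bounding box padded by three bandwidths, normalised to unit mass, and the
area is the count of grid cells above the smallest density threshold whose
cells jointly hold at least the requested mass, times the cell area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def href_bandwidth(points: np.ndarray) -> float:
    """Reference bandwidth for a set of planar points (n x 2 array)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 5:
        raise ValueError("reference bandwidth needs >= 5 points")
    pooled = 0.5 * (np.var(pts[:, 0], ddof=1) + np.var(pts[:, 1], ddof=1))
    if pooled <= 0:
        raise ValueError("degenerate dispersion: all points identical")
    return float(np.sqrt(pooled) * n ** (-1.0 / 6.0))


@dataclass
class KudEstimate:
    """A kernel home-range estimate for one chick."""

    chick_id: object
    level: float
    bandwidth_m: float
    area_m2: float
    grid_resolution: int
    grid_extent: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax


def kud_area(
    points: np.ndarray,
    level: float = 0.95,
    h: float | None = None,
    resolution: int = 200,
    pad: float | None = None,
    chick_id: object = None,
) -> KudEstimate:
    """Area of the *level* kernel utilization distribution of *points*.

    Parameters
    ----------
    points
        (n, 2) array of planar positions, n >= 5.
    level
        Probability mass of the utilization region, in (0, 1).
    h
        Kernel bandwidth (metres); defaults to :func:`href_bandwidth`.
    resolution
        Grid cells per axis.
    pad
        Margin added around the bounding box (default ``3 h``).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 5:
        raise ValueError("kud_area needs an (n, 2) array with n >= 5")
    if h is None:
        h = href_bandwidth(pts)
    if pad is None:
        pad = 3.0 * h
    xmin, xmax = pts[:, 0].min() - pad, pts[:, 0].max() + pad
    ymin, ymax = pts[:, 1].min() - pad, pts[:, 1].max() + pad
    gx = np.linspace(xmin, xmax, resolution)
    gy = np.linspace(ymin, ymax, resolution)
    # separable Gaussian kernel: density grid = Kx @ Ky.T over points
    kx = np.exp(-0.5 * ((gx[:, None] - pts[None, :, 0]) / h) ** 2)
    ky = np.exp(-0.5 * ((gy[:, None] - pts[None, :, 1]) / h) ** 2)
    dens = kx @ ky.T  # (nx, ny), unnormalised
    cell = (gx[1] - gx[0]) * (gy[1] - gy[0])
    dens /= dens.sum()  # grid mass -> 1
    flat = np.sort(dens.ravel())[::-1]
    cum = np.cumsum(flat)
    n_cells = int(np.searchsorted(cum, level) + 1)  # smallest count with mass >= level
    area = n_cells * cell
    return KudEstimate(
        chick_id=chick_id,
        level=level,
        bandwidth_m=float(h),
        area_m2=float(area),
        grid_resolution=resolution,
        grid_extent=(float(xmin), float(xmax), float(ymin), float(ymax)),
    )


def home_range_table(
    fixes: pd.DataFrame,
    level: float = 0.95,
    resolution: int = 200,
) -> pd.DataFrame:
    """95% KUD area for every tag in a (resampled) fix table."""
    rows = []
    for tag, grp in fixes.groupby("tag_id", sort=False):
        pts = grp[["x", "y"]].to_numpy(dtype=float)
        if len(pts) < 5:
            rows.append({"chick_id": tag, "area_m2": np.nan, "bandwidth_m": np.nan})
            continue
        est = kud_area(pts, level=level, resolution=resolution, chick_id=tag)
        rows.append({"chick_id": tag, "area_m2": est.area_m2, "bandwidth_m": est.bandwidth_m})
    return pd.DataFrame(rows, columns=["chick_id", "area_m2", "bandwidth_m"])
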