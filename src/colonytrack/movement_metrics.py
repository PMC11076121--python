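"""Movement activity, daily means and repeatability of chick movement.

Movement activity is the mean Euclidean distance between successive
5-min-resampled positions over the whole tracking period.  Consistency of
movement across days is quantified as repeatability (intraclass
correlation): the among-chick variance share from a Gaussian
random-intercept model of the daily square-root mean step,

    sqrt_step_ij = mu + a_i + e_ij,   R = var(a) / (var(a) + var(e)),

fitted by REML, with a percentile confidence interval from a parametric
bootstrap (simulate from the fitted model, refit, repeat).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._lmm import ri_lmm_fit

logger = logging.getLogger("colonytrack")

DAY_S = 86400.0


def step_distances(track: pd.DataFrame, interval_s: float = 300.0) -> np.ndarray:
    """Distances between consecutive resampled fixes exactly one interval apart.

    Pairs spanning an omitted grid time contribute no step.
    """
    if len(track) < 2:
        return np.empty(0)
    t = track["t"].to_numpy(dtype=float)
    dx = np.diff(track["x"].to_numpy(dtype=float))
    dy = np.diff(track["y"].to_numpy(dtype=float))
    adjacent = np.isclose(np.diff(t), interval_s)
    return np.hypot(dx, dy)[adjacent]


def movement_activity(track: pd.DataFrame, interval_s: float = 300.0) -> float:
    """Mean step distance over the whole tracking period (NaN if no steps)."""
    steps = step_distances(track, interval_s)
    if len(steps) == 0:
        logger.warning("movement_activity: no valid steps; flagged missing")
        return float("nan")
    return float(np.mean(steps))


def daily_means(track: pd.DataFrame, interval_s: float = 300.0) -> pd.DataFrame:
    """Per-day mean step and its square root.

    Days are 24 h blocks anchored at the chick's first fix; a step belongs to
    the day of its starting fix.  Days without steps are omitted.
    """
    if len(track) < 2:
        return pd.DataFrame(columns=["day_index", "mean_step_m", "sqrt_mean_step"])
    t = track["t"].to_numpy(dtype=float)
    dx = np.diff(track["x"].to_numpy(dtype=float))
    dy = np.diff(track["y"].to_numpy(dtype=float))
    adjacent = np.isclose(np.diff(t), interval_s)
    day = ((t[:-1] - t[0]) // DAY_S).astype(int)[adjacent] + 1
    steps = np.hypot(dx, dy)[adjacent]
    df = pd.DataFrame({"day_index": day, "step": steps})
    out = df.groupby("day_index")["step"].mean().rename("mean_step_m").reset_index()
    out["sqrt_mean_step"] = np.sqrt(out["mean_step_m"])
    return out


def daily_movement_table(
    fixes: pd.DataFrame, interval_s: float = 300.0
) -> pd.DataFrame:
    """Daily (square-root) mean movement for every tag in a resampled fix table."""
    parts = []
    for tag, grp in fixes.groupby("tag_id", sort=False):
        d = daily_means(grp, interval_s)
        d.insert(0, "chick_id", tag)
        parts.append(d)
    if not parts:
        return pd.DataFrame(columns=["chick_id", "day_index", "mean_step_m", "sqrt_mean_step"])
    return pd.concat(parts, ignore_index=True)


@dataclass
class RepeatabilityEstimate:
    """Variance-ratio repeatability with parametric-bootstrap CI."""

    R: float
    ci_low: float
    ci_high: float
    n_boot: int
    var_among: float
    var_within: float


def repeatability(
    values: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    bootstrap: str = "parametric",
) -> RepeatabilityEstimate:
    """Repeatability of ``sqrt_mean_step`` across days within chicks.

    Parameters
    ----------
    values
        DataFrame with columns ``chick_id`` and ``sqrt_mean_step`` (one row
        per chick-day), e.g. from :func:`daily_movement_table`.
    n_boot
        Bootstrap replicates for the 95% percentile CI (0 disables the CI).
    seed
        Seed or Generator for the bootstrap.
    bootstrap
        ``"parametric"`` (simulate from the fitted random-intercept model,
        the default) or ``"cases"`` (resample chicks with replacement).
    """
    counts = values.groupby("chick_id").size()
    if len(counts) < 2 or (counts >= 2).sum() < 2:
        raise ValueError("repeatability needs >=2 chicks with >=2 days each")
    y = values["sqrt_mean_step"].to_numpy(dtype=float)
    ids = values["chick_id"].to_numpy()
    X = np.ones((len(y), 1))
    fit = ri_lmm_fit(y, X, ids, reml=True)
    R = fit.icc
    if fit.sigma2_group <= 0:
        logger.warning("repeatability: singular fit (no among-chick variance); R = 0")
    if n_boot <= 0:
        return RepeatabilityEstimate(R, float("nan"), float("nan"), 0,
                                     fit.sigma2_group, fit.sigma2_resid)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    codes, inv = np.unique(ids, return_inverse=True)
    boots = np.empty(n_boot)
    mu = float(fit.beta[0])
    sa, se_ = np.sqrt(fit.sigma2_group), np.sqrt(fit.sigma2_resid)
    for b in range(n_boot):
        if bootstrap == "parametric":
            a = rng.normal(0.0, sa, len(codes))
            yb = mu + a[inv] + rng.normal(0.0, se_, len(y))
            gb = inv
        elif bootstrap == "cases":
            pick = rng.integers(0, len(codes), len(codes))
            rows = np.concatenate([np.flatnonzero(inv == c) for c in pick])
            yb = y[rows]
            gb = np.repeat(np.arange(len(codes)), [np.sum(inv == c) for c in pick])
        else:
            raise ValueError(f"unknown bootstrap kind {bootstrap!r}")
        boots[b] = ri_lmm_fit(yb, np.ones((len(yb), 1)), gb, reml=True).icc
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return RepeatabilityEstimate(R, float(lo), float(hi), n_boot,
                                 fit.sigma2_group, fit.sigma2_resid)
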