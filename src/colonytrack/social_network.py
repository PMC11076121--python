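"""Proximity-based social associations and per-chick network metrics.

An association event is two chicks detected simultaneously (timestamps
rounded to the nearest 30 s) less than 0.6 m apart — the tags' spatial
resolution added to a chick's body envelope.  Detection runs on the raw,
unsampled fixes to maximise the chance of catching co-occurrences.

Per-chick metrics follow the usual proxies: *degree* is the number of
distinct non-sibling partners, *strength* the total count of non-sibling
events; sibling events (which dominate by an order of magnitude) are
reported separately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

ASSOCIATION_THRESHOLD_M = 0.6
ROUND_STEP_S = 30.0


def round_times(fixes: pd.DataFrame, step_s: float = ROUND_STEP_S) -> pd.DataFrame:
    """Round timestamps to the nearest multiple of *step_s* (half-way up).

    If several fixes of one tag round to the same value, the fix nearest the
    rounded time is kept (ties -> the earlier fix).
    """
    if len(fixes) == 0:
        return fixes.copy()
    t = fixes["t"].to_numpy(dtype=float)
    rounded = np.floor(t / step_s + 0.5) * step_s  # half-up, also for negatives
    out = fixes.assign(t=rounded, _err=np.abs(t - rounded), _orig=t)
    out = (
        out.sort_values(["tag_id", "t", "_err", "_orig"], kind="mergesort")
        .drop_duplicates(["tag_id", "t"], keep="first")
        .drop(columns=["_err", "_orig"])
        .reset_index(drop=True)
    )
    return out


def detect_associations(
    fixes: pd.DataFrame, threshold_m: float = ASSOCIATION_THRESHOLD_M
) -> pd.DataFrame:
    """All pairwise co-occurrences closer than *threshold_m* (strict).

    Expects time-rounded fixes (one fix per tag and rounded timestamp).
    Returns one row per event: ``chick_a, chick_b, t, distance_m`` with
    ``chick_a < chick_b``.
    """
    events: list[tuple] = []
    for t, grp in fixes.groupby("t", sort=True):
        if len(grp) < 2:
            continue
        ids = grp["tag_id"].to_numpy()
        xy = grp[["x", "y"]].to_numpy(dtype=float)
        tree = cKDTree(xy)
        for i, j in tree.query_pairs(r=threshold_m, output_type="ndarray"):
            d = float(np.hypot(*(xy[i] - xy[j])))
            if d < threshold_m:  # query_pairs is <=; the rule is strict
                a, b = sorted((ids[i], ids[j]))
                events.append((a, b, t, d))
    return pd.DataFrame(events, columns=["chick_a", "chick_b", "t", "distance_m"])


def node_metrics(events: pd.DataFrame, chicks: pd.DataFrame) -> pd.DataFrame:
    """Degree, strength and sibling-event counts per chick.

    Siblings are chicks sharing a foster nest (``sibling_group`` in the
    chick table).  Events referencing a chick absent from *chicks* raise.
    """
    known = set(chicks["chick_id"])
    in_events = set(events["chick_a"]) | set(events["chick_b"]) if len(events) else set()
    unknown = in_events - known
    if unknown:
        raise ValueError(f"association events reference unknown chick(s): {sorted(unknown)}")
    group = chicks.set_index("chick_id")["sibling_group"]
    out = pd.DataFrame(
        {"chick_id": chicks["chick_id"], "degree": 0, "strength": 0, "sibling_events": 0}
    ).set_index("chick_id")
    if len(events):
        sib = (
            events["chick_a"].map(group).to_numpy() == events["chick_b"].map(group).to_numpy()
        )
        sib_counts = pd.concat(
            [events.loc[sib, "chick_a"], events.loc[sib, "chick_b"]]
        ).value_counts()
        out.loc[sib_counts.index, "sibling_events"] = sib_counts
        ns = events.loc[~sib]
        strength = pd.concat([ns["chick_a"], ns["chick_b"]]).value_counts()
        out.loc[strength.index, "strength"] = strength
        pairs = ns[["chick_a", "chick_b"]].drop_duplicates()
        degree = pd.concat([pairs["chick_a"], pairs["chick_b"]]).value_counts()
        out.loc[degree.index, "degree"] = degree
    return out.reset_index()


def edge_list(events: pd.DataFrame) -> pd.DataFrame:
    """Weighted undirected edge list (all events, siblings included)."""
    if len(events) == 0:
        return pd.DataFrame(columns=["chick_a", "chick_b", "weight"])
    return (
        events.groupby(["chick_a", "chick_b"]).size().rename("weight").reset_index()
    )


def to_graph(events: pd.DataFrame, chicks: pd.DataFrame | None = None):
    """networkx Graph of the association network (edge attribute ``weight``)."""
    import networkx as nx

    g = nx.Graph()
    if chicks is not None:
        g.add_nodes_from(chicks["chick_id"])
    for _, row in edge_list(events).iterrows():
        g.add_edge(row["chick_a"], row["chick_b"], weight=int(row["weight"]))
    return g
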