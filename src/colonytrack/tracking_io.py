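"""Reading, validating and writing the pipeline's tabular and geometric inputs.

Three kinds of input are handled:

* **fix tables** — one row per tag detection: ``tag_id, t, x, y``.  ``t`` is
  stored internally as real-valued seconds since tracking start; ISO-8601
  timestamps are accepted on input and converted.  Coordinates are local
  planar metres (the colony spans well under 100 m, so no geodesy).
* **colony geometry** — a JSON file with the colony boundary polygon, fence
  segments, plot polygons and nest positions (with plot membership and
  HD/LD density class).
* **chick metadata** — CSV with one row per chick: identity, origin and
  foster nests, sibling group, sex, age, tarsus, mass and plot.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

logger = logging.getLogger("colonytrack")

FIX_COLUMNS = ["tag_id", "t", "x", "y"]
CHICK_COLUMNS = [
    "chick_id",
    "nest_origin",
    "nest_foster",
    "sibling_group",
    "sex",
    "age_days",
    "tarsus_mm",
    "mass_g",
    "plot_id",
]


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class GeometryError(ValueError):
    """Colony geometry violates an invariant (nest outside plots, overlap...)."""


# ---------------------------------------------------------------------------
# Fix tables
# ---------------------------------------------------------------------------

def validate_fixes(fixes: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalise a fix table.

    Sorts by ``(tag_id, t)`` (stable), collapses duplicate ``(tag_id, t)``
    rows to the first occurrence (logged), and checks coordinates are finite.
    """
    missing = [c for c in FIX_COLUMNS if c not in fixes.columns]
    if missing:
        raise SchemaError(f"fix table missing column(s): {missing}")
    out = fixes.loc[:, FIX_COLUMNS].copy()
    for col in ("t", "x", "y"):
        try:
            out[col] = pd.to_numeric(out[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = out[pd.to_numeric(out[col], errors="coerce").isna()].index
            raise SchemaError(
                f"non-numeric value in column {col!r} at row(s) {list(bad[:5])}"
            ) from exc
    if not np.isfinite(out[["x", "y"]].to_numpy()).all():
        raise SchemaError("non-finite coordinate in fix table")
    out = out.sort_values(["tag_id", "t"], kind="mergesort")
    n_dup = int(out.duplicated(["tag_id", "t"]).sum())
    if n_dup:
        logger.warning("dropping %d duplicate (tag_id, t) fixes (keeping first)", n_dup)
        out = out.drop_duplicates(["tag_id", "t"], keep="first")
    return out.reset_index(drop=True)


def read_fixes(path: str | Path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a fix table from delimited text.

    Parameters
    ----------
    path
        CSV file with columns ``tag_id, t, x, y`` (or names mapped via
        *schema*).
    schema
        Optional mapping from file column names to the canonical names,
        e.g. ``{"id": "tag_id", "timestamp": "t"}``.

    Returns
    -------
    DataFrame sorted by ``(tag_id, t)`` with duplicates collapsed.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in FIX_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if df["t"].dtype == object:
        # ISO-8601 timestamps: convert to seconds since the earliest fix.
        ts = pd.to_datetime(df["t"], format="ISO8601")
        df = df.assign(t=(ts - ts.min()).dt.total_seconds())
    return validate_fixes(df)


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write any tabular result as CSV; lossless round-trip with ``pd.read_csv``."""
    pd.DataFrame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Colony geometry
# ---------------------------------------------------------------------------

@dataclass
class ColonyMap:
    """Colony geometry: boundary, fences, plots and nests.

    Attributes
    ----------
    boundary
        Simple polygon enclosing the colony (metres).
    fences
        Physical fence segments: the plot separators and the outer fence.
    plots
        Label -> polygon; the plots partition the boundary.
    nests
        DataFrame indexed by nest id with columns ``x, y, plot,
        density_class``.
    """

    boundary: Polygon
    fences: list[LineString] = field(default_factory=list)
    plots: dict[str, Polygon] = field(default_factory=dict)
    nests: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["x", "y", "plot", "density_class"])
    )

    def validate(self) -> "ColonyMap":
        if not self.boundary.is_valid or self.boundary.is_empty:
            raise GeometryError("invalid colony boundary polygon")
        labels = list(self.plots)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                inter = self.plots[a].intersection(self.plots[b])
                if inter.area > 1e-9:
                    raise GeometryError(f"plots {a!r} and {b!r} overlap (area {inter.area:.3g})")
        for nest_id, row in self.nests.iterrows():
            p = Point(row["x"], row["y"])
            containing = [lbl for lbl, poly in self.plots.items() if poly.covers(p)]
            if not containing:
                raise GeometryError(f"nest {nest_id!r} lies outside all plots")
            # shared plot edges: covers() may report both; keep the declared one
            if row["plot"] not in containing:
                raise GeometryError(
                    f"nest {nest_id!r} declared in plot {row['plot']!r} "
                    f"but lies in {containing}"
                )
        return self

    def nest_point(self, nest_id: str) -> Point:
        row = self.nests.loc[nest_id]
        return Point(row["x"], row["y"])

    def to_dict(self) -> dict:
        return {
            "boundary": [list(xy) for xy in self.boundary.exterior.coords[:-1]],
            "fences": [[list(seg.coords[0]), list(seg.coords[1])] for seg in self.fences],
            "plots": {
                lbl: [list(xy) for xy in poly.exterior.coords[:-1]]
                for lbl, poly in self.plots.items()
            },
            "nests": {
                str(nid): {
                    "x": float(row["x"]),
                    "y": float(row["y"]),
                    "plot": row["plot"],
                    "density_class": row["density_class"],
                }
                for nid, row in self.nests.iterrows()
            },
        }


def colony_from_dict(obj: dict) -> ColonyMap:
    boundary = Polygon(obj["boundary"])
    fences = [LineString(seg) for seg in obj.get("fences", [])]
    plots = {lbl: Polygon(verts) for lbl, verts in obj.get("plots", {}).items()}
    nests = pd.DataFrame.from_dict(obj.get("nests", {}), orient="index")
    if len(nests) == 0:
        nests = pd.DataFrame(columns=["x", "y", "plot", "density_class"])
    nests.index.name = "nest_id"
    return ColonyMap(boundary=boundary, fences=fences, plots=plots, nests=nests).validate()


def read_colony(path: str | Path) -> ColonyMap:
    """Read and validate colony geometry from its JSON representation."""
    with open(path) as fh:
        obj = json.load(fh)
    return colony_from_dict(obj)


def write_colony(colony: ColonyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(colony.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# Chick metadata
# ---------------------------------------------------------------------------

def validate_chicks(chicks: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CHICK_COLUMNS if c not in chicks.columns]
    if missing:
        raise SchemaError(f"chick table missing column(s): {missing}")
    out = chicks.loc[:, CHICK_COLUMNS].copy()
    if (out["mass_g"] <= 0).any():
        raise SchemaError("non-positive body mass in chick table")
    if ((out["age_days"] < 5) | (out["age_days"] > 60)).any():
        raise SchemaError("implausible age_days in chick table (expected ~15-25 d)")
    # sibling groups are defined by the shared foster nest
    by_group = out.groupby("sibling_group")["nest_foster"].nunique()
    if (by_group > 1).any():
        bad = by_group[by_group > 1].index.tolist()
        raise SchemaError(f"sibling group(s) spanning several foster nests: {bad}")
    return out.reset_index(drop=True)


def read_chicks(path: str | Path) -> pd.DataFrame:
    """Read chick metadata CSV and validate its invariants."""
    return validate_chicks(pd.read_csv(path))
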