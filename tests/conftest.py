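import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Polygon

from colonytrack.tracking_io import ColonyMap


@pytest.fixture
def square_colony() -> ColonyMap:
    """A 30 x 30 m colony split into two 15 m plots, three nests."""
    boundary = Polygon([(0, 0), (30, 0), (30, 30), (0, 30)])
    plots = {
        "P1": Polygon([(0, 0), (15, 0), (15, 30), (0, 30)]),
        "P2": Polygon([(15, 0), (30, 0), (30, 30), (15, 30)]),
    }
    fences = [
        LineString([(15, 0), (15, 30)]),
        LineString([(0, 0), (30, 0)]),
        LineString([(30, 0), (30, 30)]),
        LineString([(30, 30), (0, 30)]),
        LineString([(0, 30), (0, 0)]),
    ]
    nests = pd.DataFrame(
        {
            "x": [5.0, 10.0, 20.0, 25.0, 8.0],
            "y": [5.0, 10.0, 20.0, 8.0, 25.0],
            "plot": ["P1", "P1", "P2", "P2", "P1"],
            "density_class": ["HD", "HD", "LD", "LD", "HD"],
        },
        index=pd.Index(["N1", "N2", "N3", "N4", "N5"], name="nest_id"),
    )
    return ColonyMap(boundary=boundary, fences=fences, plots=plots, nests=nests).validate()


def fix_table(rows):
    """Helper: build a fix table from (tag, t, x, y) tuples."""
    return pd.DataFrame(rows, columns=["tag_id", "t", "x", "y"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)
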