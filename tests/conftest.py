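import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from cellmech.adhesions import MorphometryConfig
from cellmech.tracks import Track


@pytest.fixture
def simple_track():
    """The 3-4-5 right-triangle track (0,0) -> (3,4) -> (3,0)."""
    return Track("t0", t=[0.0, 10.0, 20.0], x=[0.0, 3.0, 3.0], y=[0.0, 4.0, 0.0])


@pytest.fixture
def morpho_config():
    return MorphometryConfig(px_size_um=0.1, background=100.0)


@pytest.fixture
def square_cell():
    """20 x 20 um square cell polygon."""
    return Polygon([(2.0, 2.0), (22.0, 2.0), (22.0, 22.0), (2.0, 22.0)])


def make_track_table(lengths, start_frames=None):
    """Long-format table of straight unit-step tracks with given lengths."""
    start_frames = start_frames or [0] * len(lengths)
    rows = []
    for tid, (n, f0) in enumerate(zip(lengths, start_frames)):
        for k in range(n):
            rows.append(
                {"track_id": tid, "frame": f0 + k, "t_s": (f0 + k) * 10.0,
                 "x_um": 100.0 * tid, "y_um": float(k)}
            )
    return pd.DataFrame(rows)
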