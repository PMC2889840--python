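import numpy as np
import pandas as pd
import pytest

from ppanet.network import CandidateEdgeSet
from ppanet.pool import load_default_pool
from ppanet.timecourse import ExpressionMatrix, StageWindow, canonical_grid_minutes


@pytest.fixture(scope="session")
def pool60():
    """The packaged 60-protein roster."""
    return load_default_pool()


@pytest.fixture
def grid25():
    return canonical_grid_minutes()


@pytest.fixture
def single_window():
    """A 10-point window over a 15-min grid (one stage, nine transitions)."""
    return StageWindow(
        index=1, start_hours=0.0, end_hours=2.25, point_indices=tuple(range(10))
    )


@pytest.fixture
def five_point_window():
    return StageWindow(
        index=1, start_hours=0.0, end_hours=1.0, point_indices=(0, 1, 2, 3, 4)
    )


def edge_set(pairs, source="BIOGRID_LIKE"):
    es = CandidateEdgeSet()
    for a, b in pairs:
        es.add(a, b, source)
    return es


@pytest.fixture
def toy_matrix():
    grid = np.arange(5, dtype=float) * 15.0
    frame = pd.DataFrame(
        np.arange(15, dtype=float).reshape(3, 5),
        index=["A", "B", "C"],
        columns=grid,
    )
    return ExpressionMatrix(frame)
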