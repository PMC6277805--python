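from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from motorgraph.atlas import load_atlas
from motorgraph.connectivity import ConnectivityMatrix, RoiTimeSeriesSet


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()


def cm_from_array(values, labels=None) -> ConnectivityMatrix:
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if labels is None:
        labels = tuple(f"R{i}" for i in range(n))
    return ConnectivityMatrix(values=values, labels=tuple(labels))


def ts_from_array(data, labels=None, subject="sub-01", session="pre") -> RoiTimeSeriesSet:
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = [f"R{i}" for i in range(data.shape[1])]
    return RoiTimeSeriesSet(
        subject_id=subject, session=session, data=pd.DataFrame(data, columns=labels)
    )


@pytest.fixture
def path_graph_abc():
    """A - B - C with unit weights: the canonical hand-checked example."""
    from motorgraph.graph_build import threshold_to_graph

    w = np.array(
        [
            [0.0, 1.0, 0.0],
            [1.0, 0.0, 1.0],
            [0.0, 1.0, 0.0],
        ]
    )
    return threshold_to_graph(cm_from_array(w, ("A", "B", "C")), 2 / 3)


@pytest.fixture
def k4_unit():
    """Complete graph on 4 nodes, unit weights."""
    from motorgraph.graph_build import threshold_to_graph

    w = np.ones((4, 4)) - np.eye(4)
    return threshold_to_graph(cm_from_array(w), 1.0)


@pytest.fixture
def star5():
    """Star: center node 0 connected to 4 leaves, unit weights."""
    from motorgraph.graph_build import threshold_to_graph

    w = np.zeros((5, 5))
    w[0, 1:] = w[1:, 0] = 1.0
    return threshold_to_graph(cm_from_array(w), 0.4)
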