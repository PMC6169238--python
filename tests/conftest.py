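import math

import numpy as np
import pytest

from persnet import PersistenceDiagram, PersistencePair


@pytest.fixture
def unit_square():
    """Pairwise distances of the unit square's four corners."""
    s = math.sqrt(2.0)
    return np.array(
        [
            [0.0, 1.0, s, 1.0],
            [1.0, 0.0, 1.0, s],
            [s, 1.0, 0.0, 1.0],
            [1.0, s, 1.0, 0.0],
        ]
    )


def make_diagram(points, dimension=0):
    """Diagram of finite points [(b, d), ...] in one homology dimension."""
    return PersistenceDiagram.from_pairs(
        [PersistencePair(dimension, float(b), float(d)) for b, d in points]
    )


@pytest.fixture
def diagram_factory():
    return make_diagram
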