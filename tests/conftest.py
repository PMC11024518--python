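import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from scgeom.ph import vr_filtration


@pytest.fixture
def unit_square_filtration():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    return vr_filtration(squareform(pdist(pts)), max_dim=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_cell_graph(rng, n, p=0.4):
    """Connected random graph: a spanning path plus Bernoulli(p) extras."""
    from scgeom.preprocess import CellGraph

    edges = {(i, i + 1) for i in range(n - 1)}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.uniform() < p:
                edges.add((i, j))
    return CellGraph(n_nodes=n, edges=edges)
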