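import networkx as nx
import numpy as np
import pytest

import trajnet as tn


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def helix_pair():
    """Pre-aligned start/end conformations for morph fixtures."""
    return tn.make_transition_pair(30)


@pytest.fixture
def flat_spec():
    """Stationary (start == end) schedule factory for pure-fluctuation runs."""

    def make(n_residues, n_frames, seed=0):
        z = np.zeros((n_residues, 3))
        return tn.MorphScheduleConfig(start=z, end=z, n_frames=n_frames, seed=seed)

    return make


@pytest.fixture
def path3():
    """3-node path graph with unit weights."""
    g = nx.path_graph(3)
    nx.set_edge_attributes(g, 1.0, "weight")
    return g


@pytest.fixture
def star4():
    """Star with centre 0 and three leaves, unit weights."""
    g = nx.star_graph(3)
    nx.set_edge_attributes(g, 1.0, "weight")
    return g


def weighted(edges):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=float(w))
    return g


@pytest.fixture
def diamond():
    """4-node diamond: two parallel 2-edge routes of total weight 2 and 3."""
    return weighted([(0, 1, 1.0), (1, 3, 1.0), (0, 2, 1.0), (2, 3, 2.0)])
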