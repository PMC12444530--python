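import numpy as np
import pytest

from enthalpograph.graphs import Atom, MolecularGraph, from_smiles


def graph_from_edges(n, edges, name=None):
    """Build a bare MolecularGraph (all-carbon labels) from an edge list."""
    return MolecularGraph(
        nodes=[Atom(i, "C", "parsed") for i in range(n)],
        edges={(min(i, j), max(i, j)) for i, j in edges},
        name=name,
    )


def random_connected_graph(rng, n_max=12):
    """Random connected simple graph: a random tree plus random extra edges."""
    n = int(rng.integers(2, n_max + 1))
    edges = set()
    for v in range(1, n):
        u = int(rng.integers(v))
        edges.add((u, v))
    extra = int(rng.integers(0, n))
    for _ in range(extra):
        i, j = rng.choice(n, size=2, replace=False)
        edges.add((min(i, j), max(i, j)))
    return graph_from_edges(n, edges)


@pytest.fixture
def p3():
    """Path graph on 3 nodes: 0 - 1 - 2."""
    return graph_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def k2():
    return graph_from_edges(2, [(0, 1)])


@pytest.fixture
def c6():
    return graph_from_edges(6, [(i, (i + 1) % 6) for i in range(6)])


@pytest.fixture(scope="session")
def benzene():
    return from_smiles("c1ccccc1", name="benzene")


@pytest.fixture(scope="session")
def alkane_features():
    """Descriptor table for n-alkanes C1..C30 (session-cached: it is the
    workhorse fixture of the regression and selection tests)."""
    from enthalpograph.series import SeriesSpec, series_features

    return series_features([SeriesSpec("n-alkane", 1, 30)])
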