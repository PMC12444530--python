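"""Topological indices, centralities and correlation tables."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from conftest import graph_from_edges, random_connected_graph
from enthalpograph.descriptors import (
    centralities,
    distance_matrix,
    estrada_index,
    featurize,
    gutman_index,
    pearson_matrix,
    top_correlated_pairs,
    wiener_index,
)
from enthalpograph.errors import ConstantColumnError, DisconnectedGraphError
from enthalpograph.graphs import adjacency, from_smiles, relabel
from enthalpograph.series import SeriesSpec, series_graphs


def floyd_warshall(a):
    """Independent all-pairs shortest-path oracle."""
    n = a.shape[0]
    d = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def test_distance_matrix_small(k2, p3):
    assert distance_matrix(adjacency(k2))[0, 1] == 1
    d = distance_matrix(adjacency(p3))
    assert sorted(d[np.triu_indices(3, 1)].tolist()) == [1, 1, 2]


def test_distance_matrix_benzene_eccentricity(benzene):
    d = distance_matrix(adjacency(benzene))
    assert d.max() == 5  # brute-force BFS confirms H-to-para-H distance


def test_distance_matrix_disconnected():
    g = graph_from_edges(4, [(0, 1), (2, 3)])
    with pytest.raises(DisconnectedGraphError):
        distance_matrix(adjacency(g))


# ---------------------------------------------------------------------------
# centralities
# ---------------------------------------------------------------------------


def test_centralities_path_graph(p3):
    c = centralities(p3)
    assert c.degree.tolist() == [1, 2, 1]
    assert c.betweenness[1] == 1.0  # single geodesic through the center
    assert c.betweenness[0] == c.betweenness[2] == 0.0
    assert c.closeness[1] == pytest.approx(1 / 2)  # unnormalized reciprocal sum
    assert c.closeness[0] == pytest.approx(1 / 3)


def test_centralities_cycle_eigenvector(c6):
    c = centralities(c6)
    assert c.eigenvector == pytest.approx(np.full(6, 1 / math.sqrt(6)), abs=1e-8)
    assert np.linalg.norm(c.eigenvector) == pytest.approx(1.0)


def test_centrality_invariants_on_molecule():
    g = from_smiles("CCCO")
    c = centralities(g)
    assert c.degree.sum() == 2 * len(g.edges)
    assert np.linalg.norm(c.eigenvector) == pytest.approx(1.0, abs=1e-9)
    assert (c.eigenvector >= 0).all()
    leaves = [a.index for a in g.nodes if g.degree(a.index) == 1]
    assert all(c.betweenness[i] == 0 for i in leaves)


def test_betweenness_matches_brandes_oracle():
    rng = np.random.default_rng(11)
    for _ in range(10):
        g = random_connected_graph(rng, n_max=10)
        c = centralities(g)
        ref = nx.betweenness_centrality(g.to_networkx(), normalized=False)
        assert c.betweenness == pytest.approx(
            [ref[i] for i in range(g.n)], abs=1e-9
        )


# ---------------------------------------------------------------------------
# indices
# ---------------------------------------------------------------------------


def test_estrada_trivial_cases(k2):
    assert estrada_index(np.zeros((1, 1))) == pytest.approx(1.0)
    assert estrada_index(adjacency(k2)) == pytest.approx(2 * math.cosh(1), abs=1e-9)


def test_estrada_benzene(benzene):
    assert estrada_index(adjacency(benzene)) == pytest.approx(28.7159, abs=1e-3)


def test_wiener_examples(k2):
    assert wiener_index(distance_matrix(adjacency(k2))) == 1
    ethane = from_smiles("CC")
    assert wiener_index(distance_matrix(adjacency(ethane))) == 58
    hdb = from_smiles("C" * 17 + "c1ccccc1")
    assert wiener_index(distance_matrix(adjacency(hdb))) == 16494


def test_gutman_examples(k2, p3, benzene):
    assert gutman_index(distance_matrix(adjacency(k2)), k2.degrees()) == 1
    # P3 pairs: (0,1) 1*1*2, (1,2) 1*2*1, (0,2) 2*1*1 -> 6
    assert gutman_index(distance_matrix(adjacency(p3)), p3.degrees()) == 6
    assert (
        gutman_index(distance_matrix(adjacency(benzene)), benzene.degrees()) == 570
    )


def test_estrada_matches_trace_expm_and_networkx():
    rng = np.random.default_rng(5)
    for _ in range(50):
        g = random_connected_graph(rng, n_max=12)
        a = adjacency(g)
        ee = estrada_index(a)
        assert abs(ee - np.trace(scipy.linalg.expm(a.astype(float)))) <= 1e-8 * ee
        assert ee == pytest.approx(nx.estrada_index(g.to_networkx()), rel=1e-8)


def test_wiener_gutman_match_floyd_warshall():
    rng = np.random.default_rng(17)
    for _ in range(50):
        g = random_connected_graph(rng, n_max=12)
        a = adjacency(g)
        d_ref = floyd_warshall(a)
        d = distance_matrix(a)
        assert (d == d_ref.astype(int)).all()
        deg = g.degrees()
        w_ref = int(np.triu(d_ref, 1).sum())
        assert wiener_index(d) == w_ref
        assert wiener_index(d) == int(nx.wiener_index(g.to_networkx()))
        g_ref = sum(
            int(d_ref[i, j]) * deg[i] * deg[j]
            for i in range(g.n)
            for j in range(i + 1, g.n)
        )
        assert gutman_index(d, deg) == g_ref


@pytest.mark.parametrize("n", range(3, 11))
def test_gutman_equals_d_squared_wiener_on_cycles(n):
    g = graph_from_edges(n, [(i, (i + 1) % n) for i in range(n)])
    d = distance_matrix(adjacency(g))
    assert gutman_index(d, g.degrees()) == 4 * wiener_index(d)


@pytest.mark.parametrize("n", [2, 5, 9, 14])
def test_path_wiener_closed_form(n):
    g = graph_from_edges(n, [(i, i + 1) for i in range(n - 1)])
    assert wiener_index(distance_matrix(adjacency(g))) == n * (n**2 - 1) // 6


# ---------------------------------------------------------------------------
# featurize
# ---------------------------------------------------------------------------


def test_featurize_benzene(benzene):
    v = featurize(benzene, aggregation="mean")
    assert v.estrada == pytest.approx(28.7159, abs=1e-3)
    assert v.gutman == 570
    assert v.degree == pytest.approx(2.0)  # 2|E|/n = 24/12
    assert v.aggregation == "mean"


def test_featurize_single_edge():
    v = featurize(from_smiles("[H][H]"))
    assert v.wiener == 1 and v.gutman == 1


def test_featurize_estrada_lower_bound():
    for smiles in ("C", "CCO", "c1ccccc1"):
        g = from_smiles(smiles)
        assert featurize(g).estrada > g.n  # strict: these graphs have edges


def test_featurize_isomorphism_invariance():
    g = from_smiles("CCC=O")
    v = featurize(g).as_array()
    rng = np.random.default_rng(23)
    for _ in range(5):
        h = relabel(g, rng.permutation(g.n))
        assert featurize(h).as_array() == pytest.approx(v, abs=1e-9)


def test_indices_increase_along_alkane_series():
    graphs = series_graphs(SeriesSpec("n-alkane", 1, 30))
    feats = [featurize(g) for g in graphs]
    for a, b in zip(feats, feats[1:]):
        assert b.estrada > a.estrada
        assert b.wiener > a.wiener
        assert b.gutman > a.gutman


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def test_pearson_exact_cases():
    x = np.arange(10.0)
    tbl = pd.DataFrame({"x": x, "double": 2 * x, "neg": -x})
    corr = pearson_matrix(tbl)
    assert corr.loc["x", "double"] == pytest.approx(1.0)
    assert corr.loc["x", "neg"] == pytest.approx(-1.0)
    assert np.allclose(np.diag(corr), 1.0)
    assert ((corr.values >= -1 - 1e-12) & (corr.values <= 1 + 1e-12)).all()


def test_pearson_permutation_null():
    rng = np.random.default_rng(3)
    x = rng.normal(size=1000)
    shuffled = rng.permutation(x)
    corr = pearson_matrix(pd.DataFrame({"x": x, "s": shuffled}))
    assert abs(corr.loc["x", "s"]) < 0.1


def test_pearson_constant_column_error():
    tbl = pd.DataFrame({"x": [1.0, 2.0, 3.0], "const": [5.0, 5.0, 5.0]})
    with pytest.raises(ConstantColumnError, match="const"):
        pearson_matrix(tbl)


def test_top_correlated_pairs_ordering():
    x = np.arange(20.0)
    rng = np.random.default_rng(1)
    tbl = pd.DataFrame({"x": x, "y": 2 * x, "noise": rng.normal(size=20)})
    pairs = top_correlated_pairs(pearson_matrix(tbl), k=1)
    assert set(pairs.iloc[0][["feature_a", "feature_b"]]) == {"x", "y"}
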