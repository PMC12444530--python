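"""Topological indices and centrality statistics of molecular graphs.

All quantities are computed on the explicit-hydrogen graph.  The three
indices used as combustion-enthalpy descriptors are

* Estrada index  EE = Σᵢ exp(λᵢ), λᵢ the adjacency eigenvalues,
* Wiener index   W  = Σ_{i<j} d(i, j)   (shortest-path edge counts),
* Gutman index   Σ_{i<j} d(i, j)·deg(i)·deg(j),

together with four node centralities (degree, betweenness, closeness,
eigenvector) aggregated to molecule level.

Conventions (they matter — popular libraries default to others):
closeness is the unnormalized reciprocal distance sum 1/Σ_t d(v, t), with
no (n−1) factor; betweenness counts unordered source–target pairs with
endpoints excluded and no normalization, so leaves score 0; eigenvector
centrality is the nonnegative principal eigenvector of A with unit
Euclidean norm.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph

from .errors import ConstantColumnError, ConvergenceError, DisconnectedGraphError
from .graphs import MolecularGraph, adjacency

#: Column order of feature tables, fixed across the package.
FEATURE_COLUMNS = (
    "estrada",
    "wiener",
    "gutman",
    "degree",
    "betweenness",
    "closeness",
    "eigenvector",
)

_AGGREGATORS = {"mean": np.mean, "sum": np.sum, "max": np.max}


def distance_matrix(a: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path edge counts (exact BFS), as integers.

    Raises :class:`DisconnectedGraphError` if any pair is unreachable.
    """
    a = np.asarray(a)
    if a.shape == (1, 1):
        return np.zeros((1, 1), dtype=np.int64)
    d = scipy.sparse.csgraph.shortest_path(
        scipy.sparse.csr_matrix(a), method="D", unweighted=True
    )
    if np.isinf(d).any():
        raise DisconnectedGraphError("graph is disconnected: infinite distances")
    return d.astype(np.int64)


def spectrum(a: np.ndarray) -> np.ndarray:
    """Adjacency eigenvalues, descending."""
    lam = scipy.linalg.eigvalsh(np.asarray(a, dtype=float))
    return lam[::-1]


def estrada_index(a_or_spectrum: np.ndarray) -> float:
    """EE = Σ exp(λᵢ) over the adjacency spectrum.

    Accepts either an adjacency matrix (2-D) or a precomputed spectrum (1-D).
    Full symmetric eigendecomposition is used, not a truncated series.
    """
    arr = np.asarray(a_or_spectrum, dtype=float)
    lam = spectrum(arr) if arr.ndim == 2 else arr
    return float(np.sum(np.exp(lam)))


def wiener_index(d: np.ndarray) -> int:
    """W = Σ_{i<j} d(i, j), exact integer."""
    d = np.asarray(d)
    return int(np.triu(d, 1).sum())


def gutman_index(d: np.ndarray, degrees: np.ndarray) -> int:
    """Σ_{i<j} d(i, j)·deg(i)·deg(j), exact integer."""
    d = np.asarray(d)
    deg = np.asarray(degrees, dtype=np.int64)
    weighted = d * np.outer(deg, deg)
    return int(np.triu(weighted, 1).sum())


def _principal_eigenvector(a: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    # Direct symmetric eigendecomposition: on long-chain molecules the
    # spectral gap is tiny and power iteration stalls, so the principal
    # eigenvector is taken from the full (exact) decomposition instead.
    lam, vec = scipy.linalg.eigh(np.asarray(a, dtype=float))
    v = vec[:, -1]
    if not np.isfinite(v).all():
        raise ConvergenceError("eigendecomposition produced non-finite entries")
    if v.sum() < 0:
        v = -v
    # Perron–Frobenius: nonnegative on connected graphs up to rounding
    v = np.where(np.abs(v) < tol, 0.0, v)
    return np.abs(v)


@dataclass
class CentralityTable:
    """Per-node centralities of one molecular graph."""

    degree: np.ndarray
    betweenness: np.ndarray
    closeness: np.ndarray
    eigenvector: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "degree": self.degree,
                "betweenness": self.betweenness,
                "closeness": self.closeness,
                "eigenvector": self.eigenvector,
            }
        )


def centralities(g: MolecularGraph) -> CentralityTable:
    """Degree, betweenness, closeness and eigenvector centrality per node."""
    if g.n < 2:
        raise ValueError("centralities require at least 2 nodes")
    if not g.is_connected():
        raise DisconnectedGraphError("centralities require a connected graph")
    a = adjacency(g)
    deg = a.sum(axis=1)
    gx = g.to_networkx()
    bc_dict = nx.betweenness_centrality(gx, normalized=False)
    bc = np.array([bc_dict[i] for i in range(g.n)])
    d = distance_matrix(a)
    cc = 1.0 / d.sum(axis=1)
    ec = _principal_eigenvector(a)
    return CentralityTable(degree=deg, betweenness=bc, closeness=cc, eigenvector=ec)


@dataclass(frozen=True)
class DescriptorVector:
    """Molecule-level feature vector in the fixed :data:`FEATURE_COLUMNS` order."""

    estrada: float
    wiener: int
    gutman: int
    degree: float
    betweenness: float
    closeness: float
    eigenvector: float
    aggregation: str = "mean"
    name: str | None = None
    smiles: str | None = None

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.estrada,
                self.wiener,
                self.gutman,
                self.degree,
                self.betweenness,
                self.closeness,
                self.eigenvector,
            ],
            dtype=float,
        )


def featurize(g: MolecularGraph, aggregation: str = "mean") -> DescriptorVector:
    """Compute the 7-feature descriptor vector of a hydrogenated graph.

    Node-level centralities are aggregated to molecule level by the given
    rule (``mean`` by default, ``sum`` and ``max`` available); the rule is
    recorded on the vector.
    """
    if aggregation not in _AGGREGATORS:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    agg = _AGGREGATORS[aggregation]
    a = adjacency(g)
    d = distance_matrix(a)
    cent = centralities(g)
    return DescriptorVector(
        estrada=estrada_index(a),
        wiener=wiener_index(d),
        gutman=gutman_index(d, cent.degree),
        degree=float(agg(cent.degree)),
        betweenness=float(agg(cent.betweenness)),
        closeness=float(agg(cent.closeness)),
        eigenvector=float(agg(cent.eigenvector)),
        aggregation=aggregation,
        name=g.name,
        smiles=g.smiles,
    )


def featurize_many(
    graphs: list[MolecularGraph], aggregation: str = "mean"
) -> pd.DataFrame:
    """Feature table (one row per molecule) with name/smiles columns."""
    rows = []
    for g in graphs:
        v = featurize(g, aggregation=aggregation)
        rows.append(
            {"name": v.name, "smiles": v.smiles}
            | {c: getattr(v, c) for c in FEATURE_COLUMNS}
        )
    return pd.DataFrame(rows)


def pearson_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the numeric columns of ``table``.

    Raises :class:`ConstantColumnError` naming the first constant column.
    """
    num = table.select_dtypes(include=[np.number])
    if len(num) < 2:
        raise ValueError("need at least 2 rows")
    for col in num.columns:
        if np.isclose(num[col].std(ddof=0), 0.0):
            raise ConstantColumnError(f"column {col!r} is constant")
    return num.corr(method="pearson")


def top_correlated_pairs(corr: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """The k strongest off-diagonal pairs by |r|, descending."""
    pairs = []
    cols = list(corr.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            pairs.append((cols[i], cols[j], float(corr.iloc[i, j])))
    pairs.sort(key=lambda t: abs(t[2]), reverse=True)
    return pd.DataFrame(pairs[:k], columns=["feature_a", "feature_b", "r"])
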