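"""SMILES → explicit-hydrogen molecular graphs and adjacency matrices.

A molecule is modelled as an unweighted, undirected simple graph G = (V, E):
one node per atom (hydrogens included), one edge per bond regardless of bond
order or aromaticity.  This is the convention under which the spectral and
distance indices in :mod:`enthalpograph.descriptors` are defined.

Node ordering is fixed for reproducibility: heavy atoms in SMILES token
order, then hydrogens appended in owner-atom order, so adjacency matrices
are bit-for-bit reproducible for a given input string.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from rdkit import Chem, RDLogger

from .errors import (
    SmilesParseError,
    UnsupportedElementError,
    UnsupportedInputError,
    ValenceError,
)

RDLogger.DisableLog("rdApp.*")

#: Organic-subset elements accepted by :func:`parse_smiles` (plus explicit H).
SUPPORTED_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}
)


@dataclass(frozen=True)
class Atom:
    """A node of the molecular graph."""

    index: int
    element: str
    origin: str  # "parsed" | "added-hydrogen"


@dataclass
class MolecularGraph:
    """Labelled undirected simple graph of atoms and bonds.

    ``edges`` holds unordered index pairs stored as sorted tuples.  The
    hydrogen-suppressed graph produced by :func:`parse_smiles` additionally
    carries per-heavy-atom implicit hydrogen counts so that
    :func:`hydrogenate` can expand it without re-parsing.
    """

    nodes: list[Atom]
    edges: set[tuple[int, int]]
    name: str | None = None
    smiles: str | None = None
    _implicit_h: list[int] = field(default_factory=list, repr=False)

    @property
    def n(self) -> int:
        return len(self.nodes)

    def degree(self, i: int) -> int:
        return sum(1 for e in self.edges if i in e)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(a.index for a in self.nodes)
        g.add_edges_from(self.edges)
        return g

    def is_connected(self) -> bool:
        if self.n == 0:
            return False
        return nx.is_connected(self.to_networkx())


def _edge(i: int, j: int) -> tuple[int, int]:
    if i == j:
        raise ValueError(f"self-loop on node {i}")
    return (i, j) if i < j else (j, i)


def parse_smiles(text: str, name: str | None = None) -> MolecularGraph:
    """Parse a single-fragment SMILES into a hydrogen-suppressed graph.

    One node per heavy atom in input order, one edge per bond (ring closures
    resolved).  Bond orders and aromaticity influence only the implicit
    hydrogen counts recorded for :func:`hydrogenate`; they never weight edges.

    Raises
    ------
    SmilesParseError
        Malformed SMILES.
    UnsupportedInputError
        Multi-fragment input (dot-disconnected).
    UnsupportedElementError
        Element outside the supported organic subset.
    ValenceError
        Chemically impossible valence (negative implicit hydrogen count).
    """
    if not isinstance(text, str) or not text.strip():
        raise SmilesParseError("empty SMILES string")
    text = text.strip()
    mol = Chem.MolFromSmiles(text, sanitize=False)
    if mol is None:
        raise SmilesParseError(f"malformed SMILES: {text!r}")
    try:
        Chem.SanitizeMol(mol)
    except Chem.AtomValenceException as exc:  # pragma: no cover - message path
        raise ValenceError(f"impossible valence in {text!r}: {exc}") from exc
    except Exception as exc:
        raise SmilesParseError(f"malformed SMILES: {text!r}: {exc}") from exc
    if len(Chem.GetMolFrags(mol)) > 1:
        raise UnsupportedInputError(
            f"multi-fragment SMILES not supported: {text!r}"
        )
    atoms: list[Atom] = []
    implicit_h: list[int] = []
    for atom in mol.GetAtoms():
        symbol = atom.GetSymbol()
        if symbol not in SUPPORTED_ELEMENTS:
            raise UnsupportedElementError(
                f"unsupported element {symbol!r} in {text!r}"
            )
        atoms.append(Atom(index=atom.GetIdx(), element=symbol, origin="parsed"))
        nh = atom.GetTotalNumHs()
        if nh < 0:  # defensive; RDKit sanitization should have caught this
            raise ValenceError(
                f"negative hydrogen count on atom {atom.GetIdx()} of {text!r}"
            )
        implicit_h.append(nh)
    edges = {
        _edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
    }
    return MolecularGraph(
        nodes=atoms, edges=edges, name=name, smiles=text, _implicit_h=implicit_h
    )


def hydrogenate(g: MolecularGraph) -> MolecularGraph:
    """Expand a hydrogen-suppressed graph to the explicit-hydrogen graph.

    Each heavy atom gains as many degree-1 hydrogen nodes as its implicit
    hydrogen count (standard valences: B 3, C 4, N 3, O 2, P 3, S 2,
    halogens 1; bracket atoms keep their stated hcount; aromatic atoms use
    aromatic-system accounting).  Hydrogens are appended after the heavy
    atoms, in owner-atom order.
    """
    if len(g._implicit_h) != g.n:
        raise ValueError("graph lacks implicit hydrogen counts; re-parse it")
    atoms = list(g.nodes)
    edges = set(g.edges)
    next_idx = g.n
    for heavy_idx, nh in enumerate(g._implicit_h):
        for _ in range(nh):
            atoms.append(Atom(index=next_idx, element="H", origin="added-hydrogen"))
            edges.add(_edge(heavy_idx, next_idx))
            next_idx += 1
    out = MolecularGraph(
        nodes=atoms, edges=edges, name=g.name, smiles=g.smiles, _implicit_h=[]
    )
    return out


def from_smiles(text: str, name: str | None = None) -> MolecularGraph:
    """Convenience: parse and hydrogenate in one step."""
    return hydrogenate(parse_smiles(text, name=name))


def adjacency(g: MolecularGraph) -> np.ndarray:
    """Binary symmetric adjacency matrix with zero diagonal (A[i,j] = 1 iff
    {i, j} is an edge)."""
    a = np.zeros((g.n, g.n), dtype=np.int64)
    for i, j in g.edges:
        a[i, j] = 1
        a[j, i] = 1
    return a


def relabel(g: MolecularGraph, perm: np.ndarray) -> MolecularGraph:
    """Apply a node permutation (new index of node i is ``perm[i]``).

    Used by the isomorphism-invariance tests; adjacency transforms as
    P·A·Pᵀ for the corresponding permutation matrix P.
    """
    perm = np.asarray(perm)
    nodes = [None] * g.n
    for a in g.nodes:
        nodes[perm[a.index]] = replace(a, index=int(perm[a.index]))
    edges = {_edge(int(perm[i]), int(perm[j])) for i, j in g.edges}
    return MolecularGraph(nodes=nodes, edges=edges, name=g.name, smiles=g.smiles)
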