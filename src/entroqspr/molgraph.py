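"""Hydrogen-suppressed molecular graphs and degree-pair edge partitions.

A molecule is modelled as a simple undirected graph on its heavy atoms:
atoms are vertices, bonds are edges, hydrogens are omitted.  Bond order,
aromaticity, formal charge and metal coordination are deliberately
ignored — every bond contributes exactly one edge and every degree is
taken in this skeleton graph.  All degree-based descriptors downstream
depend on the graph only through its *edge partition*: the multiset of
unordered endpoint-degree pairs (i, j) with their multiplicities n_ij.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "MolecularGraph",
    "EdgePartition",
    "read_edge_list",
    "read_smiles",
    "edge_partition",
    "partition_from_counts",
    "read_partition_csv",
]


class GraphInputError(ValueError):
    """Raised when an input document does not describe a valid molecular graph."""


@dataclass(frozen=True)
class MolecularGraph:
    """A simple, hydrogen-suppressed molecular graph.

    Vertices are opaque string identifiers; no element information is
    stored because every descriptor in this package is a function of
    vertex degrees only.  Isolated atoms (degree 0) are rejected: they
    carry no edge and therefore no descriptor information.
    """

    graph: nx.Graph
    name: str | None = None

    def __post_init__(self) -> None:
        g = self.graph
        if g.number_of_nodes() == 0 or g.number_of_edges() == 0:
            raise GraphInputError("graph must have at least one edge")
        loops = list(nx.selfloop_edges(g))
        if loops:
            raise GraphInputError(f"self-loops are not allowed: {loops[0]}")
        isolated = [v for v, d in g.degree() if d == 0]
        if isolated:
            raise GraphInputError(f"isolated vertices are not allowed: {isolated}")
        if not nx.is_connected(g):
            warnings.warn(
                f"molecular graph {self.name or ''} is disconnected; "
                "descriptors are edge-local and remain well defined",
                stacklevel=2,
            )

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, v: str) -> int:
        return self.graph.degree(v)

    def edges(self) -> Iterable[tuple[str, str]]:
        return self.graph.edges()


@dataclass(frozen=True)
class EdgePartition:
    """Counts n_ij of edges whose endpoint degrees are (i, j), i <= j.

    This is the sole input every topological and entropy index needs;
    two graphs with the same partition are indistinguishable to them.
    """

    cells: Mapping[tuple[int, int], int]
    name: str | None = None
    cells_frozen: tuple = field(init=False, repr=False, compare=False, default=())

    def __post_init__(self) -> None:
        norm: dict[tuple[int, int], int] = {}
        for (i, j), n in self.cells.items():
            if not (isinstance(i, int) and isinstance(j, int) and i >= 1 and j >= 1):
                raise GraphInputError(f"degrees must be integers >= 1, got ({i}, {j})")
            if not (isinstance(n, int) and n >= 1):
                raise GraphInputError(f"cell count must be a positive integer, got {n}")
            key = (i, j) if i <= j else (j, i)
            norm[key] = norm.get(key, 0) + n
        object.__setattr__(self, "cells", dict(sorted(norm.items())))
        object.__setattr__(self, "cells_frozen", tuple(sorted(norm.items())))

    @property
    def m(self) -> int:
        """Total number of edges, sum of all cell counts."""
        return sum(self.cells.values())

    def items(self):
        return self.cells.items()


def read_edge_list(text: str, name: str | None = None) -> MolecularGraph:
    """Parse a plain-text edge list into a :class:`MolecularGraph`.

    One edge per non-empty, non-comment line, written as two
    whitespace-separated vertex tokens.  Lines starting with ``#`` are
    comments.  Duplicate edges and self-loops are rejected with the
    offending line number.
    """
    g = nx.Graph()
    any_line = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise GraphInputError(
                f"line {lineno}: expected two vertex tokens, got {len(tokens)}"
            )
        u, v = tokens
        if u == v:
            raise GraphInputError(f"line {lineno}: self-loop {u!r}")
        if g.has_edge(u, v):
            raise GraphInputError(f"line {lineno}: duplicate edge {u!r} {v!r}")
        g.add_edge(u, v)
        any_line = True
    if not any_line:
        raise GraphInputError("empty edge-list document")
    return MolecularGraph(g, name=name)


def read_smiles(smiles: str, name: str | None = None) -> MolecularGraph:
    """Build the heavy-atom skeleton graph from a SMILES string.

    Parsing is delegated to RDKit.  Bond orders and aromaticity collapse
    to single edges; charges and isotopes are irrelevant to degrees.
    """
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError(
            "SMILES support not installed: the 'rdkit' package is required "
            "(install the 'smiles' extra)"
        ) from exc

    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise GraphInputError(f"unparseable SMILES: {smiles!r}")
    # degree computation needs only connectivity; skip valence sanitization
    # so organometallics (e.g. Pt complexes) are accepted
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS, catchErrors=True)
    g = nx.Graph()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 1:
            g.add_node(f"a{atom.GetIdx()}")
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() == 1 or b.GetAtomicNum() == 1:
            continue
        g.add_edge(f"a{a.GetIdx()}", f"a{b.GetIdx()}")
    if g.number_of_edges() == 0:
        raise GraphInputError(f"SMILES {smiles!r} has no heavy-atom bonds")
    return MolecularGraph(g, name=name)


def edge_partition(graph: MolecularGraph) -> EdgePartition:
    """Reduce a graph to its degree-pair edge partition.

    For each edge uv the endpoint degrees (d_u, d_v) are computed in the
    hydrogen-suppressed graph, sorted so i <= j, and counted.
    """
    deg = dict(graph.graph.degree())
    cells: dict[tuple[int, int], int] = {}
    for u, v in graph.edges():
        i, j = sorted((deg[u], deg[v]))
        cells[(i, j)] = cells.get((i, j), 0) + 1
    return EdgePartition(cells, name=graph.name)


def partition_from_counts(
    rows: Sequence[tuple[int, int, int]], name: str | None = None
) -> EdgePartition:
    """Build an :class:`EdgePartition` from (i, j, count) triples.

    Keys are normalized to i <= j; duplicate cells after normalization
    are summed.  This lets a partition printed in the literature be
    entered without reconstructing any structure.
    """
    cells: dict[tuple[int, int], int] = {}
    for i, j, n in rows:
        key = (i, j) if i <= j else (j, i)
        if not (i >= 1 and j >= 1 and n >= 1):
            raise GraphInputError(f"non-positive entry in partition row ({i}, {j}, {n})")
        cells[key] = cells.get(key, 0) + int(n)
    if not cells:
        raise GraphInputError("empty partition")
    return EdgePartition(cells, name=name)


def read_partition_csv(text: str, name: str | None = None) -> EdgePartition:
    """Read a partition from CSV with header ``du,dv,count``."""
    reader = csv.DictReader(io.StringIO(text))
    required = {"du", "dv", "count"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise GraphInputError("partition CSV must have header du,dv,count")
    rows = [(int(r["du"]), int(r["dv"]), int(r["count"])) for r in reader]
    return partition_from_counts(rows, name=name)
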