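"""Molecular graphs, vertex-degree labelings and edge partitions.

A molecular graph is the hydrogen-suppressed skeleton of a molecule: vertices
are heavy atoms, edges are covalent bonds, and neither bond orders nor 3D
geometry are retained.  Two vertex labelings are supported:

* ``degree`` — the ordinary vertex degree d(v);
* ``reduced_reverse`` — RR(v) = Δ(G) − d(v) + 2, where Δ(G) is the maximum
  degree of the graph.  RR(v) ≥ 2 always, with equality exactly at vertices
  of maximum degree.

An *edge partition* groups the edges of a graph by the unordered pair of
endpoint labels.  Every degree-based (or reduced-reverse-degree-based)
topological index is a linear functional of this partition, which is what
makes closed-form index polynomials for repeat-unit families possible
(see :mod:`rrqspr.indices`).
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "MolecularGraph",
    "EdgePartition",
    "LABELINGS",
    "build_graph",
    "degree_map",
    "max_degree",
    "reduced_reverse_degrees",
    "edge_partition",
    "read_edgelist",
]

LABELINGS = ("degree", "reduced_reverse")

Vertex = Hashable


class MolecularGraph:
    """Undirected simple graph of heavy atoms.

    Thin wrapper around :class:`networkx.Graph` enforcing the molecular-graph
    invariants: no self-loops, no parallel edges, opaque vertex identifiers.
    Disconnected graphs are admissible; Δ(G) is always taken over the whole
    graph.
    """

    def __init__(self, g: nx.Graph):
        loops = list(nx.selfloop_edges(g))
        if loops:
            raise ValueError(f"self-loop edge not allowed: {loops[0]}")
        self._g = g

    @classmethod
    def from_edges(cls, edge_pairs: Iterable[tuple[Vertex, Vertex]]) -> "MolecularGraph":
        g = nx.Graph()
        for pair in edge_pairs:
            u, v = pair
            if u == v:
                raise ValueError(f"self-loop pair not allowed: {(u, v)!r}")
            g.add_edge(u, v)
        return cls(g)

    @property
    def vertices(self) -> frozenset:
        return frozenset(self._g.nodes)

    @property
    def edges(self) -> frozenset:
        return frozenset(frozenset(e) for e in self._g.edges)

    @property
    def n_vertices(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edge_list(self) -> list[tuple[Vertex, Vertex]]:
        return list(self._g.edges)

    def degree(self, v: Vertex) -> int:
        return self._g.degree[v]

    def is_connected(self) -> bool:
        return self.n_vertices > 0 and nx.is_connected(self._g)

    def relabel(self, mapping: Mapping[Vertex, Vertex]) -> "MolecularGraph":
        """Apply a vertex bijection; all label-based invariants are unchanged."""
        return MolecularGraph(nx.relabel_nodes(self._g, dict(mapping), copy=True))

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    def __len__(self) -> int:
        return self.n_vertices

    def __repr__(self) -> str:
        return f"MolecularGraph(|V|={self.n_vertices}, |E|={self.n_edges})"


def build_graph(edge_pairs: Sequence[tuple[Vertex, Vertex]]) -> MolecularGraph:
    """Build a molecular graph from vertex-identifier pairs.

    Duplicate pairs (in either order) collapse to a single edge; a pair with
    identical endpoints is rejected.
    """
    return MolecularGraph.from_edges(edge_pairs)


def degree_map(G: MolecularGraph) -> dict[Vertex, int]:
    """Degree of every vertex (number of incident edges)."""
    if G.n_vertices == 0:
        raise ValueError("degree_map of an empty graph")
    return {v: d for v, d in G.to_networkx().degree}


def max_degree(G: MolecularGraph) -> int:
    """Maximum degree Δ(G)."""
    dm = degree_map(G)
    return max(dm.values())


def reduced_reverse_degrees(G: MolecularGraph) -> dict[Vertex, int]:
    """Reduced reverse degree RR(v) = Δ(G) − d(v) + 2 for every vertex.

    Δ(G) is computed over this graph exactly; the minimum attainable label is
    2, reached precisely at the maximum-degree vertices.
    """
    dm = degree_map(G)
    delta = max(dm.values())
    return {v: delta - d + 2 for v, d in dm.items()}


@dataclass(frozen=True)
class EdgePartition:
    """Edge counts per unordered endpoint-label pair.

    ``classes`` maps canonical pairs (a, b) with a ≥ b to positive counts;
    the counts sum to the number of edges of the source graph.
    """

    labeling: str
    classes: Mapping[tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self):
        if self.labeling not in LABELINGS:
            raise ValueError(f"unknown labeling {self.labeling!r}; expected one of {LABELINGS}")
        canon = {}
        for (a, b), count in dict(self.classes).items():
            if a < 1 or b < 1:
                raise ValueError(f"labels must be positive integers, got {(a, b)}")
            if count < 0:
                raise ValueError(f"negative edge count for class {(a, b)}")
            key = (a, b) if a >= b else (b, a)
            canon[key] = canon.get(key, 0) + count
        object.__setattr__(self, "classes", canon)

    @property
    def total(self) -> int:
        """Number of edges accounted for by the partition."""
        return sum(self.classes.values())

    def to_json(self) -> str:
        rows = [
            {"a": a, "b": b, "count": c}
            for (a, b), c in sorted(self.classes.items(), reverse=True)
        ]
        return json.dumps({"labeling": self.labeling, "classes": rows}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EdgePartition":
        obj = json.loads(text)
        classes = {(row["a"], row["b"]): row["count"] for row in obj["classes"]}
        return cls(labeling=obj["labeling"], classes=classes)

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["a", "b", "count"])
        for (a, b), c in sorted(self.classes.items(), reverse=True):
            w.writerow([a, b, c])
        return buf.getvalue()


def edge_partition(G: MolecularGraph, labeling_kind: str) -> EdgePartition:
    """Partition the edges of ``G`` by unordered endpoint-label pair."""
    if labeling_kind not in LABELINGS:
        raise ValueError(f"unknown labeling_kind {labeling_kind!r}; expected one of {LABELINGS}")
    labels = degree_map(G) if labeling_kind == "degree" else reduced_reverse_degrees(G)
    classes: dict[tuple[int, int], int] = {}
    for u, v in G.edge_list():
        a, b = labels[u], labels[v]
        key = (a, b) if a >= b else (b, a)
        classes[key] = classes.get(key, 0) + 1
    return EdgePartition(labeling=labeling_kind, classes=classes)


def read_edgelist(path_or_buffer) -> MolecularGraph:
    """Read an edge-list file: one edge per line, whitespace-separated
    vertex identifiers; '#' starts a comment; blank lines ignored."""
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer) as fh:
            text = fh.read()
    pairs = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected two vertex identifiers, got {raw!r}")
        pairs.append((parts[0], parts[1]))
    if not pairs:
        raise ValueError("edge list contains no edges")
    return build_graph(pairs)
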