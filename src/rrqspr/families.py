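"""Graph families: benzenoid (fused-hexagon) systems, the HA–paclitaxel
conjugate partition, and random fixture graphs.

Benzenoid systems are built on the hexagonal lattice from axial cell
coordinates; shared lattice corners of adjacent hexagons unify, so vertex
degrees are always 2 or 3 (hydrogen-suppressed convention).  The
hyaluronic-acid–paclitaxel conjugate polymer (HAP)_n is represented by its
published reduced-reverse edge partition (nine classes, counts linear in the
repeat count n) rather than by an explicit drawing-derived graph.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from typing import Iterable, Sequence

import networkx as nx

from .graph import MolecularGraph, build_graph
from .indices import LinearForm, SymbolicEdgePartition

__all__ = [
    "HexSystem",
    "hexagonal_system",
    "hap_partition",
    "implied_vertex_form",
    "random_molecular_graph",
]

# axial-coordinate neighbour offsets of a hexagonal cell
_AXIAL_NEIGHBOURS = [(1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)]


@dataclass(frozen=True)
class HexSystem:
    """A set of hexagon positions in axial lattice coordinates."""

    cells: frozenset

    def __init__(self, cells: Iterable[tuple[int, int]]):
        object.__setattr__(self, "cells", frozenset((int(q), int(r)) for q, r in cells))
        if not self.cells:
            raise ValueError("a hex system needs at least one cell")

    def is_connected(self) -> bool:
        g = nx.Graph()
        g.add_nodes_from(self.cells)
        for q, r in self.cells:
            for dq, dr in _AXIAL_NEIGHBOURS:
                if (q + dq, r + dr) in self.cells:
                    g.add_edge((q, r), (q + dq, r + dr))
        return nx.is_connected(g)

    @classmethod
    def chain(cls, h: int) -> "HexSystem":
        """Linear chain of h hexagons (linear polyacene arrangement)."""
        if h < 1:
            raise ValueError("chain length must be >= 1")
        return cls([(i, 0) for i in range(h)])


def _corner_key(q: int, r: int, k: int) -> tuple[int, int]:
    """Exact integer identifier for corner k of hexagon (q, r).

    Corners are identified on a doubled integer grid so that shared corners
    of adjacent hexagons get identical keys (pointy-top orientation; centre
    of cell (q, r) at x = 2·(2q + r), y = 6r on the doubled grid).
    """
    cx, cy = 2 * (2 * q + r), 6 * r
    offsets = [(2, 2), (0, 4), (-2, 2), (-2, -2), (0, -4), (2, -2)]
    dx, dy = offsets[k % 6]
    return (cx + dx, cy + dy)


def hexagonal_system(cells: HexSystem | Sequence[tuple[int, int]]) -> MolecularGraph:
    """Molecular graph of a benzenoid system: the union of the six boundary
    vertices/edges of each hexagonal cell, with shared corners merged.

    Degrees of the result are in {2, 3}; a disconnected cell set is rejected.
    """
    if not isinstance(cells, HexSystem):
        cells = HexSystem(cells)
    if not cells.is_connected():
        raise ValueError("hexagonal cell set is not edge-connected")
    edges = set()
    for q, r in cells.cells:
        corners = [_corner_key(q, r, k) for k in range(6)]
        for k in range(6):
            u, v = corners[k], corners[(k + 1) % 6]
            edges.add((u, v) if u <= v else (v, u))
    return build_graph(sorted(edges))


def hap_partition() -> SymbolicEdgePartition:
    """The reduced-reverse edge partition of the (HAP)_n conjugate polymer.

    Nine classes with counts linear in the repeat count n; the class counts
    sum to 96n edges.  Loaded from the packaged partition file.
    """
    text = resources.files("rrqspr.data").joinpath("hap_partition.json").read_text()
    return SymbolicEdgePartition.from_json(text)


def implied_vertex_form(sp: SymbolicEdgePartition, delta: int) -> LinearForm:
    """Vertex count implied by a reduced-reverse edge partition.

    With maximum degree Δ, a label a maps back to the degree d = Δ + 2 − a.
    Each edge contributes 1/d(u) + 1/d(v) to the vertex count (every vertex
    of degree d ≥ 1 is counted once across its d incident edges), so the
    symbolic vertex count is Σ_classes count·(1/d(a) + 1/d(b)).  Computed in
    exact rational arithmetic.
    """
    if delta < 1:
        raise ValueError("delta must be a positive integer")
    slope = Fraction(0)
    intercept = Fraction(0)
    for (a, b), form in sp.classes.items():
        for lab in (a, b):
            d = delta + 2 - lab
            if d < 1:
                raise ValueError(
                    f"label {lab} implies degree {d} < 1 under delta={delta}"
                )
        contrib = Fraction(1, delta + 2 - a) + Fraction(1, delta + 2 - b)
        slope += contrib * Fraction(form.slope).limit_denominator(10**6)
        intercept += contrib * Fraction(form.intercept).limit_denominator(10**6)
    return LinearForm(float(slope), float(intercept))


def random_molecular_graph(n_vertices: int, max_deg: int, seed: int) -> MolecularGraph:
    """Connected simple random graph with all degrees ≤ max_deg.

    Grown as a random tree with a degree cap, then densified with random
    extra edges that respect the cap.  Deterministic for a fixed seed.
    """
    if n_vertices < 2:
        raise ValueError("need at least 2 vertices")
    if max_deg < 1:
        raise ValueError("max_deg must be >= 1")
    if max_deg == 1 and n_vertices > 2:
        raise ValueError("max_deg=1 admits only a single edge (n_vertices <= 2)")
    rng = random.Random(seed)
    g = nx.Graph()
    g.add_node(0)
    for v in range(1, n_vertices):
        candidates = [u for u in g.nodes if g.degree[u] < max_deg]
        if not candidates:
            raise ValueError(
                f"cannot attach vertex {v}: degree cap {max_deg} saturated"
            )
        g.add_edge(v, rng.choice(candidates))
    # densify: try a few random chords without violating the cap
    extra_attempts = n_vertices
    for _ in range(extra_attempts):
        u, v = rng.sample(range(n_vertices), 2)
        if u != v and not g.has_edge(u, v) and g.degree[u] < max_deg and g.degree[v] < max_deg:
            g.add_edge(u, v)
    return MolecularGraph(g)
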