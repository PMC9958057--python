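"""Degree-based and reduced-reverse-degree-based topological indices.

Every index here is an edge sum Σ_{uv∈E} w(ℓ(u), ℓ(v)) where ℓ is either the
vertex degree or the reduced reverse degree RR(v) = Δ(G) − d(v) + 2, and w is
a symmetric weight on positive integer labels.  Because such a sum depends on
the graph only through its edge partition, each index can be evaluated three
ways, all provided here:

* directly on a graph (:func:`index_value`);
* from a numeric edge partition (:func:`index_from_partition`);
* symbolically, as a linear polynomial a·n + b, when the edge-class counts of
  a repeat-unit family G_n are themselves linear in n (:func:`closed_form`).

The reduced-reverse family comprises the first/second Zagreb-type sums RRM1,
RRM2, the hyper-Zagreb analogues RRHM1, RRHM2, the forgotten-index analogue
RRF, atom-bond-connectivity RRABC, geometric–arithmetic RRGA, and the
Randić-type RRR_α (α ∈ {1, −1, ½, −½}; α=1 coincides with RRM2).  The
classical comparators are the standard degree-based Zagreb, hyper-Zagreb,
forgotten, ABC, Randić (with variants), geometric–arithmetic, harmonic,
Gourava and hyper-Gourava indices as defined in the topological-index
literature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Optional

from .graph import EdgePartition, LABELINGS, MolecularGraph, edge_partition

__all__ = [
    "IndexSpec",
    "LinearForm",
    "SymbolicEdgePartition",
    "catalog",
    "get_spec",
    "randic_spec",
    "index_value",
    "index_from_partition",
    "closed_form",
    "evaluate_form",
]


@dataclass(frozen=True)
class IndexSpec:
    """A named edge-weight rule over endpoint labels."""

    name: str
    labeling: str  # "degree" or "reduced_reverse"
    weight: Callable[[float, float], float]
    alpha: Optional[float] = None
    family: str = ""

    def __post_init__(self):
        if self.labeling not in LABELINGS:
            raise ValueError(f"unknown labeling {self.labeling!r}")

    def w(self, a: float, b: float) -> float:
        return self.weight(a, b)

    def __repr__(self) -> str:
        al = f", alpha={self.alpha}" if self.alpha is not None else ""
        return f"IndexSpec({self.name!r}, {self.labeling}{al})"


@dataclass(frozen=True)
class LinearForm:
    """A linear polynomial slope·n + intercept in the repeat count n."""

    slope: float
    intercept: float = 0.0

    def __call__(self, n: int) -> float:
        return evaluate_form(self, n)

    def __add__(self, other: "LinearForm") -> "LinearForm":
        return LinearForm(self.slope + other.slope, self.intercept + other.intercept)

    def scale(self, c: float) -> "LinearForm":
        return LinearForm(c * self.slope, c * self.intercept)

    def __repr__(self) -> str:
        sign = "+" if self.intercept >= 0 else "-"
        return f"{self.slope}n {sign} {abs(self.intercept)}"


def evaluate_form(f: LinearForm, n: int) -> float:
    if n < 1:
        raise ValueError(f"repeat count n must be >= 1, got {n}")
    return f.slope * n + f.intercept


@dataclass(frozen=True)
class SymbolicEdgePartition:
    """Edge-class counts of a repeat-unit family, linear in the repeat count.

    Each class (a, b) carries a :class:`LinearForm`; instantiating at an
    integer n ≥ 1 must yield non-negative integer counts.
    """

    labeling: str
    classes: Mapping[tuple[int, int], LinearForm]

    def __post_init__(self):
        if self.labeling not in LABELINGS:
            raise ValueError(f"unknown labeling {self.labeling!r}")
        canon = {}
        for (a, b), form in dict(self.classes).items():
            if a < 1 or b < 1:
                raise ValueError(f"labels must be positive integers, got {(a, b)}")
            key = (a, b) if a >= b else (b, a)
            canon[key] = form
        object.__setattr__(self, "classes", canon)

    def total_form(self) -> LinearForm:
        """Symbolic total edge count Σ classes."""
        total = LinearForm(0.0, 0.0)
        for form in self.classes.values():
            total = total + form
        return total

    def instantiate(self, n: int) -> EdgePartition:
        """Numeric partition at repeat count n (counts must be ≥ 0 integers)."""
        if n < 1:
            raise ValueError(f"repeat count n must be >= 1, got {n}")
        classes = {}
        for key, form in self.classes.items():
            c = form(n)
            ci = round(c)
            if abs(c - ci) > 1e-9 or ci < 0:
                raise ValueError(f"class {key} count {c} at n={n} is not a non-negative integer")
            classes[key] = ci
        return EdgePartition(labeling=self.labeling, classes=classes)

    def to_json(self) -> str:
        import json

        rows = [
            {"a": a, "b": b, "slope": f.slope, "intercept": f.intercept}
            for (a, b), f in sorted(self.classes.items(), reverse=True)
        ]
        return json.dumps({"labeling": self.labeling, "classes": rows}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SymbolicEdgePartition":
        import json

        obj = json.loads(text)
        classes = {
            (row["a"], row["b"]): LinearForm(row["slope"], row.get("intercept", 0.0))
            for row in obj["classes"]
        }
        return cls(labeling=obj["labeling"], classes=classes)


# ---------------------------------------------------------------------------
# Weight functions.  ABC-type weights are 0 at the degenerate pair (1, 1):
# the numerator a + b − 2 vanishes, so the summand is defined, not an error.

def _w_abc(a, b):
    return math.sqrt((a + b - 2) / (a * b))


def _w_ga(a, b):
    return 2.0 * math.sqrt(a * b) / (a + b)


def _make_randic(alpha):
    def w(a, b):
        return float((a * b) ** alpha)

    return w


_RR_WEIGHTS = {
    "RRM1": (lambda a, b: a + b, "Zagreb"),
    "RRM2": (lambda a, b: a * b, "Zagreb"),
    "RRHM1": (lambda a, b: (a + b) ** 2, "hyper-Zagreb"),
    "RRHM2": (lambda a, b: (a * b) ** 2, "hyper-Zagreb"),
    "RRF": (lambda a, b: a**2 + b**2, "forgotten"),
    "RRABC": (_w_abc, "ABC"),
    "RRGA": (_w_ga, "geometric-arithmetic"),
}

_CLASSICAL_WEIGHTS = {
    "M1": (lambda a, b: a + b, "Zagreb"),
    "M2": (lambda a, b: a * b, "Zagreb"),
    "HM1": (lambda a, b: (a + b) ** 2, "hyper-Zagreb"),
    "HM2": (lambda a, b: (a * b) ** 2, "hyper-Zagreb"),
    "F": (lambda a, b: a**2 + b**2, "forgotten"),
    "ABC": (_w_abc, "ABC"),
    "GA": (_w_ga, "geometric-arithmetic"),
    "H": (lambda a, b: 2.0 / (a + b), "harmonic"),
    "GO1": (lambda a, b: (a + b) + a * b, "Gourava"),
    "GO2": (lambda a, b: (a + b) * a * b, "Gourava"),
    "HGO1": (lambda a, b: ((a + b) + a * b) ** 2, "hyper-Gourava"),
    "HGO2": (lambda a, b: ((a + b) * a * b) ** 2, "hyper-Gourava"),
}

# Randić-type members of the catalog: (name, labeling, alpha).  The plain
# Randić index R uses α = −1/2 by convention.  RRR with α = 1 coincides with
# RRM2 and is therefore not a separate catalog entry (use randic_spec).
_RANDIC_MEMBERS = [
    ("RRR_-1", "reduced_reverse", -1.0),
    ("RRR_1/2", "reduced_reverse", 0.5),
    ("RRR_-1/2", "reduced_reverse", -0.5),
    ("R", "degree", -0.5),
    ("R_-1", "degree", -1.0),
    ("R_1/2", "degree", 0.5),
    ("R_-1/2", "degree", -0.5),
]


def randic_spec(labeling: str, alpha: float, name: Optional[str] = None) -> IndexSpec:
    """Randić-type spec Σ (ℓ(u)·ℓ(v))^α for an arbitrary exponent α."""
    if name is None:
        prefix = "RRR" if labeling == "reduced_reverse" else "R"
        name = f"{prefix}_{alpha:g}"
    return IndexSpec(name=name, labeling=labeling, weight=_make_randic(alpha), alpha=alpha, family="Randic")


def catalog() -> list[IndexSpec]:
    """All 26 catalogued index specs: 10 reduced-reverse + 16 degree-based."""
    specs = [
        IndexSpec(name, "reduced_reverse", w, family=fam) for name, (w, fam) in _RR_WEIGHTS.items()
    ]
    specs += [
        IndexSpec(name, "degree", w, family=fam) for name, (w, fam) in _CLASSICAL_WEIGHTS.items()
    ]
    specs += [randic_spec(labeling, alpha, name=name) for name, labeling, alpha in _RANDIC_MEMBERS]
    return specs


_ALIASES = {
    "RR_R": "RRR",  # exponent supplied separately
    "RRR-1": "RRR_-1",
    "RRR-1/2": "RRR_-1/2",
    "RRR1/2": "RRR_1/2",
    "R-1": "R_-1",
    "R-1/2": "R_-1/2",
    "R1/2": "R_1/2",
}


def get_spec(name: str, alpha: Optional[float] = None) -> IndexSpec:
    """Look up a catalogued spec by (case-insensitive) name.

    ``RR_R`` / ``RRR`` and ``R`` with an explicit ``alpha`` build a
    Randić-type spec for that exponent instead of a catalog lookup.
    """
    key = name.strip().upper().replace(" ", "")
    key = _ALIASES.get(key, key)
    if alpha is not None:
        if key in ("RRR", "RR_R"):
            return randic_spec("reduced_reverse", alpha)
        if key == "R":
            return randic_spec("degree", alpha)
        raise ValueError(f"exponent alpha only applies to Randic-type specs, not {name!r}")
    for spec in catalog():
        if spec.name.upper() == key:
            return spec
    known = ", ".join(s.name for s in catalog())
    raise KeyError(f"unknown index {name!r}; known: {known}")


def index_value(G: MolecularGraph, spec: IndexSpec) -> float:
    """Evaluate the index by direct summation over the edges of ``G``."""
    if G.n_vertices == 0:
        raise ValueError("index of an empty graph")
    from .graph import degree_map, reduced_reverse_degrees

    dm = degree_map(G)
    if any(d == 0 for d in dm.values()):
        warnings.warn("graph has isolated vertices; they contribute nothing to the index")
    labels = dm if spec.labeling == "degree" else reduced_reverse_degrees(G)
    return float(sum(spec.w(labels[u], labels[v]) for u, v in G.edge_list()))


def index_from_partition(p: EdgePartition, spec: IndexSpec) -> float:
    """Evaluate the index as Σ count·w(a,b) over the partition classes."""
    if p.labeling != spec.labeling:
        raise ValueError(
            f"partition labeling {p.labeling!r} does not match spec labeling {spec.labeling!r}"
        )
    return float(sum(c * spec.w(a, b) for (a, b), c in p.classes.items()))


def closed_form(sp: SymbolicEdgePartition, spec: IndexSpec) -> LinearForm:
    """Closed-form index polynomial a·n + b for a repeat-unit family.

    Weights distribute over the linear class counts, so the index of G_n is
    (Σ slope·w)·n + (Σ intercept·w); slopes/intercepts are accumulated in
    double precision.
    """
    if sp.labeling != spec.labeling:
        raise ValueError(
            f"partition labeling {sp.labeling!r} does not match spec labeling {spec.labeling!r}"
        )
    total = LinearForm(0.0, 0.0)
    for (a, b), form in sp.classes.items():
        total = total + form.scale(spec.w(a, b))
    return total
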