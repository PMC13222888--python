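"""Partial-order ranking of areal units and the Hasse diagram derived from it.

Units (counties) are compared componentwise on an oriented, normalized
indicator table: x ≥ y holds iff every indicator of x is at least that of y.
Pairs ordered in neither direction are incomparable — the partial order keeps
that information instead of forcing a weighted aggregate.  Units with
identical indicator vectors are collapsed into equivalence classes before
ordering, which preserves antisymmetry.

From the strict order this module derives the Hasse diagram (cover
relations, i.e. the transitive reduction), assigns levels counted so that
maximal — undominated — elements occupy the top level, enumerates maximal
chains, flags isolated elements, and computes LPOM0 average-rank estimates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drivers import NormalizedTable

__all__ = [
    "ComparisonOutcome",
    "Poset",
    "HasseDiagram",
    "compare",
    "build_poset",
    "transitive_reduction",
    "assign_levels",
    "hasse",
    "maximal_chains",
    "isolated_elements",
    "lpom_average_rank",
    "to_dot",
]


class ComparisonOutcome(enum.Enum):
    LESS = "less"
    GREATER = "greater"
    EQUAL = "equal"
    INCOMPARABLE = "incomparable"


def compare(x, y, tol: float = 0.0) -> ComparisonOutcome:
    """Componentwise comparison of two oriented indicator vectors.

    ``greater`` iff x dominates y on every component (with at least one
    strict component), ``less`` symmetrically, ``equal`` iff the vectors
    agree componentwise within ``tol``; otherwise ``incomparable``.

    ``tol`` treats components within that distance as tied; the default 0
    demands exact equality, which is meaningful on normalized data where
    ties come from identical inputs.  Note that a positive ``tol`` makes the
    induced relation only approximately transitive.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vectors must be 1-D with equal length, got {x.shape} vs {y.shape}")
    ge = bool(np.all(x >= y - tol))
    le = bool(np.all(y >= x - tol))
    if ge and le:
        return ComparisonOutcome.EQUAL
    if ge:
        return ComparisonOutcome.GREATER
    if le:
        return ComparisonOutcome.LESS
    return ComparisonOutcome.INCOMPARABLE


@dataclass(frozen=True)
class Poset:
    """A strict partial order over equivalence classes of units.

    ``elements`` are class representatives (one unit id per class of
    identical indicator vectors); ``members`` maps each representative to all
    unit ids of its class; ``below`` holds ordered pairs (a, b) meaning
    a < b in the strict order.
    """

    elements: tuple
    below: frozenset  # of (a, b) pairs, a < b
    members: dict = field(default_factory=dict)
    vectors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            object.__setattr__(self, "members", {e: (e,) for e in self.elements})

    @property
    def n(self) -> int:
        return len(self.elements)

    def unit_class(self, unit_id):
        """Representative of the equivalence class a unit belongs to."""
        for rep, mem in self.members.items():
            if unit_id in mem:
                return rep
        raise KeyError(unit_id)

    def validate(self) -> None:
        """Check irreflexivity, antisymmetry and transitivity by enumeration."""
        elems = set(self.elements)
        for a, b in self.below:
            if a == b:
                raise ValueError(f"relation is not irreflexive: {a} < {a}")
            if (b, a) in self.below:
                raise ValueError(f"relation is not antisymmetric: {a} <> {b}")
            if a not in elems or b not in elems:
                raise ValueError(f"relation pair ({a}, {b}) outside element set")
        for a, b in self.below:
            for c in self.elements:
                if (b, c) in self.below and (a, c) not in self.below:
                    raise ValueError(
                        f"relation is not transitive: {a} < {b} < {c} but not {a} < {c}"
                    )

    @classmethod
    def from_relations(cls, elements, strict_pairs) -> "Poset":
        """Build a poset from explicit a < b pairs, closing transitively."""
        elements = tuple(elements)
        below = set(map(tuple, strict_pairs))
        changed = True
        while changed:  # transitive closure (Warshall would do; n is small)
            changed = False
            for a, b in list(below):
                for b2, c in list(below):
                    if b2 == b and (a, c) not in below and a != c:
                        below.add((a, c))
                        changed = True
        p = cls(elements=elements, below=frozenset(below))
        p.validate()
        return p


def build_poset(
    table: NormalizedTable, columns=None, tol: float = 0.0
) -> Poset:
    """Construct the strict partial order of units under componentwise
    comparison on the selected indicator columns.

    The table must already be oriented.  Units with (tol-)identical vectors
    are merged into one equivalence class, represented by the first unit in
    table order.
    """
    if not table.oriented:
        raise ValueError("table must be oriented before building a poset")
    if columns is None:
        columns = list(table.values.columns)
    columns = list(columns)
    if not columns:
        raise ValueError("column selection is empty")
    sub = table.values[columns]
    units = list(sub.index)
    vecs = {u: sub.loc[u].to_numpy(dtype=float) for u in units}

    # collapse equal vectors (union-find handles tol > 0 chains of ties)
    parent = {u: u for u in units}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for i, u in enumerate(units):
        for v in units[i + 1 :]:
            if compare(vecs[u], vecs[v], tol) is ComparisonOutcome.EQUAL:
                parent[find(v)] = find(u)

    members: dict = {}
    for u in units:  # table order ⇒ first member is the representative
        members.setdefault(find(u), []).append(u)
    reps = list(members.keys())

    below = set()
    for i, a in enumerate(reps):
        for b in reps[i + 1 :]:
            out = compare(vecs[a], vecs[b], tol)
            if out is ComparisonOutcome.LESS:
                below.add((a, b))
            elif out is ComparisonOutcome.GREATER:
                below.add((b, a))
    return Poset(
        elements=tuple(reps),
        below=frozenset(below),
        members={r: tuple(m) for r, m in members.items()},
        vectors={r: vecs[r] for r in reps},
    )


def transitive_reduction(p: Poset) -> frozenset:
    """Cover relations of the order: (a, b) with a < b and no c in between."""
    covers = set()
    for a, b in p.below:
        if not any((a, c) in p.below and (c, b) in p.below for c in p.elements):
            covers.add((a, b))
    return frozenset(covers)


def assign_levels(elements, covers) -> tuple[dict, int]:
    """Top-down level assignment from the cover DAG.

    level(x) = L − depth(x) where depth(x) is the longest upward path (in
    cover edges) from x to a maximal element and L = 1 + max depth.  Maximal
    elements — including isolated ones — sit at the top level L.
    """
    up: dict = {e: [] for e in elements}
    for a, b in covers:
        up[a].append(b)

    depth: dict = {}
    on_stack: set = set()

    def walk(e):
        if e in depth:
            return depth[e]
        if e in on_stack:
            raise ValueError("cycle detected: the relation is not a valid order")
        on_stack.add(e)
        d = 0 if not up[e] else 1 + max(walk(s) for s in up[e])
        on_stack.discard(e)
        depth[e] = d
        return d

    for e in elements:
        walk(e)
    n_levels = 1 + (max(depth.values()) if depth else 0)
    levels = {e: n_levels - d for e, d in depth.items()}
    return levels, n_levels


@dataclass(frozen=True)
class HasseDiagram:
    """Cover edges, levels and isolated elements of a poset."""

    covers: frozenset
    levels: dict  # element -> level in [1, n_levels]
    n_levels: int
    isolated: frozenset
    elements: tuple
    members: dict

    def unit_level(self, unit_id) -> int:
        for rep, mem in self.members.items():
            if unit_id in mem:
                return self.levels[rep]
        raise KeyError(unit_id)


def isolated_elements(p: Poset) -> frozenset:
    """Elements incomparable with every other element of the poset."""
    related = {a for a, _ in p.below} | {b for _, b in p.below}
    return frozenset(e for e in p.elements if e not in related)


def hasse(p: Poset) -> HasseDiagram:
    """Derive the Hasse diagram: transitive reduction, levels, isolated set."""
    covers = transitive_reduction(p)
    levels, n_levels = assign_levels(p.elements, covers)
    return HasseDiagram(
        covers=covers,
        levels=levels,
        n_levels=n_levels,
        isolated=isolated_elements(p),
        elements=tuple(p.elements),
        members=dict(p.members),
    )


def maximal_chains(h: HasseDiagram) -> list[tuple]:
    """All maximal chains of the order: source-to-sink paths in the cover
    DAG with at least two elements.  Isolated elements form no chain and are
    reported through ``h.isolated`` instead."""
    succ: dict = {e: [] for e in h.elements}
    has_pred = set()
    for a, b in h.covers:
        succ[a].append(b)
        has_pred.add(b)
    for e in succ:
        succ[e].sort(key=str)

    chains: list[tuple] = []

    def extend(path):
        tail = path[-1]
        if not succ[tail]:
            if len(path) >= 2:
                chains.append(tuple(path))
            return
        for nxt in succ[tail]:
            extend(path + [nxt])

    sources = [e for e in h.elements if e not in has_pred and succ[e]]
    for s in sorted(sources, key=str):
        extend([s])
    return chains


def lpom_average_rank(p: Poset, h: HasseDiagram | None = None) -> pd.DataFrame:
    """LPOM0 average-rank table for every element of the poset.

    For element x with S(x) elements strictly below, P(x) strictly above and
    U(x) incomparable (S + P + U = N − 1), the local-partial-order estimate
    of the mean rank over all linear extensions is

        Rav(x) = (S(x) + 1)(N + 1) / (N + 1 − U(x)),

    exact on chains and antichains and a standard closed-form approximation
    elsewhere.  Rank 1 is the bottom.
    """
    if h is None:
        h = hasse(p)
    n = p.n
    rows = []
    for e in p.elements:
        s = sum(1 for (a, b) in p.below if b == e)
        big = sum(1 for (a, b) in p.below if a == e)
        u = n - 1 - s - big
        rav = (s + 1) * (n + 1) / (n + 1 - u)
        rows.append(
            {
                "element": e,
                "members": ";".join(str(m) for m in p.members[e]),
                "level": h.levels[e],
                "S": s,
                "P": big,
                "U": u,
                "Rav": rav,
            }
        )
    return pd.DataFrame(rows).set_index("element")


def to_dot(h: HasseDiagram, title: str = "hasse") -> str:
    """Render the Hasse diagram as Graphviz DOT text.

    Nodes are annotated with their level and ranked bottom-up; isolated
    elements are drawn dashed.  Edges point from the smaller element to the
    element that covers it.
    """

    def q(s) -> str:
        return '"' + str(s).replace('"', r"\"") + '"'

    lines = [f"digraph {q(title)} {{", "  rankdir=BT;", "  node [shape=box];"]
    for level in range(1, h.n_levels + 1):
        same = [e for e in h.elements if h.levels[e] == level]
        if same:
            lines.append("  { rank=same; " + " ".join(q(e) for e in same) + " }")
    for e in h.elements:
        style = ', style="dashed"' if e in h.isolated else ""
        label = f"{e}\\nlevel {h.levels[e]}"
        lines.append(f"  {q(e)} [label={q(label)}{style}];")
    for a, b in sorted(h.covers, key=lambda p_: (str(p_[0]), str(p_[1]))):
        lines.append(f"  {q(a)} -> {q(b)};")
    lines.append("}")
    return "\n".join(lines)


def covers_to_csv(h: HasseDiagram, path) -> None:
    """Write the cover edges as a two-column CSV (lower, upper)."""
    rows = sorted(h.covers, key=lambda p_: (str(p_[0]), str(p_[1])))
    pd.DataFrame(rows, columns=["lower", "upper"]).to_csv(path, index=False)
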