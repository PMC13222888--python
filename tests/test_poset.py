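"""Partial-order construction, Hasse diagrams, levels, chains and LPOM0
ranks, checked against brute-force and networkx oracles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ldrank import (
    ComparisonOutcome,
    IndicatorMeta,
    NormalizedTable,
    Poset,
    assign_levels,
    build_poset,
    compare,
    hasse,
    isolated_elements,
    lpom_average_rank,
    maximal_chains,
    transitive_reduction,
)
from ldrank.examples import SIX_COUNTY_STRUCTURE

from conftest import random_poset

LESS, GREATER = ComparisonOutcome.LESS, ComparisonOutcome.GREATER
EQUAL, INCOMP = ComparisonOutcome.EQUAL, ComparisonOutcome.INCOMPARABLE


# ---------------------------------------------------------------- oracles
def nx_reduction(p: Poset) -> frozenset:
    g = nx.DiGraph()
    g.add_nodes_from(p.elements)
    g.add_edges_from(p.below)
    return frozenset(nx.transitive_reduction(g).edges())


def oracle_levels(elements, covers):
    """Levels via exhaustive enumeration of all upward cover paths."""
    succ = {e: [b for (a, b) in covers if a == e] for e in elements}

    def all_path_lengths(e):
        if not succ[e]:
            return [0]
        return [1 + n for s in succ[e] for n in all_path_lengths(s)]

    depth = {e: max(all_path_lengths(e)) for e in elements}
    n_levels = 1 + max(depth.values())
    return {e: n_levels - d for e, d in depth.items()}, n_levels


def oracle_chains(elements, covers):
    g = nx.DiGraph()
    g.add_nodes_from(elements)
    g.add_edges_from(covers)
    sources = [n for n in g if g.in_degree(n) == 0 and g.out_degree(n) > 0]
    sinks = [n for n in g if g.out_degree(n) == 0 and g.in_degree(n) > 0]
    out = set()
    for s in sources:
        for t in sinks:
            for path in nx.all_simple_paths(g, s, t):
                out.add(tuple(path))
    return out


def exact_mean_ranks(p: Poset) -> dict:
    """Average rank over all linear extensions by full enumeration (rank 1
    = bottom of the extension)."""
    elems = list(p.elements)
    totals = {e: 0 for e in elems}
    count = 0
    for perm in itertools.permutations(elems):
        pos = {e: i for i, e in enumerate(perm)}
        if all(pos[a] < pos[b] for (a, b) in p.below):
            count += 1
            for i, e in enumerate(perm):
                totals[e] += i + 1
    return {e: totals[e] / count for e in elems}


# ---------------------------------------------------------------- compare
class TestCompare:
    def test_componentwise_dominance(self):
        assert compare([0.5, 0.4], [0.1, 0.2]) is GREATER
        assert compare([0.1, 0.2], [0.5, 0.4]) is LESS

    def test_crossing_components_incomparable(self):
        assert compare([0.5, 0.1], [0.1, 0.5]) is INCOMP

    def test_identical_vectors_equal(self):
        assert compare([0.3, 0.3, 0.9], [0.3, 0.3, 0.9]) is EQUAL

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            compare([0.1], [0.1, 0.2])

    def test_tolerance_merges_near_ties(self):
        assert compare([0.50, 0.41], [0.505, 0.40], tol=0.01) is EQUAL
        assert compare([0.6, 0.41], [0.505, 0.40], tol=0.01) is GREATER

    @pytest.mark.parametrize("seed", range(10))
    def test_exactly_one_outcome_and_mirror_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.integers(0, 3, 4) / 2.0, rng.integers(0, 3, 4) / 2.0
        out, back = compare(x, y), compare(y, x)
        mirror = {LESS: GREATER, GREATER: LESS, EQUAL: EQUAL, INCOMP: INCOMP}
        assert back is mirror[out]


# ------------------------------------------------------------ build_poset
class TestBuildPoset:
    def table(self, rows, n_cols):
        metas = [IndicatorMeta(f"f{j}", "natural") for j in range(n_cols)]
        df = pd.DataFrame(rows, index=[f"u{i}" for i in range(len(rows))],
                          columns=[m.name for m in metas])
        return NormalizedTable(df, metas, oriented=True)

    def test_singleton(self):
        p = build_poset(self.table([[0.5, 0.5]], 2))
        assert p.n == 1 and not p.below

    def test_two_chain(self):
        p = build_poset(self.table([[0.0, 0.0], [1.0, 1.0]], 2))
        assert p.below == frozenset({("u0", "u1")})

    def test_equal_vectors_collapse_to_one_class(self):
        p = build_poset(self.table([[0.2, 0.8], [0.2, 0.8], [1.0, 1.0]], 2))
        assert p.n == 2
        assert p.members[p.unit_class("u1")] == ("u0", "u1")
        # class inherits relations of its vector
        assert (p.unit_class("u0"), "u2") in p.below

    def test_unoriented_table_rejected(self):
        t = self.table([[0.1, 0.2]], 2)
        t.oriented = False
        with pytest.raises(ValueError, match="oriented"):
            build_poset(t)

    def test_empty_column_selection_rejected(self, fig_table):
        with pytest.raises(ValueError, match="empty"):
            build_poset(fig_table, columns=[])

    @pytest.mark.parametrize("seed", range(20))
    def test_relation_matches_exhaustive_pairwise_comparison(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, 4, size=(8, 3)) / 3.0
        t = self.table(rows, 3)
        p = build_poset(t)
        p.validate()  # irreflexive, antisymmetric, transitive
        vec = {f"u{i}": rows[i] for i in range(8)}
        for a in p.elements:
            for b in p.elements:
                if a == b:
                    continue
                expect = compare(vec[a], vec[b]) is LESS
                assert ((a, b) in p.below) == expect

    @pytest.mark.parametrize("seed", range(8))
    def test_adding_indicator_columns_only_removes_relations(self, seed):
        # comparability is antitone in the indicator set
        rng = np.random.default_rng(1000 + seed)
        rows = rng.random((7, 4))
        t = self.table(rows, 4)
        p_full = build_poset(t)
        # every strict relation on the full indicator set must already hold
        # (as less-or-equal) on any column subset
        for a, b in p_full.below:
            assert compare(rows[int(a[1:]), :2], rows[int(b[1:]), :2]) in (LESS, EQUAL)


# ------------------------------------------------- reduction/levels/chains
class TestHasseStructure:
    def test_three_chain_reduces_to_two_covers(self):
        p = Poset.from_relations("abc", [("a", "b"), ("b", "c")])
        assert transitive_reduction(p) == frozenset({("a", "b"), ("b", "c")})

    def test_antichain_has_no_covers_and_one_level(self):
        p = Poset.from_relations("abcd", [])
        h = hasse(p)
        assert not h.covers
        assert h.n_levels == 1
        assert all(lev == 1 for lev in h.levels.values())
        assert h.isolated == frozenset("abcd")
        assert maximal_chains(h) == []

    def test_level_assignment_follows_longest_path(self):
        # diamond with a tail: a < b < d, a < c < d, d < e
        p = Poset.from_relations(
            "abcde", [("a", "b"), ("a", "c"), ("b", "d"), ("c", "d"), ("d", "e")]
        )
        h = hasse(p)
        assert h.levels == {"a": 1, "b": 2, "c": 2, "d": 3, "e": 4}

    def test_cycle_detection(self):
        with pytest.raises(ValueError, match="cycle"):
            assign_levels("ab", {("a", "b"), ("b", "a")})

    def test_single_cover_edge_yields_one_chain(self):
        p = Poset.from_relations("ab", [("a", "b")])
        assert maximal_chains(hasse(p)) == [("a", "b")]

    def test_chain_poset_has_no_isolated_elements(self):
        p = Poset.from_relations("abc", [("a", "b"), ("b", "c")])
        assert isolated_elements(p) == frozenset()

    @pytest.mark.parametrize("seed", range(40))
    def test_reduction_levels_chains_match_oracles(self, seed):
        rng = np.random.default_rng(seed)
        p = random_poset(rng)
        covers = transitive_reduction(p)
        assert covers == nx_reduction(p)
        levels, n_levels = assign_levels(p.elements, covers)
        olevels, on = oracle_levels(p.elements, covers)
        assert (levels, n_levels) == (olevels, on)
        h = hasse(p)
        assert set(maximal_chains(h)) == oracle_chains(p.elements, covers)

    @pytest.mark.parametrize("seed", range(15))
    def test_closure_of_covers_recovers_strict_order(self, seed):
        rng = np.random.default_rng(500 + seed)
        p = random_poset(rng)
        g = nx.DiGraph()
        g.add_nodes_from(p.elements)
        g.add_edges_from(transitive_reduction(p))
        closure = frozenset(nx.transitive_closure_dag(g).edges())
        assert closure == p.below

    @pytest.mark.parametrize("seed", range(15))
    def test_level_monotonicity_along_the_order(self, seed):
        rng = np.random.default_rng(900 + seed)
        p = random_poset(rng)
        h = hasse(p)
        for a, b in p.below:
            assert h.levels[a] < h.levels[b]


# -------------------------------------------------------- worked example
class TestSixCountyExample:
    def test_cover_structure(self, fig_table):
        h = hasse(build_poset(fig_table))
        assert set(h.covers) == SIX_COUNTY_STRUCTURE["covers"]

    def test_levels(self, fig_table):
        h = hasse(build_poset(fig_table))
        assert h.n_levels == 3
        assert h.levels == SIX_COUNTY_STRUCTURE["levels"]

    def test_chains_and_isolated(self, fig_table):
        p = build_poset(fig_table)
        h = hasse(p)
        assert set(maximal_chains(h)) == SIX_COUNTY_STRUCTURE["chains"]
        assert isolated_elements(p) == frozenset({"ZLT"})


# ------------------------------------------------------------------ LPOM0
class TestLpomAverageRank:
    def test_chain_gets_exact_positions(self):
        p = Poset.from_relations("abc", [("a", "b"), ("b", "c")])
        rav = lpom_average_rank(p)["Rav"]
        assert rav["a"] == pytest.approx(1.0)
        assert rav["b"] == pytest.approx(2.0)
        assert rav["c"] == pytest.approx(3.0)

    def test_two_antichain_gets_mid_rank(self):
        p = Poset.from_relations("ab", [])
        rav = lpom_average_rank(p)["Rav"]
        assert rav["a"] == rav["b"] == pytest.approx(1.5)

    def test_four_element_poset_hand_values(self):
        # a < c, b < c, b < d
        p = Poset.from_relations("abcd", [("a", "c"), ("b", "c"), ("b", "d")])
        t = lpom_average_rank(p)
        assert t.loc["a", "Rav"] == pytest.approx(5 / 3)
        assert t.loc["b", "Rav"] == pytest.approx(5 / 4)
        assert t.loc["c", "Rav"] == pytest.approx(15 / 4)
        assert t.loc["d", "Rav"] == pytest.approx(10 / 3)
        # ordering agrees with the exact linear-extension mean ranks
        exact = exact_mean_ranks(p)
        lpom_order = t["Rav"].sort_values().index.tolist()
        exact_order = sorted(exact, key=exact.get)
        assert lpom_order == exact_order

    @pytest.mark.parametrize("n", [2, 4, 6, 8])
    def test_exact_on_chains_and_antichains(self, n):
        elems = [f"e{i}" for i in range(n)]
        chain = Poset.from_relations(
            elems, [(elems[i], elems[i + 1]) for i in range(n - 1)]
        )
        antichain = Poset.from_relations(elems, [])
        for p in (chain, antichain):
            exact = exact_mean_ranks(p)
            rav = lpom_average_rank(p)["Rav"]
            for e in elems:
                assert rav[e] == pytest.approx(exact[e])

    @pytest.mark.parametrize("seed", range(20))
    def test_count_identity_and_rank_bounds(self, seed):
        rng = np.random.default_rng(300 + seed)
        p = random_poset(rng)
        t = lpom_average_rank(p)
        n = p.n
        assert ((t["S"] + t["P"] + t["U"]) == n - 1).all()
        assert (t["Rav"] >= 1.0 - 1e-12).all()
        assert (t["Rav"] <= n + 1e-12).all()
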