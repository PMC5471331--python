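"""Statistical primitives against brute-force oracles and hand calculations."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from drynet.graphstats import (ContingencyTable2x2, GenePartition,
                               cluster_network, fisher_enrichment_one_sided,
                               fowlkes_mallows, go_enrichment, modularity,
                               paired_t_test)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def hypergeom_upper_tail_oracle(a, module_total, b, nonmodule_total):
    """Exhaustive enumeration of P(X >= a) from the hypergeometric pmf."""
    N = module_total + nonmodule_total
    K = a + b
    n = module_total
    total = 0.0
    for k in range(a, min(K, n) + 1):
        total += math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
    return total


def fm_oracle(p1: dict, p2: dict) -> float:
    """Pair-counting Fowlkes-Mallows."""
    tp = fp = fn = 0
    for a, b in itertools.combinations(sorted(p1), 2):
        same1 = p1[a] == p1[b]
        same2 = p2[a] == p2[b]
        tp += same1 and same2
        fp += same1 and not same2
        fn += same2 and not same1
    if tp == 0:
        return 0.0
    return tp / math.sqrt((tp + fp) * (tp + fn))


def set_partitions(items):
    """All partitions of a small collection (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


# ---------------------------------------------------------------------------
# clustering & modularity
# ---------------------------------------------------------------------------

class TestClustering:
    def test_two_cliques_recovered(self):
        g = nx.Graph()
        for block, offset in ((range(5), 0), (range(5), 5)):
            for i, j in itertools.combinations(block, 2):
                g.add_edge(f"n{i + offset}", f"n{j + offset}", weight=1.0)
        g.add_edge("n0", "n5", weight=1.0)
        part = cluster_network(g, rng_seed=0)
        clusters = {frozenset(m) for m in part.clusters().values()}
        assert clusters == {
            frozenset(f"n{i}" for i in range(5)),
            frozenset(f"n{i}" for i in range(5, 10)),
        }

    def test_partition_beats_trivial_partition(self):
        g = nx.karate_club_graph()
        g = nx.relabel_nodes(g, {n: f"g{n}" for n in g.nodes})
        part = cluster_network(g, rng_seed=3)
        trivial = GenePartition({n: 0 for n in g.nodes})
        assert modularity(g, part) > modularity(g, trivial) == 0.0

    def test_seeded_reproducibility(self):
        g = nx.random_geometric_graph(40, 0.3, seed=5)
        g = nx.relabel_nodes(g, {n: f"g{n}" for n in g.nodes})
        p1 = cluster_network(g, rng_seed=11)
        p2 = cluster_network(g, rng_seed=11)
        assert p1.membership == p2.membership

    def test_isolated_nodes_become_singletons(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        g.add_node("lonely")
        part = cluster_network(g, rng_seed=0)
        assert part.membership["lonely"] not in {
            part.membership["a"], part.membership["b"]
        }


class TestModularity:
    def test_single_cluster_is_zero(self):
        g = nx.complete_graph(4)
        part = GenePartition({n: 0 for n in g.nodes})
        assert modularity(g, part) == pytest.approx(0.0)

    def test_two_disconnected_triangles(self):
        g = nx.Graph()
        for i, j in itertools.combinations(range(3), 2):
            g.add_edge(i, j)
            g.add_edge(i + 3, j + 3)
        part = GenePartition({n: n // 3 for n in g.nodes})
        # per clique: e_c/m = 0.5 and (d_c/2m)^2 = 0.25 -> Q = 2*(0.5-0.25)
        assert modularity(g, part) == pytest.approx(0.5)

    def test_exhaustive_optimum_on_small_graph(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
        best = max(
            modularity(g, GenePartition(
                {n: i for i, block in enumerate(part) for n in block}))
            for part in set_partitions(g.nodes)
        )
        found = modularity(g, cluster_network(g, rng_seed=0))
        assert found == pytest.approx(best)

    def test_edgeless_graph_rejected(self):
        g = nx.Graph()
        g.add_node("a")
        with pytest.raises(ValueError, match="edgeless"):
            modularity(g, GenePartition({"a": 0}))


# ---------------------------------------------------------------------------
# Fowlkes-Mallows
# ---------------------------------------------------------------------------

class TestFowlkesMallows:
    def test_identical_partitions_score_one(self):
        p = GenePartition({"a": 0, "b": 0, "c": 1, "d": 1})
        assert fowlkes_mallows(p, p) == pytest.approx(1.0)

    def test_hand_counted_example(self):
        p1 = GenePartition({"a": 0, "b": 0, "c": 1, "d": 1})
        p2 = GenePartition({"a": 0, "b": 0, "c": 0, "d": 1})
        # TP=1 (ab), FP=1 (cd), FN=2 (ac, bc) -> 1/sqrt(6)
        assert fowlkes_mallows(p1, p2) == pytest.approx(1 / math.sqrt(6))

    def test_all_singletons_score_zero(self):
        p1 = GenePartition({"a": 0, "b": 1, "c": 2})
        p2 = GenePartition({"a": 0, "b": 0, "c": 0})
        assert fowlkes_mallows(p1, p2) == 0.0

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError, match="universes"):
            fowlkes_mallows(GenePartition({"a": 0}), GenePartition({"b": 0}))

    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)),
                    min_size=2, max_size=12))
    def test_matches_pair_counting_oracle(self, labels):
        p1 = {f"g{i}": a for i, (a, _) in enumerate(labels)}
        p2 = {f"g{i}": b for i, (_, b) in enumerate(labels)}
        got = fowlkes_mallows(GenePartition(p1), GenePartition(p2))
        assert got == pytest.approx(fm_oracle(p1, p2), abs=1e-12)
        assert got == pytest.approx(
            fowlkes_mallows(GenePartition(p2), GenePartition(p1)))


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------

class TestFisherEnrichment:
    def test_tiny_exhaustive_case(self):
        # N=6, K=3, n=3: P(X>=2) = 9/20 + 1/20 = 0.5
        p = fisher_enrichment_one_sided(ContingencyTable2x2(2, 3, 1, 3))
        assert p == pytest.approx(0.5)

    @given(st.integers(1, 30), st.integers(1, 30),
           st.integers(0, 30), st.data())
    def test_matches_enumeration_oracle(self, module_total, nonmodule_total,
                                        b, data):
        b = min(b, nonmodule_total)
        a = data.draw(st.integers(0, module_total))
        if a + b > module_total + nonmodule_total:
            return
        got = fisher_enrichment_one_sided(
            ContingencyTable2x2(a, module_total, b, nonmodule_total))
        want = hypergeom_upper_tail_oracle(a, module_total, b, nonmodule_total)
        assert got == pytest.approx(want, rel=1e-9)

    def test_impossible_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(5, 3, 0, 10)


class TestGoEnrichment:
    def test_closed_form_extreme_table(self):
        universe = [f"g{i}" for i in range(100)]
        annot = {g: frozenset({"T"}) for g in universe[:10]}
        table, (term, p) = go_enrichment(universe[:10], annot, universe)
        assert term == "T"
        assert p == pytest.approx(1 / math.comb(100, 10), rel=1e-9)

    def test_universal_term_not_enriched(self):
        universe = [f"g{i}" for i in range(20)]
        annot = {g: frozenset({"T"}) for g in universe}
        _, (term, p) = go_enrichment(universe[:5], annot, universe)
        assert p == pytest.approx(1.0)

    def test_unannotated_cluster_has_no_best_term(self):
        universe = ["a", "b", "c"]
        with pytest.raises(ValueError, match="no annotated"):
            go_enrichment(["a"], {"c": frozenset({"T"})}, universe)

    def test_ties_break_lexicographically(self):
        universe = [f"g{i}" for i in range(10)]
        annot = {g: frozenset({"TB", "TA"}) for g in universe[:4]}
        _, (term, _) = go_enrichment(universe[:4], annot, universe)
        assert term == "TA"


# ---------------------------------------------------------------------------
# paired t-test
# ---------------------------------------------------------------------------

class TestPairedT:
    def test_null_exactly_true(self):
        x = [1.0, 2.0, 3.0]
        assert paired_t_test(x, x) == (0.0, 1.0)

    def test_closed_form_statistic(self):
        x = np.array([2.0, 4.0, 6.0])
        y = x - np.array([1.0, 2.0, 3.0])  # differences (1, 2, 3)
        t, p = paired_t_test(x, y, alternative="greater")
        assert t == pytest.approx(2 * math.sqrt(3))
        assert p == pytest.approx(float(stats.t.sf(2 * math.sqrt(3), df=2)))

    def test_swapping_flips_sign(self):
        x = [1.0, 5.0, 2.0, 8.0]
        y = [0.5, 4.0, 3.0, 6.0]
        t1, _ = paired_t_test(x, y)
        t2, _ = paired_t_test(y, x)
        assert t1 == pytest.approx(-t2)

    def test_degenerate_nonzero_differences_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_t_test([2.0, 3.0], [1.0, 2.0])
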