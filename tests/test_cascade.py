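"""Network augmentation, cascade tree construction, hubs and major paths."""

import networkx as nx
import numpy as np
import pytest

from drynet.cascade import (augment_network, build_cascade_tree,
                            check_coherency, find_hub_tfs, find_major_paths)

from conftest import toy_annotation, toy_expression

TS_COLUMNS = ["W0", "W1", "W6", "E0", "E1", "E6"]


def graph_from(edges, tfs):
    g = nx.Graph()
    for a, b, w in edges:
        g.add_edge(a, b, weight=w)
    for n in g.nodes:
        g.nodes[n]["is_tf"] = n in tfs
    return g


class TestAugment:
    def test_no_qualifying_pairs_is_identity(self):
        ts = toy_expression(
            {"r": [1, 2, 3, 4, 5, 6], "a": [1.1, 2, 3, 4, 5, 6.2],
             "x": [5, 1, 4, 2, 6, 3]},
            samples=TS_COLUMNS,
        )
        ann = toy_annotation(ts.index, tfs=("r",))
        net = graph_from([("r", "a", 0.9)], tfs={"r"})
        out = augment_network(net, ts, ann, "r", ["a"], cutoff=0.5)
        assert set(out.edges()) == set(net.edges())

    def test_disconnected_gene_connected_through_weaker_edge(self):
        rng = np.random.default_rng(0)
        base = np.array([1.0, 2, 3, 4, 5, 6])
        # g correlates ~0.6 with TF r: below a 0.67 build cutoff, above 0.5
        g_vec = base + rng.normal(0, 2.0, 6)
        while not 0.5 < abs(np.corrcoef(base, g_vec)[0, 1]) < 0.67:
            g_vec = base + rng.normal(0, 2.0, 6)
        ts = toy_expression({"r": base, "a": base * 2, "g": g_vec},
                            samples=TS_COLUMNS)
        ann = toy_annotation(ts.index, tfs=("r",))
        net = graph_from([("r", "a", 0.95)], tfs={"r"})
        out = augment_network(net, ts, ann, "r", ["g"], cutoff=0.5,
                              transform=None)
        assert out.has_edge("r", "g")

    def test_never_adds_nontf_pairs(self):
        ts = toy_expression(
            {"r": [6, 5, 4, 3, 2, 1], "a": [1, 2, 3, 4, 5, 6],
             "b": [1.1, 2.1, 3, 4, 5, 6]},
            samples=TS_COLUMNS,
        )
        ann = toy_annotation(ts.index, tfs=("r",))
        net = graph_from([("r", "a", -0.9)], tfs={"r"})
        out = augment_network(net, ts, ann, "r", ["b"], cutoff=0.5,
                              transform=None)
        assert not out.has_edge("a", "b")
        assert out.has_edge("r", "b")  # via the TF, |PCC| ~ 1

    def test_root_missing_rejected(self):
        ts = toy_expression({"a": [1, 2, 3, 4, 5, 6]}, samples=TS_COLUMNS)
        ann = toy_annotation(ts.index, tfs=("a",))
        with pytest.raises(ValueError, match="root"):
            augment_network(nx.Graph(), ts, ann, "zz", ["a"])


class TestCoherency:
    def test_identical_networks_score_one(self):
        net = graph_from([("r", "a", 0.9), ("r", "b", 0.8)], tfs={"r"})
        assert check_coherency(net, net, rng_seed=0) == pytest.approx(1.0)

    def test_synthetic_augmentation_keeps_modules(self, pipeline_result):
        assert pipeline_result.summary["coherency_fm"] >= 0.9

    def test_shrunken_universe_rejected(self):
        big = graph_from([("r", "a", 0.9), ("r", "b", 0.8)], tfs={"r"})
        small = graph_from([("r", "a", 0.9)], tfs={"r"})
        with pytest.raises(ValueError):
            check_coherency(big, small)


class TestCascadeTree:
    def test_star_network(self):
        net = graph_from([("r", "a", 0.9), ("r", "b", -0.8), ("r", "c", 0.7)],
                         tfs={"r"})
        tree = build_cascade_tree(net, "r")
        assert tree.max_depth() == 1
        assert all(tree.parent[n] == "r" for n in "abc")
        assert tree.downstream_count("r") == 3

    def test_parent_is_strongest_pcc_neighbor(self):
        net = graph_from(
            [("r", "A", 0.9), ("r", "B", 0.9), ("A", "c", 0.7),
             ("B", "c", -0.8)],
            tfs={"r", "A", "B"},
        )
        tree = build_cascade_tree(net, "r")
        assert tree.depth["c"] == 2
        assert tree.parent["c"] == "B"  # |-0.8| beats |0.7|
        assert tree.pcc["c"] == -0.8

    def test_tie_breaks_prefer_positive_then_lexicographic(self):
        net = graph_from(
            [("r", "A", 0.9), ("r", "B", 0.9), ("A", "c", -0.8),
             ("B", "c", 0.8)],
            tfs={"r", "A", "B"},
        )
        tree = build_cascade_tree(net, "r")
        assert tree.parent["c"] == "B"  # +0.8 preferred over -0.8

    def test_nontf_cannot_relay_the_cascade(self):
        net = graph_from([("r", "x", 0.9), ("x", "y", 0.9)], tfs={"r"})
        tree = build_cascade_tree(net, "r", {"y": "m1"})
        assert "y" not in tree.depth
        assert tree.unreachable == {"y"}

    def test_non_parent_and_same_level_edges_removed(self):
        net = graph_from(
            [("r", "A", 0.9), ("r", "D", 0.6), ("A", "D", 0.5),
             ("A", "C", 0.7), ("D", "C", 0.95)],
            tfs={"r", "A", "C", "D"},
        )
        tree = build_cascade_tree(net, "r")
        kids = tree.children()
        # C keeps only its strongest depth-1 parent; the alternative path
        # through A and the same-level A-D edge are both discarded
        assert tree.parent["C"] == "D"
        assert kids["A"] == []
        assert "D" not in kids["A"] and "A" not in kids["D"]

    def test_subtree_sizes_partition_reachable_nodes(self):
        net = graph_from(
            [("r", "A", 0.9), ("r", "B", 0.8), ("A", "c", 0.7),
             ("A", "d", 0.7), ("B", "e", 0.6)],
            tfs={"r", "A", "B"},
        )
        tree = build_cascade_tree(net, "r")
        kids = tree.children()["r"]
        assert 1 + sum(len(tree.subtree(k)) for k in kids) == len(tree.nodes)

    def test_nontf_root_rejected(self):
        net = graph_from([("r", "a", 0.9)], tfs=set())
        with pytest.raises(ValueError, match="not a TF"):
            build_cascade_tree(net, "r")


class TestHubs:
    def make_tree(self):
        net = graph_from(
            [("r", "A", 0.9), ("A", "a1", 0.8), ("A", "a2", 0.8),
             ("A", "B", 0.8), ("B", "b1", 0.7), ("B", "b2", 0.7),
             ("B", "b3", 0.7)],
            tfs={"r", "A", "B"},
        )
        return build_cascade_tree(net, "r")

    def test_strictly_more_than_threshold(self):
        tree = self.make_tree()
        hubs = find_hub_tfs(tree, min_downstream=3)
        # A has 6 downstream, B has 3 (strict ">": B excluded)
        assert list(hubs["gene_id"]) == ["r", "A"]
        assert list(hubs["downstream"]) == [7, 6]

    def test_leaf_tf_never_a_hub(self):
        net = graph_from([("r", "A", 0.9)], tfs={"r", "A"})
        tree = build_cascade_tree(net, "r")
        assert "A" not in set(find_hub_tfs(tree, 0)["gene_id"])


class TestMajorPaths:
    def test_single_module_coverage(self):
        net = graph_from(
            [("r", "A", 0.9)] + [("A", f"m{i}", 0.8) for i in range(6)] +
            [("r", f"x{i}", 0.7) for i in range(4)],
            tfs={"r", "A"},
        )
        modules = {f"m{i}": "mod1" for i in range(6)}
        modules.update({f"x{i}": "mod1" for i in range(4)})
        tree = build_cascade_tree(net, "r", modules)
        paths = find_major_paths(tree, modules, min_coverage=0.10)
        assert len(paths) == 1
        assert paths[0].chain == ("r", "A")
        assert paths[0].coverage == pytest.approx(0.6)

    def test_unreachable_bound_gives_empty_list(self):
        net = graph_from([("r", "A", 0.9), ("A", "m0", 0.8),
                          ("r", "x", 0.7)], tfs={"r", "A"})
        modules = {"m0": "mod1", "x": "mod1"}
        tree = build_cascade_tree(net, "r", modules)
        assert find_major_paths(tree, modules, min_coverage=1.0) == []

    def test_deepest_qualifying_chain_reported_once(self):
        net = graph_from(
            [("r", "A", 0.9), ("A", "B", 0.85)] +
            [("B", f"m{i}", 0.8) for i in range(5)],
            tfs={"r", "A", "B"},
        )
        modules = {f"m{i}": "mod1" for i in range(5)}
        tree = build_cascade_tree(net, "r", modules)
        paths = find_major_paths(tree, modules, min_coverage=0.10)
        assert [p.chain for p in paths] == [("r", "A", "B")]

    def test_parent_chain_coverage_dominates_extensions(self):
        net = graph_from(
            [("r", "A", 0.9), ("A", "B", 0.85), ("A", "m0", 0.8)] +
            [("B", f"m{i}", 0.8) for i in range(1, 4)],
            tfs={"r", "A", "B"},
        )
        modules = {f"m{i}": "mod1" for i in range(4)}
        tree = build_cascade_tree(net, "r", modules)
        cov_a = len(tree.subtree("A") & set(modules)) / len(modules)
        cov_b = len(tree.subtree("B") & set(modules)) / len(modules)
        assert cov_a >= cov_b

    def test_empty_module_rejected(self):
        net = graph_from([("r", "A", 0.9)], tfs={"r", "A"})
        tree = build_cascade_tree(net, "r")
        with pytest.raises(ValueError, match="empty"):
            find_major_paths(tree, {}, min_coverage=0.1)


def test_planted_regulator_chains_recovered(pipeline_result):
    """Each planted non-root module is reached root -> hub with high coverage."""
    s = pipeline_result.summary
    assert s["n_major_paths"] >= 4
    assert s["tree_unreachable"] == 0
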