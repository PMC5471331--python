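"""Root-TF-centric cascade trees: hub TFs and major regulatory paths.

The module-bearing condition network is first augmented with weaker edges
(|PCC| > 0.5 in the time-series data) to restore connectivity between the
root TF (the transgene) and the modules, then collapsed level-wise into a
tree: depth is the BFS shortest-path distance from the root over
TF-respecting edges (only TFs can have children), each gene keeps the single
strongest-|PCC| parent one level up, and all other edges — including back
edges to earlier levels — are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .graphstats import GenePartition, cluster_network, fowlkes_mallows, go_enrichment
from .network import _expression_values, _standardize_rows

__all__ = [
    "CascadeTree",
    "RegulatoryPath",
    "augment_network",
    "check_coherency",
    "build_cascade_tree",
    "find_hub_tfs",
    "find_major_paths",
]


@dataclass
class CascadeTree:
    """Rooted tree over network genes.

    ``parent`` maps every non-root node to its chosen parent, ``pcc`` to the
    parent edge's correlation, ``depth`` to the edge count from the root.
    """

    root: str
    parent: dict[str, str]
    depth: dict[str, int]
    pcc: dict[str, float]
    is_tf: dict[str, bool]
    module: dict[str, str] = field(default_factory=dict)
    unreachable: set[str] = field(default_factory=set)

    @property
    def nodes(self) -> set[str]:
        return set(self.depth)

    def children(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {node: [] for node in self.depth}
        for child, par in self.parent.items():
            out[par].append(child)
        for kids in out.values():
            kids.sort()
        return out

    def subtree(self, node: str) -> set[str]:
        """Node plus all its descendants."""
        kids = self.children()
        out, stack = set(), [node]
        while stack:
            cur = stack.pop()
            out.add(cur)
            stack.extend(kids[cur])
        return out

    def downstream_count(self, node: str) -> int:
        return len(self.subtree(node)) - 1

    def max_depth(self) -> int:
        return max(self.depth.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g,
                "parent": self.parent.get(g, ""),
                "depth": self.depth[g],
                "pcc": self.pcc.get(g, np.nan),
                "is_tf": self.is_tf[g],
                "module": self.module.get(g, ""),
            }
            for g in sorted(self.depth, key=lambda g: (self.depth[g], g))
        ]
        return pd.DataFrame(rows)


@dataclass
class RegulatoryPath:
    """A root-to-TF chain covering a substantial fraction of one module."""

    chain: tuple[str, ...]
    module: str
    coverage: float
    n_covered: int
    go_term: str | None = None
    go_p: float | None = None


def augment_network(
    network: nx.Graph,
    ts: pd.DataFrame,
    annotation: pd.DataFrame,
    root: str,
    target_genes: Iterable[str],
    cutoff: float = 0.5,
    transform: str | None = "log2",
    floor: float = 1.0,
) -> nx.Graph:
    """Add weaker time-series edges to reconnect target genes to the root.

    New TF-involving edges with |PCC| > cutoff in ``ts`` are added whenever
    they touch a target gene not currently connected to the root's
    component. Original edges are kept untouched; TF-TF edges may appear but
    nonTF-nonTF pairs never do.
    """
    if root not in network:
        raise ValueError(f"root {root!r} absent from network")
    built_at = network.graph.get("cutoff")
    if built_at is not None and cutoff > built_at:
        raise ValueError("augmentation cutoff must not exceed the build cutoff")
    target_genes = set(target_genes)
    reached = nx.node_connected_component(network, root)
    unreached = target_genes - reached
    out = network.copy()
    if not unreached:
        return out

    genes = [g for g in ts.index if g in set(network.nodes) | target_genes]
    sub = ts.loc[genes]
    values = _expression_values(sub, transform, floor)
    z, defined = _standardize_rows(values)
    is_tf = annotation.loc[genes, "is_tf"].to_numpy(dtype=bool)
    tf_idx = np.flatnonzero(is_tf & defined)
    corr = (z[tf_idx] @ z.T) / values.shape[1]
    np.clip(corr, -1.0, 1.0, out=corr)
    corr[:, ~defined] = 0.0

    gene_arr = np.asarray(genes)
    rows, cols = np.nonzero(np.abs(corr) > cutoff)
    for r, c in zip(rows, cols):
        a, b = gene_arr[tf_idx[r]], gene_arr[c]
        if a == b or out.has_edge(a, b):
            continue
        if a not in unreached and b not in unreached:
            continue
        out.add_edge(a, b, weight=float(corr[r, c]))
    for node in out.nodes:
        out.nodes[node].setdefault("is_tf", bool(annotation.at[node, "is_tf"]))
    return out


def check_coherency(before: nx.Graph, after: nx.Graph, rng_seed: int = 0) -> float:
    """Fowlkes-Mallows coherency of the clustering before vs after augmentation.

    Both networks are clustered with the same seed; the comparison runs on
    the genes of the pre-augmentation network (the augmented one may have
    grown).
    """
    if not set(before.nodes) <= set(after.nodes):
        raise ValueError("augmented network must contain all original genes")
    p_before = cluster_network(before, rng_seed=rng_seed)
    p_after = cluster_network(after, rng_seed=rng_seed)
    restricted = GenePartition(
        {g: p_after.membership[g] for g in p_before.membership}
    )
    return fowlkes_mallows(p_before, restricted)


def build_cascade_tree(
    network: nx.Graph,
    root: str,
    module_genes: Mapping[str, str] | None = None,
) -> CascadeTree:
    """Collapse a network into a cascade tree rooted at a TF.

    Depth is BFS distance from the root where edges emanate from TFs only (a
    nonTF gene cannot relay the cascade). Each non-root node keeps the single
    parent one level up with the greatest |PCC|, ties broken by larger
    signed PCC then lexicographically; every other edge, back edges
    included, is dropped. Module genes that cannot be reached are recorded in
    ``tree.unreachable``.
    """
    if root not in network:
        raise ValueError(f"root {root!r} absent from network")
    if not network.nodes[root].get("is_tf", False):
        raise ValueError(f"root {root!r} is not a TF")

    depth: dict[str, int] = {root: 0}
    frontier = [root]
    level = 0
    while frontier:
        nxt = []
        for node in frontier:
            if not network.nodes[node].get("is_tf", False):
                continue  # nonTFs are leaves of the cascade
            for nb in network.neighbors(node):
                if nb not in depth:
                    depth[nb] = level + 1
                    nxt.append(nb)
        frontier = nxt
        level += 1

    parent: dict[str, str] = {}
    pcc: dict[str, float] = {}
    for node, d in depth.items():
        if node == root:
            continue
        candidates = [
            (nb, network[node][nb]["weight"])
            for nb in network.neighbors(node)
            if depth.get(nb) == d - 1 and network.nodes[nb].get("is_tf", False)
        ]
        # greatest |PCC|; ties -> larger signed PCC, then lexicographic id
        best = min(candidates, key=lambda item: (-abs(item[1]), -item[1], item[0]))
        parent[node], pcc[node] = best[0], float(best[1])

    module = dict(module_genes) if module_genes else {}
    unreachable = set(module) - set(depth)
    return CascadeTree(
        root=root,
        parent=parent,
        depth=depth,
        pcc=pcc,
        is_tf={g: bool(network.nodes[g].get("is_tf", False)) for g in depth},
        module={g: m for g, m in module.items() if g in depth},
        unreachable=unreachable,
    )


def find_hub_tfs(tree: CascadeTree, min_downstream: int = 200) -> pd.DataFrame:
    """TFs with strictly more than ``min_downstream`` genes in their subtree.

    Sorted by downstream count descending (gene id breaks ties). The root
    qualifies like any other TF.
    """
    rows = []
    for gene in sorted(tree.nodes):
        if not tree.is_tf[gene]:
            continue
        count = tree.downstream_count(gene)
        if count > min_downstream:
            rows.append({"gene_id": gene, "downstream": count,
                         "depth": tree.depth[gene]})
    out = pd.DataFrame(rows, columns=["gene_id", "downstream", "depth"])
    return out.sort_values(["downstream", "gene_id"],
                           ascending=[False, True]).reset_index(drop=True)


def _chain_to(tree: CascadeTree, node: str) -> tuple[str, ...]:
    chain = [node]
    while chain[-1] != tree.root:
        chain.append(tree.parent[chain[-1]])
    return tuple(reversed(chain))


def find_major_paths(
    tree: CascadeTree,
    modules: Mapping[str, str],
    min_coverage: float = 0.10,
    go_annot: Mapping[str, frozenset[str]] | None = None,
    universe: Iterable[str] | None = None,
) -> list[RegulatoryPath]:
    """Root-to-TF chains whose subtree covers > ``min_coverage`` of a module.

    For every module, the deepest qualifying TF along each branch is
    reported once (a parent chain always covers at least as much as any of
    its extensions, so reporting prefixes would be redundant). When GO
    annotation is supplied, the most significant term of the covered genes
    is attached.
    """
    if not modules:
        raise ValueError("empty module assignment")
    by_module: dict[str, set[str]] = {}
    for gene, label in modules.items():
        by_module.setdefault(label, set()).add(gene)
    for label, members in by_module.items():
        if not members:
            raise ValueError(f"module {label!r} is empty")

    subtrees = {g: tree.subtree(g) for g in tree.nodes
                if tree.is_tf[g] and g != tree.root}
    paths: list[RegulatoryPath] = []
    for label in sorted(by_module):
        members = by_module[label]
        qualifying = {
            tf for tf, sub in subtrees.items()
            if len(sub & members) / len(members) > min_coverage
        }
        # keep only TFs with no qualifying strict descendant (deepest chains)
        deepest = {
            tf for tf in qualifying
            if not any(other != tf and other in subtrees[tf] for other in qualifying)
        }
        for tf in sorted(deepest):
            covered = sorted(subtrees[tf] & members)
            go_term: str | None = None
            go_p: float | None = None
            if go_annot is not None:
                uni = list(universe) if universe is not None else sorted(tree.nodes)
                try:
                    _, (go_term, go_p) = go_enrichment(covered, go_annot, uni)
                except ValueError:
                    pass
            paths.append(
                RegulatoryPath(
                    chain=_chain_to(tree, tf),
                    module=label,
                    coverage=len(covered) / len(members),
                    n_covered=len(covered),
                    go_term=go_term,
                    go_p=go_p,
                )
            )
    paths.sort(key=lambda p: (p.module, -p.coverage, p.chain))
    return paths


def paths_to_frame(paths: list[RegulatoryPath]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "module": p.module,
                "chain": "->".join(p.chain),
                "coverage": p.coverage,
                "n_covered": p.n_covered,
                "go_term": p.go_term,
                "go_p": p.go_p,
            }
            for p in paths
        ]
    )
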