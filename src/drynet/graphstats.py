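"""Graph clustering and shared statistical primitives.

Multi-level (Louvain) modularity clustering, Newman modularity, the
Fowlkes-Mallows partition-coherency index, the one-sided Fisher /
hypergeometric enrichment test, GO term enrichment, and the paired t-test.
These are the building blocks every later stage composes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import fowlkes_mallows_score

__all__ = [
    "GenePartition",
    "ContingencyTable2x2",
    "cluster_network",
    "modularity",
    "fowlkes_mallows",
    "fisher_enrichment_one_sided",
    "go_enrichment",
    "paired_t_test",
]


@dataclass
class GenePartition:
    """Disjoint assignment of genes to clusters."""

    membership: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.membership = dict(self.membership)

    @property
    def genes(self) -> set[str]:
        return set(self.membership)

    def cluster_ids(self) -> list[int]:
        return sorted(set(self.membership.values()))

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for gene, cid in self.membership.items():
            out.setdefault(cid, []).append(gene)
        for members in out.values():
            members.sort()
        return out

    def sizes(self) -> dict[int, int]:
        return {cid: len(m) for cid, m in self.clusters().items()}

    def __len__(self) -> int:
        return len(self.membership)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for a module association test.

    ``a`` genes of the query set inside the module (of ``module_total``
    genes), ``b`` query genes outside it (of ``nonmodule_total`` genes).
    """

    a: int
    module_total: int
    b: int
    nonmodule_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.a <= self.module_total):
            raise ValueError(f"need 0 <= a <= module_total, got {self}")
        if not (0 <= self.b <= self.nonmodule_total):
            raise ValueError(f"need 0 <= b <= nonmodule_total, got {self}")


def cluster_network(network: nx.Graph, rng_seed: int = 0,
                    weighted: bool = False) -> GenePartition:
    """Multi-level modularity (Louvain) clustering of the gene network.

    Runs on the unweighted edge set by default (the network is already
    thresholded; connectivity is the signal). Isolated nodes come back as
    singleton clusters. Deterministic for a fixed ``rng_seed``.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty network")
    weight = "weight" if weighted else None
    communities = nx.community.louvain_communities(
        network, weight=weight, seed=int(rng_seed)
    )
    # stable cluster ids: order communities by their smallest member
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    membership = {g: cid for cid, members in enumerate(communities) for g in members}
    return GenePartition(membership)


def modularity(network: nx.Graph, partition: GenePartition) -> float:
    """Newman modularity Q of a partition on the unweighted graph."""
    if network.number_of_edges() == 0:
        raise ValueError("modularity is undefined on an edgeless network")
    if set(network.nodes) - partition.genes:
        raise ValueError("partition does not cover all network nodes")
    communities = [set(m) for m in partition.clusters().values()]
    return float(nx.community.modularity(network, communities, weight=None))


def fowlkes_mallows(p1: GenePartition, p2: GenePartition) -> float:
    """Fowlkes-Mallows coherency TP/sqrt((TP+FP)(TP+FN)) over co-clustered pairs.

    Both partitions must cover the same gene universe. All-singleton
    partitions have no co-clustered pairs and score 0.
    """
    if p1.genes != p2.genes:
        raise ValueError("partitions cover different gene universes")
    genes = sorted(p1.genes)
    if len(genes) < 2:
        return 1.0
    a = [p1.membership[g] for g in genes]
    b = [p2.membership[g] for g in genes]
    return float(fowlkes_mallows_score(a, b))


def fisher_enrichment_one_sided(table: ContingencyTable2x2) -> float:
    """Exact hypergeometric upper tail P(X >= a).

    Population ``N = module_total + nonmodule_total``, successes
    ``K = a + b`` (the query set), draws ``n = module_total`` (the module).
    This is the enrichment-only version of Fisher's exact test; a depleted
    table scores near 1.
    """
    N = table.module_total + table.nonmodule_total
    K = table.a + table.b
    n = table.module_total
    if K > N:
        raise ValueError("query set larger than the population")
    return float(stats.hypergeom.sf(table.a - 1, N, K, n))


def go_enrichment(
    member_genes: Iterable[str],
    go_annot: Mapping[str, frozenset[str]],
    universe: Iterable[str],
) -> tuple[pd.DataFrame, tuple[str, float]]:
    """One-sided GO enrichment of a gene cluster against a universe.

    For every GO term annotated to at least one member, tests whether the
    term's gene set is over-represented in the cluster. Returns the per-term
    table and the best (minimum p) term, ties broken lexicographically by
    term id. Raw p-values; no multiple-testing correction is applied, since
    downstream selection uses fixed raw thresholds.
    """
    members = sorted(set(member_genes))
    if not members:
        raise ValueError("empty member set")
    universe = set(universe)
    if not set(members) <= universe:
        raise ValueError("member genes must be contained in the universe")
    term_universe: dict[str, set[str]] = {}
    for gene in universe:
        for term in go_annot.get(gene, ()):  # genes may be unannotated
            term_universe.setdefault(term, set()).add(gene)
    member_set = set(members)
    rows = []
    for term in sorted(term_universe):
        in_members = len(term_universe[term] & member_set)
        if in_members == 0:
            continue
        table = ContingencyTable2x2(
            a=in_members,
            module_total=len(members),
            b=len(term_universe[term]) - in_members,
            nonmodule_total=len(universe) - len(members),
        )
        rows.append(
            {
                "term": term,
                "a": in_members,
                "term_total": len(term_universe[term]),
                "cluster_size": len(members),
                "universe_size": len(universe),
                "p": fisher_enrichment_one_sided(table),
            }
        )
    result = pd.DataFrame(rows, columns=["term", "a", "term_total", "cluster_size",
                                         "universe_size", "p"])
    if result.empty:
        raise ValueError("cluster has no annotated genes; best term undefined")
    best = result.sort_values(["p", "term"], kind="stable").iloc[0]
    return result, (str(best["term"]), float(best["p"]))


def paired_t_test(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Paired t-test: one-sample t on d = x - y with df = n - 1.

    ``alternative`` is "two-sided", "greater" (H1: mean x > mean y) or
    "less". When every difference is identical the statistic is degenerate:
    a zero mean difference returns (0, 1); a nonzero one raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = x - y
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            return 0.0, 1.0
        raise ValueError("all differences equal and nonzero: t is degenerate")
    res = stats.ttest_rel(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
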