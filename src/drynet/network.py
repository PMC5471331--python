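"""Correlation-thresholded TF network construction and cutoff selection.

A TF network connects transcription factors to putative target genes whose
expression profiles are strongly correlated (|PCC| strictly above a cutoff);
edges between two non-TF genes are never included. A *template* network is
built on a large expression compendium; a *condition* network keeps only the
template edges that remain strongly correlated in condition-specific data.
The cutoff itself is chosen by scanning a grid and maximizing the
functionality score, a cluster-size-weighted mean of -log10 of each
cluster's best GO enrichment p-value.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graphstats import GenePartition, cluster_network, go_enrichment

__all__ = [
    "UndefinedCorrelationError",
    "pearson_correlation",
    "build_network",
    "functionality_score",
    "scan_cutoffs",
    "subsample_convergence",
]

logger = logging.getLogger("drynet.network")


class UndefinedCorrelationError(ValueError):
    """Correlation is undefined (constant input vector)."""


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length sample vectors.

    Raises :class:`UndefinedCorrelationError` for constant vectors, which
    callers treat as "no edge": zero-variance genes are common in FPKM data
    and must not propagate NaN into the edge set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 samples")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelationError("constant vector has no defined correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    return max(-1.0, min(1.0, r))


def _expression_values(expr: pd.DataFrame, transform: str | None,
                       floor: float) -> np.ndarray:
    values = expr.to_numpy(dtype=float)
    if transform == "log2":
        values = np.log2(values + floor)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    return values


def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardize; returns (z, defined) where constant rows are flagged."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    defined = sd[:, 0] > 0.0
    sd[~defined] = 1.0
    z = (values - mean) / sd
    return z, defined


def build_network(
    expr: pd.DataFrame,
    annotation: pd.DataFrame,
    cutoff: float,
    restrict_to: nx.Graph | None = None,
    transform: str | None = None,
    floor: float = 1.0,
) -> nx.Graph:
    """Build a TF network at a strict |PCC| cutoff.

    An unordered pair (g, h) becomes an edge iff at least one of g, h is a
    TF, |PCC(g, h)| > cutoff (strictly), and — when ``restrict_to`` is given
    — (g, h) is an edge of that graph. Edge weight is the signed PCC in
    ``expr``. ``transform="log2"`` correlates log2(x + floor), the treatment
    applied to FPKM-scale RNA-seq data; the compendium is used as provided.
    Nodes are the edge endpoints, flagged with ``is_tf``.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to build a network")
    missing = set(expr.index) - set(annotation.index)
    if missing:
        raise ValueError(f"annotation missing genes, e.g. {sorted(missing)[:3]}")
    genes = expr.index.to_numpy()
    is_tf = annotation.loc[genes, "is_tf"].to_numpy(dtype=bool)
    if not is_tf.any():
        raise ValueError("no TFs annotated among expression genes")

    values = _expression_values(expr, transform, floor)
    z, defined = _standardize_rows(values)
    n = values.shape[1]

    tf_idx = np.flatnonzero(is_tf & defined)
    corr = (z[tf_idx] @ z.T) / n  # TF x all genes
    np.clip(corr, -1.0, 1.0, out=corr)
    corr[:, ~defined] = 0.0

    allowed = None
    if restrict_to is not None:
        allowed = {frozenset(e) for e in restrict_to.edges()}

    graph = nx.Graph()
    rows, cols = np.nonzero(np.abs(corr) > cutoff)
    for r, c in zip(rows, cols):
        a, b = genes[tf_idx[r]], genes[c]
        if a == b:
            continue
        if allowed is not None and frozenset((a, b)) not in allowed:
            continue
        graph.add_edge(a, b, weight=float(corr[r, c]))
    for node in graph.nodes:
        graph.nodes[node]["is_tf"] = bool(annotation.at[node, "is_tf"])
    graph.graph["cutoff"] = float(cutoff)
    logger.info(
        "built network at |PCC|>%g: %d genes, %d edges",
        cutoff, graph.number_of_nodes(), graph.number_of_edges(),
    )
    return graph


def functionality_score(
    partition: GenePartition,
    best_p: Mapping[int, float],
    n_genes: int | None = None,
) -> float:
    """Cluster-size-weighted mean of -log10(best GO p) over a partition.

    ``score = -sum_i (|c_i| / N) * log10(p_ci)`` where N is the number of
    genes in the network and p_ci the best GO enrichment p-value of cluster
    c_i. High scores mean the network splits into large, functionally
    coherent clusters. Clusters absent from ``best_p`` contribute p = 1
    (score 0): a cluster with no annotated member carries no evidence.
    """
    sizes = partition.sizes()
    n = len(partition) if n_genes is None else int(n_genes)
    if n <= 0:
        raise ValueError("N must be positive")
    score = 0.0
    for cid, size in sizes.items():
        p = best_p.get(cid, 1.0)
        if not 0.0 < p <= 1.0:
            raise ValueError(f"best GO p for cluster {cid} must be in (0, 1], got {p}")
        score -= size / n * np.log10(p)
    return float(score)


def _network_go_score(
    graph: nx.Graph,
    go_annot: Mapping[str, frozenset[str]],
    rng_seed: int,
) -> tuple[float, GenePartition]:
    partition = cluster_network(graph, rng_seed=rng_seed)
    universe = sorted(graph.nodes)
    best_p: dict[int, float] = {}
    for cid, members in partition.clusters().items():
        try:
            _, (_, p) = go_enrichment(members, go_annot, universe)
        except ValueError:  # no annotated genes in cluster
            continue
        best_p[cid] = p
    return functionality_score(partition, best_p), partition


def scan_cutoffs(
    expr: pd.DataFrame,
    annotation: pd.DataFrame,
    go_annot: Mapping[str, frozenset[str]],
    cutoffs: Iterable[float],
    rng_seed: int = 0,
    transform: str | None = None,
    floor: float = 1.0,
) -> pd.DataFrame:
    """Score a grid of |PCC| cutoffs by functionality score.

    For each cutoff: build the network, cluster it, GO-test every cluster,
    and compute the functionality score. Returns a table (cutoff, score,
    n_genes, n_edges, n_clusters); the argmax cutoff is stored in
    ``result.attrs["argmax_cutoff"]``. Empty networks score 0 with a warning.
    """
    cutoffs = sorted(float(c) for c in cutoffs)
    if not cutoffs or not all(0.0 < c < 1.0 for c in cutoffs):
        raise ValueError("cutoff grid must lie within (0, 1)")
    rows = []
    for cutoff in cutoffs:
        graph = build_network(expr, annotation, cutoff, transform=transform, floor=floor)
        if graph.number_of_edges() == 0:
            logger.warning("empty network at cutoff %g; score recorded as 0", cutoff)
            rows.append({"cutoff": cutoff, "score": 0.0, "n_genes": 0,
                         "n_edges": 0, "n_clusters": 0})
            continue
        score, partition = _network_go_score(graph, go_annot, rng_seed)
        rows.append(
            {
                "cutoff": cutoff,
                "score": score,
                "n_genes": graph.number_of_nodes(),
                "n_edges": graph.number_of_edges(),
                "n_clusters": len(partition.cluster_ids()),
            }
        )
    result = pd.DataFrame(rows)
    result.attrs["argmax_cutoff"] = float(result.loc[result["score"].idxmax(), "cutoff"])
    return result


def subsample_convergence(
    expr: pd.DataFrame,
    annotation: pd.DataFrame,
    sizes: Sequence[int],
    replicates: int,
    cutoff: float,
    rng_seed: int = 0,
    transform: str | None = None,
    floor: float = 1.0,
) -> pd.DataFrame:
    """Edge-set agreement of networks built on random sample subsets.

    For each size, draws ``replicates`` random subsets of samples (without
    replacement, seeded), builds a network on each, and reports the mean
    pairwise Jaccard agreement of the edge sets. Pearson correlations
    converge with sample size, so agreement rises toward 1; drawing the full
    compendium leaves no sampling variation and scores exactly 1.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    n_samples = expr.shape[1]
    rng = np.random.default_rng(rng_seed)
    rows = []
    for size in sizes:
        size = int(size)
        if size < 3:
            raise ValueError("subsample size must be at least 3")
        if size > n_samples:
            raise ValueError(f"subsample size {size} exceeds {n_samples} samples")
        edge_sets = []
        for _ in range(replicates):
            cols = rng.choice(n_samples, size=size, replace=False)
            sub = expr.iloc[:, np.sort(cols)]
            graph = build_network(sub, annotation, cutoff,
                                  transform=transform, floor=floor)
            edge_sets.append({frozenset(e) for e in graph.edges()})
        agreements = []
        for i in range(replicates):
            for j in range(i + 1, replicates):
                union = edge_sets[i] | edge_sets[j]
                if not union:
                    agreements.append(1.0)  # two empty networks agree
                else:
                    agreements.append(len(edge_sets[i] & edge_sets[j]) / len(union))
        rows.append({"size": size, "mean_jaccard": float(np.mean(agreements)),
                     "n_pairs": len(agreements)})
    return pd.DataFrame(rows)
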