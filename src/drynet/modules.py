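"""Phenotype-differential networks and differential module selection.

Node values are log2 expression changes: within a genotype between two time
points (e.g. log2(W1/W0)), or the between-genotype difference of two such
changes (log2(E1/E0) - log2(W1/W0)). Clusters of the condition network are
tested for differential expression (paired t-test across member genes,
pairing the two genotypes' within-genotype changes by gene) and for GO
enrichment; clusters significant in BOTH tests at the module threshold
(default p < 1e-9) are designated modules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .graphstats import GenePartition, go_enrichment, paired_t_test

__all__ = [
    "ContrastSpec",
    "ModuleReport",
    "instantiate_node_values",
    "node_value_table",
    "global_shift_test",
    "test_clusters",
    "deg_count",
]


@dataclass(frozen=True)
class ContrastSpec:
    """A within- or between-genotype expression contrast.

    ``within``: value = log2(num/den), e.g. num="W1", den="W0".
    ``between``: value = log2(num/den) - log2(num2/den2), the canonical case
    being log2(E1/E0) - log2(W1/W0).
    """

    kind: str
    num: str
    den: str
    num2: str | None = None
    den2: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("within_genotype", "between_genotype"):
            raise ValueError(f"unknown contrast kind {self.kind!r}")
        if self.kind == "between_genotype" and (self.num2 is None or self.den2 is None):
            raise ValueError("between-genotype contrast needs a second sample pair")

    @classmethod
    def parse(cls, text: str) -> "ContrastSpec":
        """Parse "W1/W0" (within) or "E1/E0-vs-W1/W0" (between)."""
        m = re.fullmatch(r"(\w+)/(\w+)-vs-(\w+)/(\w+)", text)
        if m:
            return cls("between_genotype", m.group(1), m.group(2),
                       m.group(3), m.group(4))
        m = re.fullmatch(r"(\w+)/(\w+)", text)
        if m:
            return cls("within_genotype", m.group(1), m.group(2))
        raise ValueError(f"cannot parse contrast {text!r}")

    def label(self) -> str:
        if self.kind == "within_genotype":
            return f"log2({self.num}/{self.den})"
        return f"log2({self.num}/{self.den})-log2({self.num2}/{self.den2})"

    def samples(self) -> list[str]:
        out = [self.num, self.den]
        if self.kind == "between_genotype":
            out += [self.num2, self.den2]
        return out


def _log_ratio(ts: pd.DataFrame, num: str, den: str, floor: float) -> pd.Series:
    return np.log2((ts[num] + floor) / (ts[den] + floor))


def node_value_table(ts: pd.DataFrame, contrast: ContrastSpec,
                     floor: float = 1.0) -> pd.Series:
    """Per-gene node value for a contrast, floored against zero FPKM."""
    for sample in contrast.samples():
        if sample not in ts.columns:
            raise ValueError(f"sample {sample!r} not in time series")
    value = _log_ratio(ts, contrast.num, contrast.den, floor)
    if contrast.kind == "between_genotype":
        value = value - _log_ratio(ts, contrast.num2, contrast.den2, floor)
    return value.rename(contrast.label())


def instantiate_node_values(
    network: nx.Graph,
    ts: pd.DataFrame,
    contrast: ContrastSpec,
    floor: float = 1.0,
) -> nx.Graph:
    """Copy the network with per-node ``value`` set to the contrast."""
    missing = set(network.nodes) - set(ts.index)
    if missing:
        raise ValueError(f"time series missing network gene {sorted(missing)[0]!r}")
    values = node_value_table(ts, contrast, floor)
    out = network.copy()
    nx.set_node_attributes(out, values.loc[list(out.nodes)].to_dict(), "value")
    out.graph["contrast"] = contrast.label()
    return out


def global_shift_test(
    ts: pd.DataFrame,
    pair: tuple[str, str],
    alternative: str = "greater",
    presence_fpkm: float = 1.0,
    floor: float = 1.0,
) -> tuple[float, float, int]:
    """Paired t-test of a global expression shift between two samples.

    Tests H1 per ``alternative`` (default "greater": earlier > later) over
    all genes passing the FPKM presence filter in at least one of the two
    samples. Returns (t, p, n_genes).
    """
    earlier, later = pair
    for sample in pair:
        if sample not in ts.columns:
            raise ValueError(f"sample {sample!r} not in time series")
    present = (ts[earlier] > presence_fpkm) | (ts[later] > presence_fpkm)
    if int(present.sum()) < 2:
        raise ValueError("fewer than 2 genes pass the presence filter")
    x = np.log2(ts.loc[present, earlier] + floor)
    y = np.log2(ts.loc[present, later] + floor)
    t, p = paired_t_test(x, y, alternative=alternative)
    return t, p, int(present.sum())


@dataclass
class ModuleReport:
    """Per-cluster differential and GO test results."""

    cluster_id: int
    size: int
    mean_value: float  # mean between-genotype node value
    t_stat: float
    t_p: float
    go_term: str | None
    go_p: float
    selected: bool


def test_clusters(
    partition: GenePartition,
    ts: pd.DataFrame,
    go_annot: Mapping[str, frozenset[str]],
    contrast: ContrastSpec,
    p_threshold: float = 1e-9,
    floor: float = 1.0,
    universe: list[str] | None = None,
) -> list[ModuleReport]:
    """Test every cluster for differential expression and GO enrichment.

    The differential test pairs, gene by gene, the two genotypes' within-
    genotype log2 changes of the between-genotype ``contrast`` (x =
    log2(num/den), y = log2(num2/den2)) and is two-sided: a module may be
    relatively up- OR down-regulated in the transgenic line. A cluster is
    ``selected`` iff both the t-test p and the best GO p fall strictly below
    ``p_threshold``. Size-1 clusters report p = 1 and are never selected.
    """
    if contrast.kind != "between_genotype":
        raise ValueError("cluster testing needs a between-genotype contrast")
    missing = partition.genes - set(ts.index)
    if missing:
        raise ValueError(f"time series missing gene {sorted(missing)[0]!r}")
    if universe is None:
        universe = sorted(partition.genes)
    x_all = _log_ratio(ts, contrast.num, contrast.den, floor)
    y_all = _log_ratio(ts, contrast.num2, contrast.den2, floor)
    reports = []
    for cid, members in partition.clusters().items():
        x = x_all.loc[members].to_numpy()
        y = y_all.loc[members].to_numpy()
        mean_value = float(np.mean(x - y))
        if len(members) < 2:
            t_stat, t_p = 0.0, 1.0
        else:
            try:
                t_stat, t_p = paired_t_test(x, y, alternative="two-sided")
            except ValueError:  # degenerate: identical differences
                t_stat, t_p = 0.0, 1.0
        try:
            _, (go_term, go_p) = go_enrichment(members, go_annot, universe)
        except ValueError:
            go_term, go_p = None, 1.0
        reports.append(
            ModuleReport(
                cluster_id=cid,
                size=len(members),
                mean_value=mean_value,
                t_stat=t_stat,
                t_p=t_p,
                go_term=go_term,
                go_p=go_p,
                selected=bool(t_p < p_threshold and go_p < p_threshold),
            )
        )
    return reports


def reports_to_frame(reports: list[ModuleReport]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in reports])


def deg_count(
    ts: pd.DataFrame,
    pair: tuple[str, str],
    fc_threshold: float = 2.0,
    presence_fpkm: float = 1.0,
    floor: float = 1.0,
) -> set[str]:
    """Genes with |log2 FC| >= log2(fc_threshold) between a sample pair.

    A simple fold-change DEG call on floored expression, applied to genes
    passing the presence filter in at least one of the two samples.
    """
    a, b = pair
    present = (ts[a] > presence_fpkm) | (ts[b] > presence_fpkm)
    lfc = _log_ratio(ts.loc[present], b, a, floor)
    return set(lfc.index[np.abs(lfc) >= np.log2(fc_threshold)])
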