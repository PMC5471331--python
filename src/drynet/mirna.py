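"""DE miRNA calling and anticorrelation filtering of candidate targets.

Candidate miRNA-target pairs (sequence-predicted, consumed as input) are
kept only when the miRNA's and the gene's expression profiles across the six
dehydration samples are strongly anticorrelated (PCC < -0.67 by default) —
the expression signature expected of genuine miRNA-mediated repression.
Differentially expressed miRNAs are called by fold change (> 2 or < 1/2)
between two time points on floored expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .graphstats import ContingencyTable2x2
from .methylome import test_module_association
from .network import UndefinedCorrelationError, pearson_correlation

__all__ = [
    "MiRNAInteraction",
    "call_demirnas",
    "filter_targets",
    "demirna_module_association",
]

logger = logging.getLogger("drynet.mirna")


@dataclass(frozen=True)
class MiRNAInteraction:
    """A retained miRNA-target pair with its expression anticorrelation."""

    mirna_id: str
    gene_id: str
    pcc: float


def call_demirnas(
    mirna_expr: pd.DataFrame,
    pair: tuple[str, str],
    fc: float = 2.0,
    floor: float = 1.0,
) -> set[str]:
    """miRNAs with fold change strictly > fc or < 1/fc between two samples.

    Fold change is (x1 + floor) / (x0 + floor); the floor guards against
    division by zero for unexpressed miRNAs. The threshold is strict: a fold
    change of exactly ``fc`` is not differential.
    """
    t0, t1 = pair
    for sample in pair:
        if sample not in mirna_expr.columns:
            raise ValueError(f"sample {sample!r} not in miRNA expression")
    ratio = (mirna_expr[t1] + floor) / (mirna_expr[t0] + floor)
    de = (ratio > fc) | (ratio < 1.0 / fc)
    return set(ratio.index[de])


def filter_targets(
    candidates: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    cutoff: float = -0.67,
    transform: str | None = "log2",
    floor: float = 1.0,
) -> list[MiRNAInteraction]:
    """Keep candidate pairs with expression PCC strictly below ``cutoff``.

    ``candidates`` has columns (mirna_id, gene_id). Correlation runs across
    the samples shared by both matrices, on log2(x + floor) by default.
    Pairs with a constant profile are dropped with a warning; positive or
    weak correlations are dropped silently.
    """
    required = {"mirna_id", "gene_id"}
    if not required <= set(candidates.columns):
        raise ValueError("candidates need columns mirna_id, gene_id")
    samples = [s for s in mirna_expr.columns if s in gene_expr.columns]
    if len(samples) < 3:
        raise ValueError("need at least 3 shared samples")

    def prep(x: np.ndarray) -> np.ndarray:
        return np.log2(x + floor) if transform == "log2" else x

    kept: list[MiRNAInteraction] = []
    for row in candidates.itertuples():
        if row.mirna_id not in mirna_expr.index:
            raise ValueError(f"unknown miRNA {row.mirna_id!r}")
        if row.gene_id not in gene_expr.index:
            raise ValueError(f"unknown gene {row.gene_id!r}")
        x = prep(mirna_expr.loc[row.mirna_id, samples].to_numpy(dtype=float))
        y = prep(gene_expr.loc[row.gene_id, samples].to_numpy(dtype=float))
        try:
            pcc = pearson_correlation(x, y)
        except UndefinedCorrelationError:
            logger.warning(
                "dropping pair %s-%s: constant expression profile",
                row.mirna_id, row.gene_id,
            )
            continue
        if pcc < cutoff:
            kept.append(MiRNAInteraction(row.mirna_id, row.gene_id, pcc))
    return kept


def demirna_module_association(
    de_mirnas: Iterable[str],
    interactions: Iterable[MiRNAInteraction],
    module: Iterable[str],
    universe: Iterable[str],
) -> tuple[ContingencyTable2x2, float]:
    """Enrichment of DE-miRNA target genes in a module.

    The gene set is the union of target genes of differentially expressed
    miRNAs over the retained interactions (pooled across genotypes and
    periods).
    """
    de_mirnas = set(de_mirnas)
    targets = {i.gene_id for i in interactions if i.mirna_id in de_mirnas}
    if not targets:
        raise ValueError("no target genes of DE miRNAs")
    return test_module_association(targets, module, universe)
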