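"""Readers and writers for every on-disk artifact the pipeline touches.

All tabular formats are UTF-8 TSV with a header row. Genomic coordinates are
held 1-based inclusive in memory; BED output converts to 0-based half-open on
write. No science lives here.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "read_expression_matrix",
    "write_expression_matrix",
    "validate_expression_matrix",
    "read_annotation",
    "write_annotation",
    "read_gene_go",
    "write_gene_go",
    "read_edge_list",
    "write_edge_list",
    "read_methylation",
    "write_methylation",
    "write_dmrs_bed",
    "read_partition",
    "write_partition",
    "to_bed_interval",
    "from_bed_interval",
]

#: columns of the annotation table, in file order
ANNOTATION_COLUMNS = ["gene_id", "is_tf", "go_terms", "chrom", "strand", "start", "end"]

#: columns of the CX-report-like methylation table
METHYLATION_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "context",
    "methylated_reads",
    "total_reads",
    "sample_id",
]


class FormatError(ValueError):
    """An on-disk artifact violates its format contract."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def validate_expression_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Check ExpressionMatrix invariants: unique ids, finite non-negative values."""
    if expr.index.has_duplicates:
        dup = expr.index[expr.index.duplicated()][0]
        raise FormatError(f"duplicate gene id: {dup!r}")
    if expr.columns.has_duplicates:
        dup = expr.columns[expr.columns.duplicated()][0]
        raise FormatError(f"duplicate sample id: {dup!r}")
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("expression matrix contains non-numeric values")
    if not np.all(np.isfinite(values)):
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise FormatError(
            f"non-finite expression value at gene {expr.index[r]!r}, "
            f"sample {expr.columns[c]!r}"
        )
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise FormatError(
            f"negative expression value at gene {expr.index[r]!r}, "
            f"sample {expr.columns[c]!r}"
        )
    return expr


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV matrix (first row samples, first column genes)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    # locate non-numeric / missing cells before coercion so the error can
    # name the offending row and column
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"non-numeric expression cell at gene {gene!r}, sample {col!r} "
                f"in {path}"
            )
        df[col] = numeric.astype(float)
    return validate_expression_matrix(df.astype(float))


def write_expression_matrix(expr: pd.DataFrame, path: str | Path) -> None:
    validate_expression_matrix(expr)
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.8g")


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def _derive_tss(strand: pd.Series, start: pd.Series, end: pd.Series) -> pd.Series:
    """TSS is the start on the + strand and the end on the - strand."""
    return start.where(strand == "+", end)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the gene annotation table.

    Returns a DataFrame indexed by ``gene_id`` with columns ``is_tf`` (bool),
    ``go_terms`` (frozenset of GO ids), ``chrom``, ``strand``, ``start``,
    ``end`` (1-based inclusive) and the derived ``tss``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"annotation file missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicate gene id: {dup!r}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise FormatError(
            f"invalid strand {df.loc[bad_strand, 'strand'].iloc[0]!r}; must be + or -"
        )
    if (df["start"] > df["end"]).any():
        gene = df.loc[df["start"] > df["end"], "gene_id"].iloc[0]
        raise FormatError(f"gene {gene!r} has start > end")
    df["is_tf"] = df["is_tf"].astype(bool)
    df["go_terms"] = [
        frozenset(t for t in str(s).split(";") if t and t != "nan")
        if not pd.isna(s)
        else frozenset()
        for s in df["go_terms"]
    ]
    df = df.set_index("gene_id")
    df["tss"] = _derive_tss(df["strand"], df["start"], df["end"])
    return df


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    out = annotation.reset_index()[ANNOTATION_COLUMNS].copy()
    out["is_tf"] = out["is_tf"].astype(bool)
    out["go_terms"] = [";".join(sorted(t)) for t in out["go_terms"]]
    out.to_csv(path, sep="\t", index=False)


def annotation_go_map(annotation: pd.DataFrame) -> dict[str, frozenset[str]]:
    """gene_id -> GO term set, from an annotation table."""
    return {g: terms for g, terms in annotation["go_terms"].items()}


def read_gene_go(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GAF-lite gene->GO mapping (columns gene_id, go_terms)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "go_terms"} <= set(df.columns):
        raise FormatError("gene-GO file needs columns gene_id, go_terms")
    return {
        row.gene_id: frozenset(t for t in str(row.go_terms).split(";") if t and t != "nan")
        for row in df.itertuples()
    }


def write_gene_go(go_annot: Mapping[str, frozenset[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tgo_terms\n")
        for gene in sorted(go_annot):
            fh.write(f"{gene}\t{';'.join(sorted(go_annot[gene]))}\n")


# ---------------------------------------------------------------------------
# networks (TSV edge lists)
# ---------------------------------------------------------------------------

def write_edge_list(network: nx.Graph, path: str | Path) -> None:
    """Write (gene_a, gene_b, weight) rows; weights keep >= 6 significant digits."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b in sorted(map(sorted, network.edges())):
            w = network[a][b]["weight"]
            fh.write(f"{a}\t{b}\t{w:.8g}\n")


def read_edge_list(path: str | Path, annotation: pd.DataFrame) -> nx.Graph:
    """Read an edge-list TSV back into a graph; TF flags come from annotation."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    graph = nx.Graph()
    known = annotation.index
    for row in df.itertuples():
        for gene in (row.gene_a, row.gene_b):
            if gene not in known:
                raise FormatError(f"edge references unknown gene {gene!r}")
        graph.add_edge(row.gene_a, row.gene_b, weight=float(row.weight))
    for node in graph.nodes:
        graph.nodes[node]["is_tf"] = bool(annotation.at[node, "is_tf"])
    return graph


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def read_methylation(path: str | Path) -> pd.DataFrame:
    """Read the CX-report-like long table of per-CpG counts per sample."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "strand": str, "context": str, "sample_id": str},
    )
    missing = set(METHYLATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"methylation file missing columns: {sorted(missing)}")
    if (df["methylated_reads"] > df["total_reads"]).any():
        raise FormatError("methylated_reads exceeds total_reads")
    return df


def write_methylation(df: pd.DataFrame, path: str | Path) -> None:
    df[METHYLATION_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genomic intervals / BED
# ---------------------------------------------------------------------------

def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> BED 0-based half-open."""
    return start - 1, end


def from_bed_interval(start: int, end: int) -> tuple[int, int]:
    """BED 0-based half-open -> 1-based inclusive."""
    return start + 1, end


def write_dmrs_bed(dmrs, path: str | Path) -> None:
    """Write DMRs as BED3+1 (chrom, start, end, n_dmcs), sorted by position."""
    rows = []
    for d in dmrs:
        if dataclasses.is_dataclass(d):
            chrom, start, end, n = d.chrom, d.start, d.end, d.n_dmcs
        else:
            chrom, start, end, n = d
        b0, b1 = to_bed_interval(int(start), int(end))
        rows.append((chrom, b0, b1, int(n)))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, b0, b1, n in rows:
            fh.write(f"{chrom}\t{b0}\t{b1}\t{n}\n")


# ---------------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------------

def write_partition(membership: Mapping[str, int | str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tcluster_id\n")
        for gene in sorted(membership):
            fh.write(f"{gene}\t{membership[gene]}\n")


def read_partition(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["gene_id"], df["cluster_id"]))
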