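"""End-to-end orchestration: simulate/load -> networks -> modules -> tree ->
methylome -> miRNA -> association tests, with one config and one seed."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as dio
from .cascade import (augment_network, build_cascade_tree, check_coherency,
                      find_hub_tfs, find_major_paths, paths_to_frame)
from .config import RunConfig
from .graphstats import GenePartition, cluster_network, fowlkes_mallows
from .logutil import get_logger
from .methylome import (MethylomeProfile, call_dmcs, call_dmrs,
                        promoter_overlap, run_significance,
                        test_module_association)
from .mirna import call_demirnas, demirna_module_association, filter_targets
from .modules import (ContrastSpec, global_shift_test, node_value_table,
                      reports_to_frame, test_clusters)
from .network import build_network
from .simulate import SimData, SimSpec, generate_all, write_fixtures

__all__ = ["PipelineError", "PipelineResult", "run_all"]

logger = get_logger("drynet.pipeline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineResult:
    summary: dict[str, Any]
    paths: dict[str, Path]
    config: RunConfig
    module_genes: dict[str, str] = field(default_factory=dict)


def stage_seed(base_seed: int, stage: str) -> int:
    """Stable per-stage seed so stages are individually reproducible."""
    return (int(base_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _load_inputs(input_dir: Path) -> dict[str, Any]:
    need = {
        "annotation": "annotation.tsv",
        "compendium": "compendium.tsv",
        "timeseries": "timeseries.tsv",
        "methylome": "methylation.tsv",
        "mirna_expr": "mirna_expression.tsv",
        "candidates": "mirna_candidates.tsv",
    }
    data: dict[str, Any] = {}
    for key, name in need.items():
        path = input_dir / name
        if not path.exists():
            raise PipelineError(f"stage load-inputs: missing file {path}")
        data[key] = {
            "annotation": dio.read_annotation,
            "methylome": dio.read_methylation,
            "candidates": lambda p: pd.read_csv(p, sep="\t", dtype=str),
        }.get(key, dio.read_expression_matrix)(path)
    return data


def run_all(
    config: RunConfig,
    outdir: str | Path,
    input_dir: str | Path | None = None,
    sim_spec: SimSpec | None = None,
    root_gene: str | None = None,
    contrast: str = "E1/E0-vs-W1/W0",
) -> PipelineResult:
    """Run every stage in workflow order and write a machine-readable summary.

    Inputs come either from ``input_dir`` (the fixture file layout) or from
    the bundled generator via ``sim_spec``. Re-running with the same config,
    spec and seed reproduces identical summary metrics.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"seed": config.rng_seed}
    paths: dict[str, Path] = {}
    truth = None

    if sim_spec is not None:
        sim_spec.rng_seed = stage_seed(config.rng_seed, "simulate")
        data: SimData = generate_all(sim_spec)
        paths.update(write_fixtures(data, outdir / "fixtures"))
        annotation, compendium, ts = data.annotation, data.compendium, data.timeseries
        methylome_df, mirna_expr = data.methylome, data.mirna_expr
        candidates, truth = data.candidates, data.truth
        go_annot = data.go_annot
        if root_gene is None:
            root_gene = truth.root
    elif input_dir is not None:
        data_d = _load_inputs(Path(input_dir))
        annotation, compendium, ts = (data_d["annotation"], data_d["compendium"],
                                      data_d["timeseries"])
        methylome_df, mirna_expr = data_d["methylome"], data_d["mirna_expr"]
        candidates = data_d["candidates"]
        go_annot = dio.annotation_go_map(annotation)
    else:
        raise PipelineError("stage load-inputs: need input_dir or sim_spec")
    if root_gene is None:
        raise PipelineError("stage cascade-tree: no root gene specified")

    floor = config.expression_floor
    rnaseq_transform = "log2" if config.log_transform_rnaseq else None

    # -- networks -----------------------------------------------------------
    try:
        template = build_network(compendium, annotation, config.template_pcc_cutoff)
    except ValueError as exc:
        raise PipelineError(f"stage template-network: {exc}") from exc
    if template.number_of_edges() == 0:
        raise PipelineError(
            f"stage template-network: empty network at "
            f"|PCC|>{config.template_pcc_cutoff}; lower template_pcc_cutoff"
        )
    condition = build_network(ts, annotation, config.condition_pcc_cutoff,
                              restrict_to=template, transform=rnaseq_transform,
                              floor=floor)
    if condition.number_of_edges() == 0:
        raise PipelineError("stage condition-network: no template edge survives "
                            "the condition data")
    dio.write_edge_list(template, outdir / "template_edges.tsv")
    dio.write_edge_list(condition, outdir / "condition_edges.tsv")
    summary.update(
        template_genes=template.number_of_nodes(),
        template_edges=template.number_of_edges(),
        condition_genes=condition.number_of_nodes(),
        condition_edges=condition.number_of_edges(),
    )

    # -- clustering and module selection ------------------------------------
    partition = cluster_network(condition, rng_seed=stage_seed(config.rng_seed,
                                                               "cluster"))
    dio.write_partition({g: str(c) for g, c in partition.membership.items()},
                        outdir / "partition.tsv")
    contrast_spec = ContrastSpec.parse(contrast)
    values = pd.DataFrame({
        c.label(): node_value_table(ts, c, floor)
        for c in (ContrastSpec.parse("W1/W0"), ContrastSpec.parse("E1/E0"),
                  contrast_spec)
    })
    values.to_csv(outdir / "node_values.tsv", sep="\t", index_label="gene_id")

    for g, t0, t1 in (("W", "W0", "W1"), ("W", "W1", "W6"),
                      ("E", "E0", "E1"), ("E", "E1", "E6")):
        if t0 in ts.columns and t1 in ts.columns:
            _, p, n = global_shift_test(ts, (t0, t1), "greater",
                                        config.presence_fpkm, floor)
            summary[f"global_shift_p_{t0}_gt_{t1}"] = p

    reports = test_clusters(partition, ts, go_annot, contrast_spec,
                            config.module_p_threshold, floor)
    reports_to_frame(reports).to_csv(outdir / "module_report.tsv", sep="\t",
                                     index=False)
    clusters = partition.clusters()
    module_genes: dict[str, str] = {}
    for rep in reports:
        if rep.selected:
            for gene in clusters[rep.cluster_id]:
                module_genes[gene] = f"module_{rep.cluster_id}"
    module_labels = sorted(set(module_genes.values()))
    summary.update(n_clusters=len(clusters), n_modules_selected=len(module_labels))
    logger.info("selected %d modules among %d clusters", len(module_labels),
                len(clusters))

    # -- cascade tree --------------------------------------------------------
    augmented = augment_network(condition, ts, annotation, root_gene,
                                module_genes, config.augmentation_pcc_cutoff,
                                rnaseq_transform, floor)
    coherency = check_coherency(condition, augmented,
                                stage_seed(config.rng_seed, "cluster"))
    tree = build_cascade_tree(augmented, root_gene, module_genes)
    tree.to_frame().to_csv(outdir / "cascade_tree.tsv", sep="\t", index=False)
    hubs = find_hub_tfs(tree, config.hub_min_downstream)
    hubs.to_csv(outdir / "hub_tfs.tsv", sep="\t", index=False)
    major_paths = find_major_paths(tree, module_genes,
                                   config.major_path_min_coverage, go_annot,
                                   universe=sorted(condition.nodes))
    paths_to_frame(major_paths).to_csv(outdir / "major_paths.tsv", sep="\t",
                                       index=False)
    summary.update(
        coherency_fm=coherency,
        tree_nodes=len(tree.nodes),
        tree_max_depth=tree.max_depth(),
        tree_unreachable=len(tree.unreachable),
        n_hub_tfs=len(hubs),
        n_major_paths=len(major_paths),
    )

    # -- methylome -----------------------------------------------------------
    profile = MethylomeProfile.from_long(methylome_df)
    levels = profile.levels(config.min_cpg_coverage)
    covered = ~np.isnan(levels).any(axis=1)
    dmc = call_dmcs(levels, config.dmc_delta)
    dmc_rate = float(dmc.sum() / max(covered.sum(), 1))
    dmrs = call_dmrs(profile.chrom, profile.pos, dmc, covered,
                     config.dmr_min_run)
    dio.write_dmrs_bed(dmrs, outdir / "dmrs.bed")
    dmr_genes = promoter_overlap(dmrs, annotation, config.promoter_bp)
    sig = run_significance(dmc_rate, config.dmr_min_run)
    summary.update(
        cpg_sites_covered=int(covered.sum()),
        n_dmcs=int(dmc.sum()),
        dmc_rate=dmc_rate,
        run_p_poisson=sig["poisson"],
        run_p_bernoulli=sig["bernoulli"],
        n_dmrs=len(dmrs),
        n_dmr_genes=len(dmr_genes),
    )

    # -- miRNA ----------------------------------------------------------------
    de_mirnas: set[str] = set()
    for g, t0, t1 in (("W", "W0", "W1"), ("W", "W0", "W6"),
                      ("E", "E0", "E1"), ("E", "E0", "E6")):
        if t0 in mirna_expr.columns and t1 in mirna_expr.columns:
            de_mirnas |= call_demirnas(mirna_expr, (t0, t1),
                                       config.demirna_fc, floor)
    interactions = filter_targets(candidates, mirna_expr, ts,
                                  config.mirna_target_pcc,
                                  rnaseq_transform, floor)
    pd.DataFrame([vars(i) for i in interactions]).to_csv(
        outdir / "mirna_interactions.tsv", sep="\t", index=False)
    summary.update(n_de_mirnas=len(de_mirnas), n_interactions=len(interactions))

    # -- association tests ----------------------------------------------------
    universe = list(annotation.index)
    assoc_rows = []
    for label in module_labels:
        members = [g for g, m in module_genes.items() if m == label]
        t_m, p_m = test_module_association(dmr_genes, members, universe)
        assoc_rows.append({"test": "methylation", "module": label,
                           "a": t_m.a, "module_total": t_m.module_total,
                           "b": t_m.b, "nonmodule_total": t_m.nonmodule_total,
                           "p": p_m})
        summary[f"assoc_methylation_{label}_p"] = p_m
        try:
            t_r, p_r = demirna_module_association(de_mirnas, interactions,
                                                  members, universe)
        except ValueError:
            t_r, p_r = None, float("nan")
        assoc_rows.append({"test": "mirna", "module": label,
                           "a": getattr(t_r, "a", 0),
                           "module_total": len(members),
                           "b": getattr(t_r, "b", 0),
                           "nonmodule_total": len(universe) - len(members),
                           "p": p_r})
        summary[f"assoc_mirna_{label}_p"] = p_r
    pd.DataFrame(assoc_rows).to_csv(outdir / "associations.tsv", sep="\t",
                                    index=False)

    # -- planted-truth recovery (simulation runs only) ------------------------
    if truth is not None:
        det_ids = {m: i for i, m in enumerate(sorted(set(module_genes.values())))}
        tru_ids = {m: i for i, m in
                   enumerate(sorted(set(truth.assignment.values())))}
        detected = GenePartition({g: det_ids[m] for g, m in module_genes.items()})
        truth_part = GenePartition({g: tru_ids[truth.assignment[g]]
                                    for g in detected.membership})
        if len(detected):
            summary["module_recovery_fm"] = fowlkes_mallows(truth_part, detected)
        called = [(d.chrom, d.start, d.end) for d in dmrs]
        recovered = sum(
            any(c == chrom and s <= start and e >= end for c, s, e in called)
            for chrom, start, end, _ in truth.expected_dmrs
        )
        false_dmrs = sum(
            not any(c == chrom and s <= end and e >= start
                    for chrom, start, end, _ in truth.expected_dmrs)
            for c, s, e in called
        )
        kept = {(i.mirna_id, i.gene_id) for i in interactions}
        planted = set(truth.planted_pairs)
        summary.update(
            n_planted_dmrs=len(truth.expected_dmrs),
            n_dmrs_recovered=int(recovered),
            n_false_dmrs=int(false_dmrs),
            mirna_target_precision=(len(kept & planted) / len(kept)) if kept else 0.0,
            mirna_target_recall=len(kept & planted) / len(planted),
            de_mirna_recall=len(de_mirnas & set(truth.de_mirnas))
            / len(truth.de_mirnas),
        )

    config.to_yaml(outdir / "config.yaml")
    with open(outdir / "summary.tsv", "w", encoding="utf-8") as fh:
        fh.write("key\tvalue\n")
        for key in sorted(summary):
            fh.write(f"{key}\t{summary[key]}\n")
    paths["summary"] = outdir / "summary.tsv"
    return PipelineResult(summary=summary, paths=paths, config=config,
                          module_genes=module_genes)
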