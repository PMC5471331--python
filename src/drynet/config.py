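"""Run configuration: every printed threshold of the analysis in one place."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Thresholds and constants driving the pipeline.

    Defaults are the analysis' published operating points: edges require
    |PCC| > 0.67 in both the template and the condition data, augmentation
    relaxes to |PCC| > 0.5, modules need p < 1e-9 in both the differential
    and the GO test, hub TFs need more than 200 downstream genes, major paths
    more than 10% module coverage, DMCs a cross-sample methylation range
    greater than 0.7 at >= 3x covered CpGs, DMRs more than eight consecutive
    DMCs, DE miRNAs a fold change above 2 (or below 1/2), and miRNA targets
    an expression anticorrelation below -0.67.
    """

    template_pcc_cutoff: float = 0.67
    condition_pcc_cutoff: float = 0.67
    augmentation_pcc_cutoff: float = 0.5
    module_p_threshold: float = 1e-9
    hub_min_downstream: int = 200
    major_path_min_coverage: float = 0.10
    dmc_delta: float = 0.7
    dmr_min_run: int = 9
    min_cpg_coverage: int = 3
    demirna_fc: float = 2.0
    mirna_target_pcc: float = -0.67
    expression_floor: float = 1.0  # FPKM pseudocount
    promoter_bp: int = 2000
    presence_fpkm: float = 1.0  # FPKM presence filter for global tests
    log_transform_rnaseq: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("template_pcc_cutoff", "condition_pcc_cutoff", "augmentation_pcc_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.module_p_threshold <= 1.0:
            raise ValueError("module_p_threshold must be in (0, 1]")
        if not -1.0 <= self.mirna_target_pcc <= 0.0:
            raise ValueError("mirna_target_pcc must be in [-1, 0]")
        if not 0.0 <= self.dmc_delta <= 1.0:
            raise ValueError("dmc_delta must be in [0, 1]")
        for name in ("hub_min_downstream", "dmr_min_run", "min_cpg_coverage", "promoter_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.demirna_fc <= 1.0:
            raise ValueError("demirna_fc must exceed 1")
        if not 0.0 < self.major_path_min_coverage <= 1.0:
            raise ValueError("major_path_min_coverage must be in (0, 1]")
        if self.expression_floor < 0:
            raise ValueError("expression_floor must be >= 0")

    def replace(self, **overrides) -> "RunConfig":
        return dataclasses.replace(self, **overrides)

    # -- flat key-value file ------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key-value config file; keyword overrides win."""
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
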