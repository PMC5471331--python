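"""Synthetic multi-omics generator with planted, recoverable structure.

Emulates the statistical shape of the study inputs at desk scale:

* an expression compendium with block-correlated TF/target modules (shared
  latent factor per module, so the expected pairwise PCC has the closed form
  corr = a^2 / (a^2 + sigma^2)) plus weakly correlated background blocks
  that populate low correlation cutoffs the way a real compendium does;
* a two-genotype (WT "W" vs transgenic "E") three-time-point (0/1/6 HAT)
  FPKM time series in which module 1 is up-regulated in both genotypes but
  less in the transgenic line, modules 2-4 down but less down, and module 5
  down but more down — with one designated hub TF per module wired between
  the root transgene and its module;
* a six-sample CpG methylome with a sparse background DMC rate and planted
  runs of consecutive DMCs inside gene promoters;
* miRNA expression with planted differential miRNAs whose targets are
  strongly anticorrelated module genes, plus uncorrelated decoy candidates.

Six samples give the time series almost no room: any two smooth drought
responses correlate. Cross-module separation is therefore engineered, not
hoped for — each of modules 2-5 carries a sample-space factor chosen in the
subspace orthogonal to the root gene's realized profile and to the
between-genotype 0->1 contrast functional (a tetrahedral frame in that
3-dimensional subspace, pairwise cosine -1/3). This keeps member-to-root and
cross-module |PCC| below the augmentation cutoff, hub-to-root |PCC| above
it by construction, and the planted between-genotype module effect free of
shared sample-level shocks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from . import io as dio

__all__ = [
    "SimSpec",
    "SimTruth",
    "SimData",
    "preset",
    "make_annotation",
    "make_compendium",
    "make_timeseries",
    "make_methylome",
    "make_mirna",
    "generate_all",
    "write_fixtures",
]

#: default per-module log2 fold-change profiles vs the genotype's own 0 HAT,
#: ordered (t1, t6) per genotype; module 1 up in both but less in the
#: transgenic line, 2-4 down but less down, 5 down but more down
DEFAULT_PROFILES: dict[str, dict[str, tuple[float, float]]] = {
    "module_1": {"W": (1.2, 1.6), "E": (0.5, 0.8)},
    "module_2": {"W": (-1.3, -1.7), "E": (-0.6, -0.9)},
    "module_3": {"W": (-1.1, -2.0), "E": (-0.5, -1.0)},
    "module_4": {"W": (-1.4, -1.2), "E": (-0.7, -0.6)},
    "module_5": {"W": (-0.7, -1.1), "E": (-1.5, -2.3)},
}
DEFAULT_BACKGROUND_PROFILE = {"W": (-0.3, -0.6), "E": (-0.15, -0.3)}

_TETRA = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)


@dataclass
class SimSpec:
    """Parameters of the synthetic study."""

    module_sizes: tuple[int, ...] = (60, 60, 60, 60, 60)
    module_tfs: int = 9  # TFs per module, hub included
    n_background_blocks: int = 15
    background_block_size: int = 20
    within_module_corr: float = 0.8
    corr_jitter: float = 0.1  # per-gene loading spread around the target
    background_corr: float = 0.0
    background_block_corr: tuple[float, float] = (0.3, 0.7)
    n_compendium_samples: int = 200
    compendium_baseline_log2: tuple[float, float] = (5.0, 11.0)
    genotype_labels: tuple[str, str] = ("W", "E")
    timepoints: tuple[int, ...] = (0, 1, 6)
    module_logfc_profiles: dict | None = None
    background_profile: dict | None = None
    noise_sd: float = 0.25
    module_factor_scale: float = 4.5  # kappa: sample-space module factor
    hub_root_corr: float = 0.6
    baseline_log2: tuple[float, float] = (8.0, 11.5)
    block_ts_factor_sd: float = 0.35
    # methylome
    n_chroms: int = 5
    cpgs_per_chrom: int = 1200
    dmc_background_rate: float = 0.014
    planted_dmc_runs: tuple[int, ...] = (8, 10, 12, 15)
    methylation_coverage: int = 40
    low_coverage_fraction: float = 0.02
    dmc_high: float = 0.95
    dmc_low: float = 0.05
    # miRNA
    n_mirnas: int = 30
    n_de_mirnas: int = 6
    targets_per_demirna: int = 2
    n_decoy_pairs: int = 20
    # annotation / GO
    go_term_dominance: float = 0.8
    n_background_go_terms: int = 30
    promoter_bp: int = 2000
    rng_seed: int = 0

    # -- derived layout -----------------------------------------------------

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_genes(self) -> int:
        return sum(self.module_sizes) + \
            self.n_background_blocks * self.background_block_size

    @property
    def n_tfs(self) -> int:
        return self.module_tfs * self.n_modules + self.n_background_blocks

    def __post_init__(self) -> None:
        self.module_sizes = tuple(int(s) for s in self.module_sizes)
        if self.module_logfc_profiles is None:
            self.module_logfc_profiles = {
                f"module_{i + 1}": DEFAULT_PROFILES[f"module_{(i % 5) + 1}"]
                for i in range(self.n_modules)
            }
        if self.background_profile is None:
            self.background_profile = dict(DEFAULT_BACKGROUND_PROFILE)
        self.validate()

    def validate(self) -> None:
        if not self.module_sizes or min(self.module_sizes) < 3:
            raise ValueError("each module needs at least 3 genes")
        if self.n_modules > 5:
            raise ValueError(
                "at most 5 modules: the 6-sample factor frame has no room for more"
            )
        if any(self.module_tfs > s for s in self.module_sizes):
            raise ValueError("module_tfs exceeds a module size")
        if not self.background_corr < self.within_module_corr < 1.0:
            raise ValueError("need background_corr < within_module_corr < 1")
        if not 0.0 <= self.within_module_corr - self.corr_jitter:
            raise ValueError("corr_jitter pushes loadings below zero")
        if self.within_module_corr + self.corr_jitter >= 1.0:
            raise ValueError("corr_jitter pushes loadings to 1 or above")
        if self.n_de_mirnas > self.n_mirnas:
            raise ValueError("n_de_mirnas exceeds n_mirnas")
        if self.n_decoy_pairs > self.n_mirnas - self.n_de_mirnas:
            raise ValueError("need one distinct non-DE miRNA per decoy pair")
        if not 0.0 <= self.dmc_background_rate <= 1.0:
            raise ValueError("dmc_background_rate must be in [0, 1]")
        if max(self.planted_dmc_runs, default=0) * 60 > self.promoter_bp:
            raise ValueError("planted run too long for a promoter window")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    # -- deterministic gene layout -------------------------------------------

    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(1, self.n_genes + 1)]

    def module_labels(self) -> list[str]:
        return [f"module_{i + 1}" for i in range(self.n_modules)]

    def assignment(self) -> dict[str, str]:
        """gene -> planted group (module_* or block_*)."""
        out: dict[str, str] = {}
        genes = iter(self.gene_ids())
        for label, size in zip(self.module_labels(), self.module_sizes):
            for _ in range(size):
                out[next(genes)] = label
        for b in range(self.n_background_blocks):
            for _ in range(self.background_block_size):
                out[next(genes)] = f"block_{b + 1:02d}"
        return out

    def tf_flags(self) -> dict[str, bool]:
        flags: dict[str, bool] = {}
        genes = iter(self.gene_ids())
        for size in self.module_sizes:
            for k in range(size):
                flags[next(genes)] = k < self.module_tfs
        for _ in range(self.n_background_blocks):
            for k in range(self.background_block_size):
                flags[next(genes)] = k == 0
        return flags

    def root_gene(self) -> str:
        return self.gene_ids()[0]  # first TF of module 1: the transgene

    def hub_genes(self) -> dict[str, str]:
        """module label -> designated hub TF (first TF of the module)."""
        offsets = np.concatenate([[0], np.cumsum(self.module_sizes)[:-1]])
        genes = self.gene_ids()
        return {label: genes[int(off)]
                for label, off in zip(self.module_labels(), offsets)}

    def sample_labels(self) -> list[str]:
        return [f"{g}{t}" for g in self.genotype_labels for t in self.timepoints]

    def profile_vector(self, label: str) -> np.ndarray:
        """Full 6-sample log2 offset vector for a planted group."""
        if label.startswith("module"):
            prof = self.module_logfc_profiles[label]
        else:
            prof = self.background_profile
        w, e = self.genotype_labels
        return np.array([0.0, *prof[w], 0.0, *prof[e]])


@dataclass
class SimTruth:
    """Planted ground truth, for recovery scoring."""

    assignment: dict[str, str]
    root: str
    hubs: dict[str, str]
    module_go_terms: dict[str, str]
    planted_dmrs: list[tuple[str, int, int, int]] = field(default_factory=list)
    expected_dmrs: list[tuple[str, int, int, int]] = field(default_factory=list)
    de_mirnas: list[str] = field(default_factory=list)
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)
    decoy_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class SimData:
    spec: SimSpec
    annotation: pd.DataFrame
    go_annot: dict[str, frozenset[str]]
    compendium: pd.DataFrame
    timeseries: pd.DataFrame
    methylome: pd.DataFrame
    mirna_expr: pd.DataFrame
    candidates: pd.DataFrame
    truth: SimTruth


def preset(name: str) -> SimSpec:
    """Named study conditions: "small" for tests, "study-scale" for structure."""
    if name == "small":
        return SimSpec()
    if name == "study-scale":
        # module sizes follow the published 713/1,363/537/1,586/1,605 at 1/10
        return SimSpec(
            module_sizes=(71, 136, 54, 159, 160),
            module_tfs=10,
            n_background_blocks=40,
            n_compendium_samples=1000,
            cpgs_per_chrom=1500,
        )
    raise ValueError(f"unknown preset {name!r}")


def _rng(spec: SimSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.rng_seed) % (2**31), stream])


# ---------------------------------------------------------------------------
# annotation & GO
# ---------------------------------------------------------------------------

def make_annotation(spec: SimSpec) -> pd.DataFrame:
    """Gene coordinates, TF flags and GO terms for the synthetic genome."""
    rng = _rng(spec, 5)
    genes = spec.gene_ids()
    order = rng.permutation(len(genes))  # genomic order independent of modules
    flags = spec.tf_flags()
    assignment = spec.assignment()

    per_chrom = int(np.ceil(len(genes) / spec.n_chroms))
    rows: list[dict] = [None] * len(genes)  # type: ignore[list-item]
    for rank, gi in enumerate(order):
        chrom_i = rank // per_chrom
        slot = rank % per_chrom
        start = 5000 + slot * 9000 + int(rng.integers(0, 1500))
        length = int(rng.integers(1500, 4000))
        strand = "+" if rng.random() < 0.5 else "-"
        rows[gi] = {
            "gene_id": genes[gi],
            "is_tf": flags[genes[gi]],
            "chrom": f"chr{chrom_i + 1}",
            "strand": strand,
            "start": start,
            "end": start + length,
        }
    df = pd.DataFrame(rows)

    # GO: one dominant synthetic term per module plus diffuse background terms
    bg_terms = [f"GO:B{i:02d}" for i in range(1, spec.n_background_go_terms + 1)]
    module_terms = {label: f"GO:M{i + 1}" for i, label in
                    enumerate(spec.module_labels())}
    go: list[str] = []
    for gene in genes:
        terms = set(rng.choice(bg_terms, size=int(rng.integers(1, 3)),
                               replace=False))
        label = assignment[gene]
        if label in module_terms and rng.random() < spec.go_term_dominance:
            terms.add(module_terms[label])
        elif label not in module_terms and rng.random() < 0.02:
            terms.add(module_terms[rng.choice(list(module_terms))])
        go.append(";".join(sorted(terms)))
    df["go_terms"] = [frozenset(t.split(";")) for t in go]
    df = df.set_index("gene_id")
    df["tss"] = df["start"].where(df["strand"] == "+", df["end"])
    return df[["is_tf", "go_terms", "chrom", "strand", "start", "end", "tss"]]


# ---------------------------------------------------------------------------
# compendium
# ---------------------------------------------------------------------------

def make_compendium(spec: SimSpec) -> pd.DataFrame:
    """Log2-intensity-like compendium with planted co-expression modules.

    Module genes share one latent factor with loading a_g = sqrt(rho_g),
    rho_g ~ U(corr +- jitter), so an (a, b) pair has expected PCC a_a*a_b.
    Background blocks get weaker block factors spanning
    ``background_block_corr``, which is what makes low |PCC| cutoffs pull in
    functionally incoherent genes during cutoff scans.
    """
    rng = _rng(spec, 1)
    n, s = spec.n_genes, spec.n_compendium_samples
    assignment = spec.assignment()
    genes = spec.gene_ids()

    factors: dict[str, np.ndarray] = {}
    block_rho: dict[str, float] = {}
    lo, hi = spec.background_block_corr
    for label in sorted(set(assignment.values())):
        factors[label] = rng.standard_normal(s)
        if label.startswith("block"):
            block_rho[label] = float(rng.uniform(lo, hi))

    baseline = rng.uniform(*spec.compendium_baseline_log2, size=n)
    values = np.empty((n, s))
    for i, gene in enumerate(genes):
        label = assignment[gene]
        if label.startswith("module"):
            rho = rng.uniform(spec.within_module_corr - spec.corr_jitter,
                              spec.within_module_corr + spec.corr_jitter)
        else:
            rho = block_rho[label]
        a = np.sqrt(rho)
        noise = rng.standard_normal(s)
        values[i] = baseline[i] + a * factors[label] + np.sqrt(1 - rho) * noise
    values = np.clip(values, 0.0, None)
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=[f"s{j + 1:04d}" for j in range(s)])


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------

def _module_factor_frame(root_centered: np.ndarray,
                         n_factors: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit sample-space factors: centered, contrast-zero, orthogonal to root.

    The admissible subspace of R^6 (orthogonal to the all-ones vector, to
    the between-genotype 0->1 contrast functional, and to the root profile)
    is 3-dimensional; up to four factors are placed on a tetrahedral frame
    there (pairwise cosine -1/3). Returns (factors, orthonormal basis rows
    of the subspace). Module profiles are later projected OFF this subspace
    so that a member's component inside it is exactly its module factor —
    otherwise profile/factor cross terms push cross-module correlations
    over the augmentation cutoff with only six samples.
    """
    ones = np.ones(6)
    contrast = np.array([1.0, -1.0, 0.0, -1.0, 1.0, 0.0])  # +W0 -W1 -E0 +E1
    basis = null_space(np.vstack([ones, contrast, root_centered]))
    if basis.shape[1] < 3:
        raise ValueError("degenerate root profile: factor frame has no room")
    q = basis.T[:3]
    return _TETRA[:n_factors] @ q, q


def make_timeseries(spec: SimSpec) -> pd.DataFrame:
    """FPKM time series W0,W1,W6,E0,E1,E6 with planted module structure."""
    rng = _rng(spec, 2)
    genes = spec.gene_ids()
    assignment = spec.assignment()
    labels = spec.sample_labels()
    kappa = spec.module_factor_scale
    sigma = spec.noise_sd
    hub_of = spec.hub_genes()
    root = spec.root_gene()

    baseline = dict(zip(genes, rng.uniform(*spec.baseline_log2, size=len(genes))))

    # root first: its realized centered profile anchors the factor frame
    root_profile = spec.profile_vector("module_1")
    root_vec = baseline[root] + root_profile + 0.2 * sigma * rng.standard_normal(6)
    root_centered = root_vec - root_vec.mean()
    r_hat = root_centered / np.linalg.norm(root_centered)

    factors, fac_basis = _module_factor_frame(r_hat, max(spec.n_modules - 1, 1))
    module_factor = {f"module_{m + 2}": factors[m]
                     for m in range(spec.n_modules - 1)}

    def clean(profile: np.ndarray) -> np.ndarray:
        """Profile with its factor-subspace component removed."""
        return profile - fac_basis.T @ (fac_basis @ profile)

    # per-block sample factors keep some background structure in the
    # condition data (clusters that exist but never pass the module tests)
    block_factor = {
        label: spec.block_ts_factor_sd * rng.standard_normal(6)
        for label in sorted(set(assignment.values())) if label.startswith("block")
    }

    x = np.empty((len(genes), 6))
    for i, gene in enumerate(genes):
        label = assignment[gene]
        profile = spec.profile_vector(label)
        if gene == root:
            x[i] = root_vec
            continue
        if label.startswith("module") and gene == hub_of[label] and \
                label in module_factor:
            # hub TF: exact mixture of the root direction and the module
            # factor -> |PCC| to the root is hub_root_corr by construction
            a = spec.hub_root_corr
            sign = np.sign(float(profile @ r_hat)) or 1.0
            direction = sign * a * r_hat + np.sqrt(1 - a * a) * module_factor[label]
            prof_c = clean(profile - profile.mean())
            scale = np.sqrt(float(prof_c @ prof_c) + kappa**2)
            x[i] = baseline[gene] + profile.mean() + scale * direction
            continue
        noise = sigma * rng.standard_normal(6)
        if label.startswith("module"):
            noise -= (noise @ r_hat) * r_hat  # keep member-root PCC bounded
            if label in module_factor:
                extra = kappa * module_factor[label]
                profile = clean(profile)
            else:
                # module 1 rides the root direction; shrink its noise inside
                # the factor subspace so noise-times-kappa cross terms cannot
                # reach other modules' factors
                noise -= 0.7 * fac_basis.T @ (fac_basis @ noise)
                extra = np.zeros(6)
        else:
            extra = block_factor[label]
        x[i] = baseline[gene] + profile + extra + noise

    fpkm = np.clip(np.exp2(x), 0.0, None)
    return pd.DataFrame(fpkm, index=pd.Index(genes, name="gene_id"),
                        columns=labels)


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def _draw_site_counts(rng, level: np.ndarray, coverage: np.ndarray,
                      want_dmc: bool, delta: float = 0.7) -> np.ndarray:
    """Binomial counts whose realized level range matches the site's role."""
    for _ in range(200):
        meth = rng.binomial(coverage, level)
        realized = meth / coverage
        rng_span = realized.max() - realized.min()
        if want_dmc and rng_span > delta + 0.02:
            return meth
        if not want_dmc and rng_span < delta - 0.05:
            return meth
    raise RuntimeError("could not realize the requested methylation pattern")


def make_methylome(spec: SimSpec, annotation: pd.DataFrame) -> tuple[pd.DataFrame, SimTruth]:
    """Six-sample CpG counts: sparse background DMCs plus planted DMC runs.

    Planted runs sit inside gene promoters (60 bp CpG spacing), one run per
    chosen gene; background CpGs avoid those windows so a run is a true
    consecutive stretch. Runs of length >= 9 are the expected DMRs; shorter
    planted runs (the default includes one of length 8) must NOT be called.
    """
    rng = _rng(spec, 3)
    samples = spec.sample_labels()
    n_s = len(samples)
    assignment = spec.assignment()

    # planted runs in promoters of background (non-module) genes, matching
    # the published observation that methylation was not module-associated
    candidates_genes = [g for g, lab in assignment.items()
                        if lab.startswith("block")]

    def promoter_window(gene: str) -> tuple[str, int, int]:
        row = annotation.loc[gene]
        if row["strand"] == "+":
            return row["chrom"], max(1, int(row["tss"]) - spec.promoter_bp), \
                int(row["tss"]) - 1
        return row["chrom"], int(row["tss"]) + 1, int(row["tss"]) + spec.promoter_bp

    # promoters hosting planted runs must not overlap each other
    for _ in range(100):
        run_genes = list(rng.choice(candidates_genes,
                                    size=len(spec.planted_dmc_runs),
                                    replace=False))
        windows = sorted(promoter_window(g) for g in run_genes)
        if all(w1[0] != w2[0] or w1[2] < w2[1]
               for w1, w2 in zip(windows, windows[1:])):
            break
    else:
        raise RuntimeError("could not place planted runs in disjoint promoters")
    reserved: dict[str, list[tuple[int, int]]] = {}
    planted: list[tuple[str, int, int, int]] = []
    site_chrom: list[str] = []
    site_pos: list[int] = []
    site_role: list[str] = []  # background | planted:<idx>

    for idx, (length, gene) in enumerate(zip(spec.planted_dmc_runs, run_genes)):
        row = annotation.loc[gene]
        if row["strand"] == "+":
            p0, p1 = max(1, int(row["tss"]) - spec.promoter_bp), int(row["tss"]) - 1
        else:
            p0, p1 = int(row["tss"]) + 1, int(row["tss"]) + spec.promoter_bp
        positions = [p0 + 10 + k * 60 for k in range(length)]
        if positions[-1] > p1:
            raise ValueError("planted run longer than the promoter window")
        reserved.setdefault(row["chrom"], []).append((p0, p1))
        planted.append((row["chrom"], positions[0], positions[-1], length))
        site_chrom += [row["chrom"]] * length
        site_pos += positions
        site_role += [f"planted:{idx}"] * length

    chrom_span = int(annotation["end"].max()) + 5000
    for c in range(spec.n_chroms):
        chrom = f"chr{c + 1}"
        pos = np.sort(rng.choice(np.arange(100, chrom_span),
                                 size=spec.cpgs_per_chrom, replace=False))
        for window in reserved.get(chrom, []):
            pos = pos[(pos < window[0]) | (pos > window[1])]
        site_chrom += [chrom] * len(pos)
        site_pos += [int(p) for p in pos]
        site_role += ["background"] * len(pos)

    order = np.lexsort((np.asarray(site_pos), np.asarray(site_chrom, dtype=object)))
    site_chrom = [site_chrom[i] for i in order]
    site_pos = [site_pos[i] for i in order]
    site_role = [site_role[i] for i in order]
    n_sites = len(site_pos)

    # background sites flanking a planted run must not be DMCs: a chance
    # background DMC there would extend the run and corrupt the planted
    # run-length truth (in particular the sub-threshold negative control)
    flank = set()
    for i in range(n_sites):
        if site_role[i].startswith("planted"):
            if i > 0 and site_chrom[i - 1] == site_chrom[i]:
                flank.add(i - 1)
            if i + 1 < n_sites and site_chrom[i + 1] == site_chrom[i]:
                flank.add(i + 1)

    coverage = 10 + rng.poisson(spec.methylation_coverage - 10,
                                size=(n_sites, n_s))
    low = rng.random(n_sites) < spec.low_coverage_fraction
    half_high = np.array([True] * (n_s // 2) + [False] * (n_s - n_s // 2))
    meth = np.empty((n_sites, n_s), dtype=int)
    for i in range(n_sites):
        if site_role[i] == "background" and low[i] and i not in flank:
            coverage[i] = rng.integers(0, 3, size=n_s)  # excluded by filter
            meth[i] = rng.binomial(coverage[i], 0.5)
            continue
        if site_role[i].startswith("planted"):
            level = np.where(half_high, spec.dmc_high, spec.dmc_low)
            meth[i] = _draw_site_counts(rng, level, coverage[i], want_dmc=True)
        elif i not in flank and rng.random() < spec.dmc_background_rate:
            level = np.where(rng.permutation(half_high), spec.dmc_high, spec.dmc_low)
            meth[i] = _draw_site_counts(rng, level, coverage[i], want_dmc=True)
        else:
            base = rng.uniform(0.05, 0.9)
            meth[i] = _draw_site_counts(rng, np.full(n_s, base), coverage[i],
                                        want_dmc=False)

    rows = []
    for i in range(n_sites):
        for j, sample in enumerate(samples):
            rows.append((site_chrom[i], site_pos[i], "+", "CG",
                         int(meth[i, j]), int(coverage[i, j]), sample))
    long = pd.DataFrame(rows, columns=dio.METHYLATION_COLUMNS)

    truth = SimTruth(
        assignment=assignment,
        root=spec.root_gene(),
        hubs=spec.hub_genes(),
        module_go_terms={lab: f"GO:M{i + 1}"
                         for i, lab in enumerate(spec.module_labels())},
        planted_dmrs=planted,
        expected_dmrs=[p for p in planted if p[3] >= 9],
    )
    return long, truth


# ---------------------------------------------------------------------------
# miRNA
# ---------------------------------------------------------------------------

def make_mirna(spec: SimSpec, timeseries: pd.DataFrame,
               floor: float = 1.0) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """miRNA expression plus candidate pairs with planted anticorrelation.

    Each planted differential miRNA mirrors (negatively) the log2 profile of
    its first target gene — repression is visible as strong anticorrelation
    (PCC near -1) and, because module genes move over time, as a fold change
    beyond the DE threshold. Decoy candidates are rejection-sampled to
    |PCC| < 0.3 so the anticorrelation filter has planted negatives.
    """
    rng = _rng(spec, 4)
    assignment = spec.assignment()
    labels = spec.sample_labels()
    mirna_ids = [f"mir{i:03d}" for i in range(1, spec.n_mirnas + 1)]
    module_members = {
        lab: [g for g, a in assignment.items() if a == lab]
        for lab in spec.module_labels()
    }
    log_ts = np.log2(timeseries[labels] + floor)

    # fold change is judged over the four within-genotype periods, as the
    # pipeline pools DE calls across genotypes and periods
    w, e = spec.genotype_labels
    t0, t1, t6 = spec.timepoints
    periods = [(f"{g}{t0}", f"{g}{t}") for g in (w, e) for t in (t1, t6)]

    def floored_log(profile: np.ndarray) -> np.ndarray:
        return np.log2(np.exp2(profile) + floor)

    def is_de(profile: np.ndarray) -> bool:
        fl = pd.Series(floored_log(profile), index=labels)
        return any(abs(fl[b] - fl[a]) > np.log2(2.0) + 0.1 for a, b in periods)

    profiles: dict[str, np.ndarray] = {}
    planted_pairs: list[tuple[str, str]] = []
    de_mirnas = mirna_ids[: spec.n_de_mirnas]
    for k, mid in enumerate(de_mirnas):
        label = spec.module_labels()[k % spec.n_modules]
        members = module_members[label]
        picks = rng.choice(len(members), size=spec.targets_per_demirna,
                           replace=False)
        targets = [members[i] for i in picks]
        anchor = log_ts.loc[targets[0]].to_numpy()
        base = float(rng.uniform(5.0, 7.0))
        # amplify the mirrored profile until some period clears the DE
        # threshold; scaling leaves the anticorrelation untouched
        span = max(abs(anchor[labels.index(b)] - anchor[labels.index(a)])
                   for a, b in periods)
        beta = max(1.0, 1.5 / max(span, 0.2))
        for _ in range(100):
            prof = base + beta * (anchor.mean() - anchor) + \
                0.05 * rng.standard_normal(6)
            ok = is_de(prof) and all(
                np.corrcoef(floored_log(prof), log_ts.loc[t])[0, 1] < -0.8
                for t in targets
            )
            if ok:
                break
            beta *= 1.2
        else:
            raise RuntimeError("could not plant anticorrelated DE miRNA")
        profiles[mid] = prof
        planted_pairs += [(mid, t) for t in targets]

    for mid in mirna_ids[spec.n_de_mirnas:]:
        base = float(rng.uniform(4.0, 7.0))
        profiles[mid] = base + 0.1 * rng.standard_normal(6)

    # decoys: one distinct non-DE miRNA per pair, rejection-sampled
    background_genes = [g for g, a in assignment.items() if a.startswith("block")]
    decoy_pairs: list[tuple[str, str]] = []
    for j in range(spec.n_decoy_pairs):
        mid = mirna_ids[spec.n_de_mirnas + j]
        for _ in range(200):
            gene = background_genes[int(rng.integers(len(background_genes)))]
            pcc = float(np.corrcoef(np.log2(np.exp2(profiles[mid]) + floor),
                                    log_ts.loc[gene])[0, 1])
            if abs(pcc) < 0.3:
                decoy_pairs.append((mid, gene))
                break
        else:
            raise RuntimeError("could not draw an uncorrelated decoy pair")

    expr = pd.DataFrame(
        np.exp2(np.vstack([profiles[m] for m in mirna_ids])),
        index=pd.Index(mirna_ids, name="mirna_id"), columns=labels,
    )
    candidates = pd.DataFrame(planted_pairs + decoy_pairs,
                              columns=["mirna_id", "gene_id"])
    candidates = candidates.sample(frac=1.0, random_state=int(spec.rng_seed) % 2**31)
    candidates = candidates.reset_index(drop=True)
    truth = SimTruth(
        assignment=assignment, root=spec.root_gene(), hubs=spec.hub_genes(),
        module_go_terms={}, de_mirnas=list(de_mirnas),
        planted_pairs=planted_pairs, decoy_pairs=decoy_pairs,
    )
    return expr, candidates, truth


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

def generate_all(spec: SimSpec) -> SimData:
    """Generate every fixture with one spec; deterministic given rng_seed."""
    annotation = make_annotation(spec)
    compendium = make_compendium(spec)
    timeseries = make_timeseries(spec)
    methylome, truth = make_methylome(spec, annotation)
    mirna_expr, candidates, mirna_truth = make_mirna(spec, timeseries)
    truth.de_mirnas = mirna_truth.de_mirnas
    truth.planted_pairs = mirna_truth.planted_pairs
    truth.decoy_pairs = mirna_truth.decoy_pairs
    go_annot = dio.annotation_go_map(annotation)
    return SimData(
        spec=spec, annotation=annotation, go_annot=go_annot,
        compendium=compendium, timeseries=timeseries, methylome=methylome,
        mirna_expr=mirna_expr, candidates=candidates, truth=truth,
    )


def write_fixtures(data: SimData, outdir: str | Path) -> dict[str, Path]:
    """Write every fixture file; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": outdir / "annotation.tsv",
        "compendium": outdir / "compendium.tsv",
        "timeseries": outdir / "timeseries.tsv",
        "methylome": outdir / "methylation.tsv",
        "mirna_expr": outdir / "mirna_expression.tsv",
        "candidates": outdir / "mirna_candidates.tsv",
        "truth": outdir / "truth.tsv",
    }
    dio.write_annotation(data.annotation, paths["annotation"])
    dio.write_expression_matrix(data.compendium, paths["compendium"])
    dio.write_expression_matrix(data.timeseries, paths["timeseries"])
    dio.write_methylation(data.methylome, paths["methylome"])
    dio.write_expression_matrix(data.mirna_expr, paths["mirna_expr"])
    data.candidates.to_csv(paths["candidates"], sep="\t", index=False)
    dio.write_partition(data.truth.assignment, paths["truth"])
    return paths
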