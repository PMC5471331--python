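import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from drynet.config import RunConfig
from drynet.pipeline import run_all
from drynet.simulate import generate_all, preset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_data():
    spec = preset("small")
    spec.rng_seed = 1
    return generate_all(spec)


@pytest.fixture(scope="session")
def studyscale_data():
    spec = preset("study-scale")
    spec.rng_seed = 1
    return generate_all(spec)


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    cfg = RunConfig(rng_seed=1, hub_min_downstream=20)
    outdir = tmp_path_factory.mktemp("pipeline")
    return run_all(cfg, outdir, sim_spec=preset("small"))


def toy_annotation(genes, tfs=(), chrom="chr1"):
    """Minimal annotation table for toy networks."""
    rows = []
    for i, g in enumerate(genes):
        start = 1000 + i * 10000
        rows.append(
            {
                "gene_id": g,
                "is_tf": g in tfs,
                "go_terms": frozenset(),
                "chrom": chrom,
                "strand": "+",
                "start": start,
                "end": start + 2000,
            }
        )
    df = pd.DataFrame(rows).set_index("gene_id")
    df["tss"] = df["start"].where(df["strand"] == "+", df["end"])
    return df


def toy_expression(vectors, samples=None):
    """Genes x samples DataFrame from a dict gene -> vector."""
    genes = list(vectors)
    mat = np.array([vectors[g] for g in genes], dtype=float)
    if samples is None:
        samples = [f"s{i}" for i in range(mat.shape[1])]
    return pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"),
                        columns=samples)
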