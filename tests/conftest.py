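import pandas as pd
import pytest

from nucdyn import synthetic
from nucdyn.pipeline import PipelineConfig, make_demo, run_pipeline


@pytest.fixture(scope="session")
def tiny_demo(tmp_path_factory):
    """One tiny synthetic demo dataset, pipeline already run."""
    outdir = tmp_path_factory.mktemp("demo")
    cfg_path = make_demo(outdir, "tiny", seed=42)
    cfg = PipelineConfig.from_yaml(cfg_path)
    manifest = run_pipeline(cfg)
    return {"dir": outdir, "config": cfg, "manifest": manifest}


@pytest.fixture(scope="session")
def small_genome():
    genome, genes = synthetic.make_genome(1, 200_000, 25, seed=11)
    return genome, genes


@pytest.fixture(scope="session")
def null_landscape(small_genome):
    genome, genes = small_genome
    mock, treated = synthetic.make_landscape(genome, genes, seed=11)
    return genome, genes, mock, treated


def make_fragments(midpoints, chrom="chr1", length=146):
    """Fragments whose floor midpoints are exactly the given positions."""
    starts = [m - length // 2 for m in midpoints]
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": [s + length for s in starts]}
    )
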