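import json

import pytest

from foxpair.config import SyntheticConfig
from foxpair.pipeline import RunConfig, run_pipeline
from foxpair.synthetic import generate_dataset


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """The reference benchmark run (default config, seed 7), executed twice
    into separate directories so determinism can be byte-checked."""
    d1 = tmp_path_factory.mktemp("run1")
    d2 = tmp_path_factory.mktemp("run2")
    summary = run_pipeline(RunConfig(), outdir=d1)
    run_pipeline(RunConfig(), outdir=d2)
    return {"summary": summary, "dir1": d1, "dir2": d2}


@pytest.fixture(scope="session")
def small_config():
    """A fast small-genome config for generator unit tests."""
    return SyntheticConfig(
        genome_length=120_000, n_chrom=1, tss_spacing=3_000,
        n_shared=10, n_a_only=5, n_b_only=5, depth_input=8_000,
        site_max_tss_offset=500, seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)
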