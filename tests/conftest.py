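import time

import numpy as np
import pytest

from saltmir.config import RunConfig, SyntheticConfig


def mini_synthetic_config() -> SyntheticConfig:
    """A scaled-down study for fast unit tests (same structure, smaller n)."""
    return SyntheticConfig(
        n_chromosomes=3,
        chrom_len=30_000,
        n_known=6,
        n_novel=6,
        n_genes=8,
        n_decoys_rrna=2,
        n_decoys_trna=2,
        n_decoys_snorna=1,
        n_decoys_snrna=1,
        n_decoys_scrna=1,
        n_repeat_families=2,
        repeat_copies=(3, 5),
        n_other_tags=30,
        reads_per_library=4_000,
        n_transcript_only_precursors=2,
        de_known_up=2,
        de_known_down=1,
        de_novel_up=2,
        de_novel_down=1,
    )


@pytest.fixture
def mini_cfg(tmp_path):
    cfg = RunConfig(seed=11, outdir=str(tmp_path / "mini"))
    cfg.synthetic = mini_synthetic_config()
    return cfg


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run under the default (study-condition) generator
    settings, shared across tests; records wall-clock duration."""
    from saltmir.pipeline import run_pipeline

    outdir = tmp_path_factory.mktemp("default_run")
    cfg = RunConfig(seed=1, outdir=str(outdir))
    t0 = time.time()
    run_pipeline(cfg, outdir)
    duration = time.time() - t0
    return {"outdir": outdir, "cfg": cfg, "duration": duration}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
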