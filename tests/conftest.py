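from __future__ import annotations

import pytest

from mirtally.synthetic import SyntheticConfig, generate_references, simulate_libraries


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """A compact experiment for fast unit/oracle tests."""
    return SyntheticConfig(
        seed=7,
        depth_per_library=3000,
        n_mirnas=20,
        n_families=8,
        error_rate=0.01,
        de_min_expected=5.0,
    )


@pytest.fixture(scope="session")
def small_run(small_cfg):
    refs = generate_references(small_cfg)
    ck, tr, truth = simulate_libraries(small_cfg, refs)
    return small_cfg, refs, ck, tr, truth


@pytest.fixture(scope="session")
def clean_cfg() -> SyntheticConfig:
    """Error-free variant used where exact accounting is asserted."""
    return SyntheticConfig(
        seed=7,
        depth_per_library=3000,
        n_mirnas=20,
        n_families=8,
        error_rate=0.0,
        de_min_expected=5.0,
    )


@pytest.fixture(scope="session")
def clean_run(clean_cfg):
    refs = generate_references(clean_cfg)
    ck, tr, truth = simulate_libraries(clean_cfg, refs)
    return clean_cfg, refs, ck, tr, truth


@pytest.fixture(scope="session")
def full_pipeline(tmp_path_factory):
    """One full-scale run under the recovery-study conditions: 50k reads per
    library, 40 miRNAs all with at least 50 expected control reads, 20%
    planted at |log2fc| = 2."""
    import dataclasses

    import pandas as pd

    from mirtally.cli import PipelineConfig, run_pipeline

    outdir = tmp_path_factory.mktemp("e2e")
    cfg = PipelineConfig(outdir=str(outdir), seed=7)
    cfg.synthetic = dataclasses.replace(cfg.synthetic, abundance_range=(50.0, 1000.0))
    paths = run_pipeline(cfg)
    de = pd.read_csv(paths["de"], sep="\t")
    truth = pd.read_csv(outdir / "ground_truth.tsv", sep="\t")
    return cfg, paths, de, truth
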