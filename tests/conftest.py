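"""Shared fixtures: one small simulated study and one full-depth end-to-end
run, both session-scoped so every test reuses the same generated data."""

from __future__ import annotations

import numpy as np
import pytest

from seedmir.pipeline import PipelineConfig, run_all
from seedmir.simulate import SimConfig, build_genome, build_transcriptome, simulate_all


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Reduced study for fast unit-level recovery checks."""
    return SimConfig(
        seed=11,
        genome_length=30_000,
        n_planted_hairpins=6,
        n_known_mirnas=12,
        n_known_families=6,
        n_ncrna_loci=10,
        n_genes=4,
        n_other_tags=60,
        n_unmapped_tags=10,
        n_transcripts=15,
        library_depths=(20_000, 20_000),
        error_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    genome, truth = build_genome(small_cfg)
    build_transcriptome(small_cfg, truth)
    return genome, truth


@pytest.fixture(scope="session")
def e2e_run(tmp_path_factory):
    """Full-depth simulated study (2 libraries x 1e5 reads) run through the
    entire pipeline; returns (truth, report bundle)."""
    workdir = tmp_path_factory.mktemp("e2e")
    cfg = SimConfig(seed=1)
    truth = simulate_all(cfg, workdir / "sim")
    pcfg = PipelineConfig(seed=1, outdir=str(workdir / "report"))
    bundle = run_all(pcfg, indir=workdir / "sim")
    return truth, bundle


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
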