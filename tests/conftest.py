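"""Shared fixtures: marker panels and simulated runs at two scales.

The small run keeps unit/integration tests fast; the study-scale run (20
samples x 10 tetra/penta markers at 500x coverage) is session-scoped and
shared by the end-to-end recovery and refinement tests.
"""
from __future__ import annotations

import numpy as np
import pytest

from ssrgbs import pipeline
from ssrgbs.config_io import MarkerDef
from ssrgbs.simulator import SimConfig, simulate_run


@pytest.fixture()
def marker() -> MarkerDef:
    return MarkerDef(name="W18_ATCT", motif="ATCT",
                     fwd_primer="ACGTACGTACGTACGTACGT",
                     rev_primer="TGCATGCATGCATGCATGCA")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """6 samples x 4 markers at 300x coverage, default noise model."""
    outdir = tmp_path_factory.mktemp("small_sim")
    cfg = SimConfig(seed=11, n_samples=6, n_markers=4, coverage_mean=300)
    return simulate_run(cfg, outdir)


@pytest.fixture(scope="session")
def small_result(small_run, tmp_path_factory):
    workdir = tmp_path_factory.mktemp("small_work")
    return pipeline.run_pipeline(small_run.sample_sheet, small_run.panel, workdir)


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """Study-scale conditions: 20 samples x 10 tetra/penta markers, 500x
    coverage, 0.1% base error, 2% chimeras, 5% per-read stutter."""
    outdir = tmp_path_factory.mktemp("study_sim")
    cfg = SimConfig(seed=42)
    return simulate_run(cfg, outdir)


@pytest.fixture(scope="session")
def study_result(study_run, tmp_path_factory):
    workdir = tmp_path_factory.mktemp("study_work")
    return pipeline.run_pipeline(study_run.sample_sheet, study_run.panel, workdir)
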