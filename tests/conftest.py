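"""Shared fixtures: one default end-to-end simulation reused across tests."""

from __future__ import annotations

import pytest

from tlamap.experiments import ExperimentRun, simulate_and_map
from tlamap.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def sim() -> ExperimentRun:
    """Default error-free single-copy simulated experiment (seed 11)."""
    return simulate_and_map(seed=11)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default pipeline run, shared across tests."""
    outdir = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(seed=1)
    report = run_pipeline(cfg, outdir)
    return report, outdir
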