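import time

import pytest

from eumir.config import PipelineConfig
from eumir.pipeline import run_all


def small_config(seed: int = 1) -> PipelineConfig:
    """A scaled-down configuration for fast pipeline-level tests."""
    cfg = PipelineConfig(seed=seed)
    cfg.simulate.n_transcripts = 20
    cfg.simulate.n_mirnas = 8
    cfg.simulate.depth = 20_000
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One scaled-down end-to-end run, shared across tests."""
    out = tmp_path_factory.mktemp("small_run")
    run_all(small_config(), out)
    return out


@pytest.fixture(scope="session")
def full_runs(tmp_path_factory):
    """Two default-configuration runs with the same seed, plus wall time.

    The default configuration is the study-condition scale: 20 planted
    miRNAs, 200k reads per library across six libraries, 50x degradome
    spikes, seed 1.
    """
    cfg = PipelineConfig(seed=1)
    out1 = tmp_path_factory.mktemp("full_run_a")
    out2 = tmp_path_factory.mktemp("full_run_b")
    t0 = time.monotonic()
    run_all(cfg, out1)
    elapsed = time.monotonic() - t0
    run_all(PipelineConfig(seed=1), out2)
    return out1, out2, elapsed
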