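"""Shared fixtures: a deterministic reference bundle and one full synthetic
pipeline run reused by the end-to-end and acceptance tests."""

from __future__ import annotations

import time

import numpy as np
import pytest

from srnacascade.pipeline import RunConfig, run_pipeline
from srnacascade.simulate import generate_reference_bundle


@pytest.fixture(scope="session")
def bundle():
    return generate_reference_bundle(seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full synthetic experiment at 10^5 reads per group (seed 1)."""
    outdir = tmp_path_factory.mktemp("pipeline") / "out"
    t0 = time.monotonic()
    result = run_pipeline(RunConfig(seed=1, total_reads=100_000,
                                    outdir=str(outdir)))
    elapsed = time.monotonic() - t0
    return result, elapsed
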