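"""Shared fixtures: small synthetic datasets and the replicated end-to-end
pipeline runs used by the recovery/classification/transfer acceptance tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from methylotime import SyntheticConfig, generate_truth, simulate_methylome
from methylotime.transfer import run_pipeline

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", message=".*ConvergenceWarning.*")


#: compact genome for unit tests: 1 chromosome, 10 tiles of 3 kb
SMALL_CONFIG = SyntheticConfig(
    n_cells=6,
    n_cells_2i=2,
    n_chroms=1,
    chrom_length=30_000,
    n_marker_intervals_cpg=2,
    n_marker_intervals_noncpg=2,
    seed=11,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SMALL_CONFIG


@pytest.fixture(scope="session")
def small_truth():
    return generate_truth(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_methylomes(small_truth):
    return {
        sid: simulate_methylome(small_truth, SMALL_CONFIG, i)
        for i, sid in enumerate(small_truth.sample_ids)
    }


#: seeds for the replicated full-pipeline runs (fixed a priori)
PIPELINE_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def pipeline_replicates():
    """Five seeded end-to-end runs at the default study conditions (N=75,
    10+10 planted markers among 480 background intervals, B=200 bootstraps,
    threshold B/2, group shift = 2 pooled SDs), each with a low- and a
    high-pseudo-time external cohort for the transfer checks."""
    runs = []
    for seed in PIPELINE_SEEDS:
        cfg = SyntheticConfig(seed=seed)
        lo, hi = cfg.pseudo_time_range
        externals = {
            "early": list(np.linspace(lo + 1, lo + (hi - lo) / 5, 6)),
            "late": list(np.linspace(lo + 4 * (hi - lo) / 5, hi, 6)),
        }
        runs.append(run_pipeline(cfg, B=200, external_pseudo_times=externals))
    return runs
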