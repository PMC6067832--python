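"""Shared fixtures.

Trained-model fixtures keep the full sheet geometry (the 6 cycles/image test
grating needs the full LGN sampling density) but use shortened training
phases, so the suite runs on one CPU in minutes.  The scientific assertions
are signatures and ratios that are stable at this horizon; the longer study
conditions are exercised by the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pytest

import gcalsim as g
from gcalsim.config import default_config

# shortened training horizon used by trained-model fixtures
TEST_PRETRAIN = 2500
TEST_POST = 2500
TEST_SEEDS = (0, 1, 2, 3, 4)


def tiny_config():
    """Minimal configuration for oracle comparisons (small unit counts)."""
    cfg = default_config()
    cfg.sheets.retina_density = 8
    cfg.sheets.lgn_density = 8
    cfg.sheets.v1_density = 16
    return cfg.validate()


@pytest.fixture(scope="session")
def baselines():
    """Pretrained (unperturbed) seed-matched states for each test seed."""
    out = {}
    for seed in TEST_SEEDS:
        st = g.build_model(seed=seed)
        g.train(st, TEST_PRETRAIN, log_every=0)
        out[seed] = st
    return out


def _continue(baseline, protocol_name):
    bundle = g.run_protocol(
        protocol_name,
        baseline.seed,
        initial_state=baseline,
        log_every=0,
        pretrain=TEST_PRETRAIN,
        post=TEST_POST,
    )
    return bundle


@pytest.fixture(scope="session")
def unmodified_runs(baselines):
    return {seed: _continue(b, "unmodified") for seed, b in baselines.items()}


@pytest.fixture(scope="session")
def chronic_runs(baselines):
    return {seed: _continue(b, "chronic_best") for seed, b in baselines.items()}


@pytest.fixture(scope="session")
def fes_runs(baselines):
    return {seed: _continue(b, "fes_best") for seed, b in baselines.items()}


def mean_at(table, sf, contrast):
    row = table[
        (table.spatial_frequency == sf)
        & (np.isclose(table.contrast, contrast))
        & (np.isclose(table.orientation, np.pi / 2))
    ]
    return float(row.mean_activation.iloc[0])
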