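"""Shared fixtures: small phantoms and the one scaled end-to-end study.

The end-to-end study (three per-plane trainings on a 10-case phantom
cohort, fusion, CRF, evaluation on held-out cases) is expensive, so it
runs once per session and every test that needs trained predictions
shares its results.
"""

from __future__ import annotations

import numpy as np
import pytest

from mpsseg import PhantomConfig, generate_phantom
from mpsseg.pipeline import RunConfig, run_comparison

#: geometry that fits a 32x48x40 grid (brain semi-axes ~ (13, 20, 17))
SMALL_SHAPE = (32, 48, 40)
SMALL_RADII = {"ed": (7.0, 8.0, 6.0), "tc": (4.5, 5.0, 4.0), "ncr": (2.0, 2.5, 2.0)}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_phantom():
    cfg = PhantomConfig(shape=SMALL_SHAPE, radii=SMALL_RADII,
                        tumor_center=(16.0, 24.0, 20.0), seed=7)
    vol, lab = generate_phantom(cfg)
    return vol, lab, cfg


@pytest.fixture(scope="session")
def noiseless_phantom():
    cfg = PhantomConfig(shape=SMALL_SHAPE, radii=SMALL_RADII,
                        tumor_center=(16.0, 24.0, 20.0), noise_sd=0.0, seed=7)
    vol, lab = generate_phantom(cfg)
    return vol, lab, cfg


@pytest.fixture(scope="session")
def e2e_study():
    """Train the reduced three-plane model once; score all decision variants."""
    return run_comparison(RunConfig(seed=1))
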