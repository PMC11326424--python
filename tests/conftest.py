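"""Shared fixtures.

The expensive fixture is ``experiment``: one canonical desk-scale run
(phantom generation, pool training at 2 runs x 3 checkpoints, evaluation of
both selection regimes) shared across every test that needs trained models.
"""

from __future__ import annotations

import numpy as np
import pytest

from daugs.config import RunConfig, run_experiment
from daugs.phantom import PhantomConfig, GammaVariate, make_phantom
from daugs.preprocess import PreprocessSpec, preprocess_series


def clean_phantom_config(**overrides) -> PhantomConfig:
    """Noise-free 64-px phantom used by deterministic geometry tests."""
    kw = dict(
        image_size=64, n_frames=16, cavity_radius=10.0, ring_thickness=5.0,
        rv_crescent=True,
        curve_params={
            "rv": GammaVariate(1.5, 2.0, 1.5, 0.9),
            "lv": GammaVariate(4.0, 2.5, 1.5, 0.95),
            "myo": GammaVariate(6.5, 2.5, 3.0, 0.35),
        },
        noise_sigma=0.0, shading_strength=0.0, seed=11,
    )
    kw.update(overrides)
    return PhantomConfig(**kw)


DESK_SPEC = PreprocessSpec(target_matrix=64, target_frames=16,
                           upsample_factor=1.0)


@pytest.fixture(scope="session")
def clean_pair():
    """One noise-free preprocessed phantom (series, mask)."""
    series, mask = make_phantom(clean_phantom_config())
    return preprocess_series(series, mask, DESK_SPEC)


@pytest.fixture(scope="session")
def experiment():
    """Canonical desk-scale experiment at seed 0 (trained pool + reports)."""
    return run_experiment(RunConfig(seed=0))


@pytest.fixture(scope="session")
def pool(experiment):
    return experiment.model.pool_


@pytest.fixture(scope="session")
def infer_grid(experiment):
    return experiment.model.grid_


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
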