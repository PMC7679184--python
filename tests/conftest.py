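"""Shared fixtures.

The expensive fixtures (a trained reduced network and its frozen validation
set) are session-scoped: several tests interrogate the same trained model
from different angles, and training it once keeps the whole suite within a
few minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pytest

from phaseret import (
    POINT_SCANNING,
    POINT_SCANNING_SMALL,
    ModelSpec,
    PupilGrid,
    build_model,
    freeze_validation_set,
    pair_stream,
    train,
)


@pytest.fixture(scope="session")
def dense_grid() -> PupilGrid:
    """Unit-cutoff pupil sampled with 256 samples of radius."""
    return PupilGrid(n=512, dk=1.0 / 256, cutoff=1.0)


@pytest.fixture(scope="session")
def grid128() -> PupilGrid:
    return PupilGrid(n=128, dk=1.0 / 64, cutoff=1.0)


@pytest.fixture(scope="session")
def trained_reduced_model():
    """Reduced PhaseNet trained on the fast 16^3 point-scanning-like stream.

    Recipe: base 4 channels, 2000 steps, batch 8, learning rate 1e-4.
    Returns (model, frozen validation pairs).
    """
    cfg = POINT_SCANNING_SMALL
    spec = ModelSpec(input_shape=cfg.shape, base_channels=4)
    model = build_model(spec, seed=0)
    model.config = cfg
    stream = pair_stream(cfg, seed=7)
    train(model, stream, steps=2000, batch_size=8, learning_rate=1e-4)
    validation = freeze_validation_set(cfg, n=100, seed=123)
    return model, validation


@pytest.fixture(scope="session")
def point_scanning_sim_grid():
    from phaseret import simulation_grid

    return simulation_grid(POINT_SCANNING)
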