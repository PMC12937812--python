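"""Shared fixtures: one default synthetic session and its trained decoder.

Session-scoped so the expensive generation/training happens once for the
whole suite.
"""

import numpy as np
import pytest

from nfsim.classifier import (offline_preprocess,
                              task_regressor_from_schedule,
                              train_classifier)
from nfsim.synthetic import SessionConfig, generate_session


@pytest.fixture(scope="session")
def default_session():
    return generate_session(subject_id=0, seed=1)


@pytest.fixture(scope="session")
def trained_model(default_session):
    s = default_session
    pre = [offline_preprocess(
        s.runs[r][0], s.truth.motion_params[r],
        task_regressor=task_regressor_from_schedule(s.runs[r][1]))
        for r in (1, 2)]
    return train_classifier(pre, [s.runs[r][1] for r in (1, 2)], s.masks)


@pytest.fixture(scope="session")
def quiet_session():
    """Noise-free, drift-free, motion-free session with planted signal."""
    cfg = SessionConfig(noise_sd=0.0, drift_slope_sd=0.0,
                        motion_scale=0.0, motion_coupling=0.0)
    return generate_session(subject_id=0, seed=7, config=cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
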