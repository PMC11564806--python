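"""Shared fixtures: geometry, a small simulated cohort, a fitted classifier.

The cohort is deliberately small (12 participants, one 180-s long trial and
two short trials each) so the whole suite stays fast; it is built once per
session and shared by the modeling, realtime and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import mwgaze as mg
from mwgaze.modeling import ModelSpec, build_model

COHORT_SEED = 20240

_TEST_PROTOCOL = mg.ProtocolConfig(
    n_focused_trials=2,
    n_mw_trials=1,
    short_clip_s=30.0,
    long_clip_s=180.0,
)


@pytest.fixture(scope="session")
def geometry() -> mg.ViewingGeometry:
    return mg.ViewingGeometry()


@pytest.fixture(scope="session")
def config(geometry) -> mg.PipelineConfig:
    return mg.PipelineConfig(geometry=geometry)


@pytest.fixture(scope="session")
def cohort(config):
    """12 simulated participants: labelled matrix + raw sessions + truths."""
    matrices, sessions, truths = [], {}, {}
    for profile in mg.cohort_profiles(12, seed=COHORT_SEED):
        gaze, events, truth = mg.simulate_session(
            profile, _TEST_PROTOCOL, config.geometry, seed=profile.seed
        )
        rows = mg.extract_features(
            gaze, events, config=config, participant=profile.participant
        )
        matrix, _ = mg.assemble_dataset(rows, mg.label_session(events))
        matrices.append(matrix)
        sessions[profile.participant] = (gaze, events)
        truths[profile.participant] = truth
    return {
        "matrix": pd.concat(matrices, ignore_index=True),
        "sessions": sessions,
        "truths": truths,
    }


@pytest.fixture(scope="session")
def fixation_cohort_matrix(config) -> pd.DataFrame:
    """Cohort whose MW state alters only fixation dynamics (2x duration,
    0.5x rate); vergence and dispersion effects are switched off."""
    base = mg.ParticipantProfile(
        duration_ratio=2.0, rate_ratio=0.5,
        dispersion_ratio=1.0, disparity_shift_px=0.0,
    )
    matrices = []
    for profile in mg.cohort_profiles(12, seed=COHORT_SEED + 1, base=base):
        gaze, events, _ = mg.simulate_session(
            profile, _TEST_PROTOCOL, config.geometry, seed=profile.seed
        )
        rows = mg.extract_features(
            gaze, events, config=config, participant=profile.participant
        )
        matrix, _ = mg.assemble_dataset(rows, mg.label_session(events))
        matrices.append(matrix)
    return pd.concat(matrices, ignore_index=True)


@pytest.fixture(scope="session")
def labeled_matrix(cohort) -> pd.DataFrame:
    return cohort["matrix"][cohort["matrix"]["label"].isin(["mw", "focused"])]


@pytest.fixture(scope="session")
def trained_model(labeled_matrix):
    model = build_model(ModelSpec(seed=7))
    model.fit(
        labeled_matrix[mg.FEATURE_NAMES].to_numpy(),
        (labeled_matrix["label"] == "mw").astype(int),
    )
    return model


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
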