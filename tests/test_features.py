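"""Windowed feature extraction: schema, arithmetic, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mwgaze as mg
from mwgaze.features import (
    FEATURE_NAMES,
    FIXATION_FEATURES,
    SACCADE_FEATURES,
    VERGENCE_FEATURES,
    describe,
    fixation_features,
    saccade_features,
    segment_windows,
    vergence_features,
    window_features,
)
from mwgaze.oculomotor import Fixation, Saccade

from .oracles import textbook_seven

GEO = mg.ViewingGeometry()


def test_schema_is_37_with_subcounts():
    assert len(FEATURE_NAMES) == 37
    assert len(FIXATION_FEATURES) == 11
    assert len(SACCADE_FEATURES) == 22
    assert len(VERGENCE_FEATURES) == 4
    assert FEATURE_NAMES == FIXATION_FEATURES + SACCADE_FEATURES + VERGENCE_FEATURES


class TestSegmentWindows:
    def test_partial_tail_discarded(self):
        assert len(segment_windows(0.0, 10.4)) == 10

    def test_sub_second_trial_has_no_windows(self):
        assert segment_windows(5.0, 5.9) == []

    def test_windows_tile_without_gap_or_overlap(self):
        wins = segment_windows(3.25, 40.75)
        for (a0, a1), (b0, b1) in zip(wins, wins[1:]):
            assert a1 == b0
            assert a1 - a0 == pytest.approx(1.0)
        assert wins[0][0] == 3.25
        assert wins[-1][1] <= 40.75


class TestDescribe:
    def test_single_value(self):
        s = describe([5.0])
        assert s.as_list() == [5.0, 5.0, 5.0, 5.0, 0.0, 0.0, 0.0]

    def test_symmetric_triple(self):
        s = describe([1.0, 2.0, 3.0])
        assert s.mean == 2.0 and s.sd == 1.0 and s.skewness == 0.0

    def test_empty_is_all_zero(self):
        assert describe([]).as_list() == [0.0] * 7

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=40))
    def test_matches_textbook_formulas(self, values):
        got = describe(values).as_list()
        want = textbook_seven(values)
        assert np.allclose(got, want, atol=1e-9, rtol=1e-9)

    def test_order_invariant(self, rng):
        v = rng.normal(size=31)
        assert np.allclose(
            describe(v).as_list(), describe(v[::-1]).as_list(), atol=1e-9
        )


def _fix(start, end, cx=0.0, cy=0.0, mec=2.0):
    return Fixation(start, end, (end - start) * 1000.0, (cx, cy), 12, mec)


def _sacc(start, end, length=50.0):
    dur = end - start
    amp = mg.px_to_deg(length, GEO)
    return Saccade(start, end, dur * 1000.0, length, amp, amp / dur)


class TestFixationFeatures:
    def test_full_window_fixation(self):
        out = fixation_features(2.0, 3.0, [_fix(1.5, 3.5)], [])
        assert out["fix_duration_pct"] == pytest.approx(1.0)
        assert out["fix_count_per_sec"] == 1

    def test_event_free_window_zero_filled(self):
        out = fixation_features(0.0, 1.0, [], [])
        assert all(v == 0.0 for v in out.values())

    def test_hand_computed_vector(self):
        # fixation A 300 ms [0.10, 0.40], B 400 ms [0.45, 0.85], saccade 50 ms
        fixes = [_fix(0.10, 0.40, mec=3.0), _fix(0.45, 0.85, mec=5.0)]
        sacs = [_sacc(0.40, 0.45)]
        out = fixation_features(0.0, 1.0, fixes, sacs)
        assert out["fix_duration_mean"] == pytest.approx(350.0)
        assert out["fix_duration_min"] == pytest.approx(300.0)
        assert out["fix_duration_max"] == pytest.approx(400.0)
        assert out["fix_duration_median"] == pytest.approx(350.0)
        assert out["fix_duration_sd"] == pytest.approx(
            np.sqrt(((300 - 350) ** 2 + (400 - 350) ** 2) / 1.0)
        )
        assert out["fix_duration_skew"] == 0.0  # undefined for n=2
        assert out["fix_count_per_sec"] == 2
        assert out["fix_duration_pct"] == pytest.approx(0.7)
        assert out["fix_sacc_duration_ratio"] == pytest.approx(0.7 / 0.05)
        assert out["fix_mec_radius_mean"] == pytest.approx(4.0)

    def test_ratio_denominator_floored_without_saccade(self):
        out = fixation_features(0.0, 1.0, [_fix(0.2, 0.5)], [])
        assert out["fix_sacc_duration_ratio"] == pytest.approx(0.3 / (1 / 120.0))


class TestSaccadeFeatures:
    def test_no_saccades_all_zero(self):
        out = saccade_features(0.0, 1.0, [])
        assert len(out) == 22 and all(v == 0.0 for v in out.values())

    def test_single_saccade_collapses_stats(self):
        out = saccade_features(0.0, 1.0, [_sacc(0.40, 0.45, length=100.0)])
        assert out["sacc_duration_mean"] == pytest.approx(50.0)
        assert out["sacc_duration_min"] == out["sacc_duration_max"] == pytest.approx(50.0)
        assert out["sacc_length_mean"] == pytest.approx(100.0)
        assert out["sacc_count_per_sec"] == 1

    def test_random_windows_match_recomputation(self, rng):
        sacs = []
        t = 0.0
        for _ in range(30):
            t += rng.uniform(0.05, 0.3)
            end = t + rng.uniform(0.02, 0.08)
            sacs.append(_sacc(t, end, length=float(rng.uniform(10, 400))))
            t = end
        out = saccade_features(1.0, 2.0, sacs)
        sel = [s for s in sacs if s.start < 2.0 and s.end > 1.0]
        want = textbook_seven([s.velocity for s in sel])
        got = [out[f"sacc_velocity_{k}"]
               for k in ("mean", "min", "max", "median", "sd", "skew", "kurt")]
        assert np.allclose(got, want, atol=1e-9)


def _binocular(t, lx, ly, rx, ry, valid=None):
    lx, ly, rx, ry = map(np.asarray, (lx, ly, rx, ry))
    cx, cy = (lx + rx) / 2, (ly + ry) / 2
    v = np.ones(len(t), bool) if valid is None else np.asarray(valid, bool)
    return mg.GazeData(t, lx, ly, rx, ry, cx, cy, v)


class TestVergenceFeatures:
    def test_identical_eyes_give_zeros(self):
        t = np.arange(0, 1, 1 / 120)
        x = np.full(len(t), 100.0)
        gaze = _binocular(t, x, x, x, x)
        out = vergence_features(0.0, 1.0, gaze, [_fix(0.0, 0.99)])
        assert all(v == 0.0 for v in out.values())

    def test_constant_offset_disparity(self):
        t = np.arange(0, 1, 1 / 120)
        x = np.full(len(t), 100.0)
        gaze = _binocular(t, x, x, x + 10.0, x)
        out = vergence_features(0.0, 1.0, gaze, [])
        assert out["verg_disparity_mean"] == pytest.approx(10.0)
        assert out["verg_disparity_sd"] == pytest.approx(0.0, abs=1e-12)

    def test_centroid_distance_matches_direct_recomputation(self, rng):
        t = np.arange(0, 1, 1 / 120)
        lx = 100 + rng.normal(0, 3, len(t))
        ly = 200 + rng.normal(0, 3, len(t))
        rx = 112 + rng.normal(0, 3, len(t))
        ry = 200 + rng.normal(0, 3, len(t))
        gaze = _binocular(t, lx, ly, rx, ry)
        fixes = [_fix(0.0, 0.45), _fix(0.5, 0.99)]
        out = vergence_features(0.0, 1.0, gaze, fixes)
        dists = []
        for f in fixes:
            m = (t >= f.start) & (t <= f.end)
            dists.append(
                np.hypot(lx[m].mean() - rx[m].mean(), ly[m].mean() - ry[m].mean())
            )
        assert out["verg_centroid_dist_mean"] == pytest.approx(np.mean(dists), abs=1e-9)
        assert out["verg_centroid_dist_sd"] == pytest.approx(np.std(dists, ddof=1), abs=1e-9)

    def test_no_valid_samples_zero_filled(self):
        t = np.arange(0, 1, 1 / 120)
        x = np.full(len(t), 1.0)
        gaze = _binocular(t, x, x, x, x, valid=np.zeros(len(t), bool))
        out = vergence_features(0.0, 1.0, gaze, [])
        assert all(v == 0.0 for v in out.values())


@pytest.fixture(scope="module")
def session(config):
    profile = mg.ParticipantProfile(seed=21)
    proto = mg.ProtocolConfig(n_focused_trials=1, n_mw_trials=1, long_clip_s=60.0)
    gaze, events, _ = mg.simulate_session(profile, proto, config.geometry, seed=21)
    return gaze, events


class TestExtractFeatures:
    def test_every_window_has_37_features(self, session, config):
        gaze, events = session
        rows = mg.extract_features(gaze, events, config=config)
        assert rows
        for w in rows:
            assert list(w.features.keys()) == FEATURE_NAMES

    def test_all_invalid_recording_retains_no_windows(self, config):
        t = np.arange(0, 5, 1 / 120)
        nan = np.full(len(t), np.nan)
        gaze = mg.GazeData(t, nan, nan, nan, nan, nan, nan, np.zeros(len(t), bool))
        events = mg.SessionEvents(
            trials=[mg.gaze_io.Trial("t0", "focused_short", 0.0, 5.0)]
        ).validate()
        assert mg.extract_features(gaze, events, config=config) == []

    def test_window_accounting_identity(self, session, config):
        gaze, events = session
        kept = mg.extract_features(gaze, events, config=config, drop_low_valid=True)
        all_rows = mg.extract_features(gaze, events, config=config, drop_low_valid=False)
        total = sum(
            len(segment_windows(tr.start, tr.end)) for tr in events.trials
        )
        dropped = sum(
            1 for w in all_rows if w.valid_fraction < config.min_valid_fraction
        )
        assert len(all_rows) == total
        assert len(kept) == total - dropped

    def test_translation_invariance(self, session, config):
        gaze, events = session
        rows = mg.extract_features(gaze, events, config=config)
        shifted = mg.GazeData(
            gaze.t, gaze.lx + 500.0, gaze.ly - 250.0, gaze.rx + 500.0,
            gaze.ry - 250.0, gaze.cx + 500.0, gaze.cy - 250.0, gaze.valid,
        )
        rows2 = mg.extract_features(shifted, events, config=config)
        assert len(rows) == len(rows2)
        for a, b in zip(rows, rows2):
            assert np.allclose(a.vector(), b.vector(), atol=1e-6)

    def test_doubling_durations_scales_duration_stats(self):
        fixes = [_fix(0.1, 0.3), _fix(0.5, 0.8)]
        out1 = fixation_features(0.0, 1.0, fixes, [])
        doubled = [_fix(f.start, f.start + 2 * (f.end - f.start)) for f in fixes]
        out2 = fixation_features(0.0, 2.0, doubled, [])
        for stat in ("mean", "min", "max", "median"):
            assert out2[f"fix_duration_{stat}"] == pytest.approx(
                2 * out1[f"fix_duration_{stat}"]
            )
        # event count is unchanged (the window stretches with the events)
        assert out2["fix_count_per_sec"] * 2.0 == out1["fix_count_per_sec"] * 1.0


def test_window_features_event_free_flag():
    t = np.arange(0, 1, 1 / 120)
    x = np.full(len(t), 7.0)
    gaze = mg.GazeData(t, x, x, x, x, x, x, np.ones(len(t), bool))
    feats, event_free = window_features(0.0, 1.0, gaze, [], [])
    assert event_free
    assert list(feats.keys()) == FEATURE_NAMES
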