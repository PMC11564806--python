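"""Grouped cross-validation, metrics, feature ranking, ablation."""

import numpy as np
import pandas as pd
import pytest

import mwgaze as mg
from mwgaze.features import FEATURE_NAMES, FIXATION_FEATURES
from mwgaze.gaze_io import ConfigError
from mwgaze.modeling import (
    DEFAULT_HYPERPARAMETERS,
    ModelSpec,
    build_model,
    evaluate,
    info_gain_ranking,
    make_folds,
    null_calibration,
    tune,
)

from .oracles import pair_counting_auc


class TestMakeFolds:
    def test_27_participants_into_9_9_9(self):
        ids = [f"p{i}" for i in range(27)]
        folds = make_folds(ids, 3, seed=1)
        assert sorted(len(f) for f in folds) == [9, 9, 9]
        assert sorted(sum(folds, [])) == sorted(ids)

    def test_remainder_rule(self):
        folds = make_folds(["a", "b", "c", "d"], 3, seed=2)
        assert sorted(len(f) for f in folds) == [1, 1, 2]

    def test_deterministic_under_seed(self):
        ids = [f"p{i}" for i in range(12)]
        assert make_folds(ids, 3, seed=5) == make_folds(ids, 3, seed=5)

    def test_too_few_participants(self):
        with pytest.raises(ConfigError):
            make_folds(["a", "b"], 3)


class TestEvaluate:
    def test_perfect_scores(self):
        out = evaluate([0.9, 0.8, 0.1, 0.2], ["mw", "mw", "focused", "focused"])
        assert out["auc"] == 1.0
        assert out["f1_weighted"] == 1.0
        assert out["fp_rate"] == 0.0
        assert out["recall_mw"] == 1.0

    def test_constant_score_auc_half(self):
        out = evaluate([0.4] * 6, ["mw", "focused"] * 3)
        assert out["auc"] == 0.5

    def test_auc_matches_pair_counting(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.8, 0.7]
        labels = ["focused", "focused", "mw", "mw", "focused", "mw"]
        y = [1 if l == "mw" else 0 for l in labels]
        out = evaluate(scores, labels)
        assert out["auc"] == pytest.approx(pair_counting_auc(scores, y), abs=1e-12)

    def test_single_class_auc_missing(self):
        out = evaluate([0.2, 0.7], ["focused", "focused"])
        assert out["auc"] is None
        assert 0.0 <= out["f1_weighted"] <= 1.0

    def test_metrics_bounded(self, rng):
        scores = rng.random(60)
        labels = np.where(rng.random(60) < 0.3, "mw", "focused")
        out = evaluate(scores, labels)
        for name, v in out.items():
            if v is not None:
                assert 0.0 <= v <= 1.0, name


class TestCrossValidate:
    def test_separable_cohort_high_auc(self, cohort):
        report = mg.cross_validate(cohort["matrix"], ModelSpec(), iterations=5,
                                   seed=3)
        assert len(report.fold_results) == 15
        assert report.mean("auc") >= 0.9

    def test_permuted_labels_null_auc(self, labeled_matrix):
        report = null_calibration(labeled_matrix, ModelSpec(), iterations=5, seed=8)
        assert len(report.fold_results) == 15
        assert 0.45 <= report.mean("auc") <= 0.55

    def test_no_leakage_fold_membership(self, cohort):
        report = mg.cross_validate(cohort["matrix"], ModelSpec(), iterations=1,
                                   seed=4)
        all_test = sum((fr["test_participants"] for fr in report.fold_results), [])
        assert sorted(all_test) == sorted(
            cohort["matrix"]["participant"].unique()
        )

    def test_vergence_exclusion_reduces_schema(self):
        spec = ModelSpec(include_vergence=False)
        assert len(spec.feature_names()) == 33


class TestTune:
    def test_single_point_grid(self, labeled_matrix):
        grid = [{"n_estimators": 20}]
        assert tune(labeled_matrix, "random-forest", grid, iterations=1,
                    seed=1) == grid[0]

    def test_output_member_of_grid(self, labeled_matrix):
        grid = [{"n_estimators": 20}, {"n_estimators": 40}]
        out = tune(labeled_matrix, "random-forest", grid, iterations=1, seed=2)
        assert out in grid

    def test_empty_grid_rejected(self, labeled_matrix):
        with pytest.raises(ConfigError):
            tune(labeled_matrix, "random-forest", [], 1)

    def test_published_defaults_present(self):
        assert DEFAULT_HYPERPARAMETERS["random-forest"]["n_estimators"] == 100
        assert DEFAULT_HYPERPARAMETERS["svm"] == {"kernel": "poly", "C": 20.0}
        assert DEFAULT_HYPERPARAMETERS["gradient-boosted-trees"] == {
            "learning_rate": 0.1, "max_depth": 10,
        }
        assert DEFAULT_HYPERPARAMETERS["multilayer-perceptron"]["momentum"] == 0.3


def _hand_table():
    """12-row fixture with a feature that splits the classes imperfectly."""
    x = [1.0, 1.2, 1.1, 1.3, 2.0, 1.4, 3.0, 3.1, 3.2, 2.9, 3.3, 1.35]
    y = ["focused"] * 6 + ["mw"] * 6
    df = pd.DataFrame({c: 0.0 for c in FEATURE_NAMES}, index=range(12))
    df["fix_duration_mean"] = x
    df["participant"] = ["pA"] * 6 + ["pB"] * 6
    df["trial_id"] = "t0"
    df["window_start"] = np.arange(12.0)
    df["label"] = y
    return df


class TestInfoGain:
    def test_feature_equal_to_label_maximal(self):
        df = _hand_table()
        df["fix_count_per_sec"] = (df["label"] == "mw").astype(float)
        ranking = info_gain_ranking(df)
        top = ranking.iloc[0]
        assert top["feature"] == "fix_count_per_sec"
        assert top["info_gain"] == pytest.approx(1.0)  # H(class) for a 6/6 split

    def test_constant_feature_zero_gain(self):
        ranking = info_gain_ranking(_hand_table())
        assert ranking.set_index("feature").loc["sacc_length_sd", "info_gain"] == 0.0

    def test_hand_computed_entropy(self):
        # the accepted cut at 2.45 splits the rows into 6 focused + 1 mw
        # (entropy H(6,1)) vs 5 mw (pure); the within-partition re-cuts fail
        # the MDL criterion, so IG = 1 - (7/12) H(6,1) - (5/12) * 0 exactly
        df = _hand_table()
        ranking = info_gain_ranking(df).set_index("feature")
        h61 = -(6 / 7) * np.log2(6 / 7) - (1 / 7) * np.log2(1 / 7)
        expected = 1.0 - (7 / 12) * h61
        got = ranking.loc["fix_duration_mean", "info_gain"]
        assert got == pytest.approx(expected, abs=1e-9)

    def test_independent_feature_near_zero(self, rng):
        df = _hand_table()
        df["verg_disparity_mean"] = rng.normal(size=12)
        ranking = info_gain_ranking(df).set_index("feature")
        assert ranking.loc["verg_disparity_mean", "info_gain"] <= 0.2

    def test_fixation_features_dominate_on_fixation_only_cohort(
        self, fixation_cohort_matrix
    ):
        labeled = fixation_cohort_matrix[
            fixation_cohort_matrix["label"] != "unlabeled"
        ]
        ranking = info_gain_ranking(labeled)
        top5 = set(ranking["feature"].head(5))
        assert len(top5 & set(FIXATION_FEATURES)) >= 3


def _fixation_signal_matrix(seed=0, n_participants=8, n_rows=40):
    """Constructed matrix where only the fixation features separate classes."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        for j in range(n_rows):
            label = "mw" if j % 2 else "focused"
            rec = {c: float(rng.normal()) for c in FEATURE_NAMES}
            if label == "mw":
                for c in FIXATION_FEATURES:
                    rec[c] += 1.5
            rec.update(
                participant=f"p{i}", trial_id="t0", window_start=float(j),
                label=label,
            )
            rows.append(rec)
    return pd.DataFrame(rows)


class TestAblate:
    def test_ablating_nothing_is_identity(self, labeled_matrix):
        full, ablated, deltas = mg.ablate(labeled_matrix, [], iterations=1, seed=5)
        assert deltas["auc"] == pytest.approx(0.0, abs=1e-12)

    def test_ablating_fixation_block_removes_signal(self):
        matrix = _fixation_signal_matrix()
        full, ablated, deltas = mg.ablate(
            matrix, FIXATION_FEATURES, iterations=2, seed=6
        )
        assert full.mean("auc") > 0.9
        assert deltas["auc"] < -0.2

    def test_ablating_pure_noise_feature_is_neutral(self):
        matrix = _fixation_signal_matrix()
        _, _, deltas = mg.ablate(
            matrix, ["verg_disparity_sd"], iterations=2, seed=6
        )
        assert abs(deltas["auc"]) < 0.02

    def test_unknown_feature_rejected(self, labeled_matrix):
        with pytest.raises(ConfigError):
            mg.ablate(labeled_matrix, ["nope"], iterations=1)


def test_build_model_families():
    for family in ("random-forest", "svm", "gradient-boosted-trees",
                   "multilayer-perceptron"):
        model = build_model(ModelSpec(family=family))
        assert hasattr(model, "fit")
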