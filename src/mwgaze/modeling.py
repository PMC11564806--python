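"""Mind-wandering classifiers under participant-grouped cross-validation.

The evaluation protocol is five iterations of 3-fold cross-validation in
which the folds are *participants*, not windows: with 27 participants each
fold leaves 9 out, so models are always tested on people they never saw —
the user-independent setting the detector is meant for.  Metrics are the
rank AUC, the support-weighted F1 over both classes, and the false-positive
rate, precision and recall of the MW class at a 0.5 probability threshold.
No class rebalancing and no within-participant normalisation are applied.

Model families and default hyperparameters: random forest (100 trees), SVM
(polynomial kernel, C = 20), gradient-boosted trees (learning rate 0.1, max
depth 10) and a two-hidden-layer perceptron (SGD, learning rate 0.5 with
inverse-scaling decay, momentum 0.3).

Feature ranking follows the information-gain attribute evaluation: each
feature is discretised by recursive entropy minimisation with the MDL
stopping criterion, and scored by the class-entropy reduction of the
resulting bins.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import FEATURE_NAMES, VERGENCE_FEATURES
from .gaze_io import ConfigError

MW_LABEL, FOCUSED_LABEL = "mw", "focused"

FAMILIES = ("random-forest", "svm", "gradient-boosted-trees", "multilayer-perceptron")

#: Published default hyperparameters per family.
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "random-forest": {"n_estimators": 100},
    "svm": {"kernel": "poly", "C": 20.0},
    "gradient-boosted-trees": {"learning_rate": 0.1, "max_depth": 10},
    "multilayer-perceptron": {
        "hidden_layer_sizes": (20, 20),
        "learning_rate_init": 0.5,
        "learning_rate": "invscaling",
        "momentum": 0.3,
    },
}


#: Default tuning grids: a small neighbourhood around the published values,
#: which are listed first so ties resolve toward them.
DEFAULT_TUNING_GRIDS: dict[str, list[dict]] = {
    "random-forest": [{"n_estimators": n} for n in (100, 50, 200)],
    "svm": [{"kernel": "poly", "C": c} for c in (20.0, 10.0, 40.0)],
    "gradient-boosted-trees": [
        {"learning_rate": lr, "max_depth": d}
        for lr, d in ((0.1, 10), (0.1, 6), (0.3, 10))
    ],
    "multilayer-perceptron": [
        {**DEFAULT_HYPERPARAMETERS["multilayer-perceptron"],
         "learning_rate_init": lr}
        for lr in (0.5, 0.1, 0.9)
    ],
}


@dataclass(frozen=True)
class ModelSpec:
    family: str = "random-forest"
    hyperparameters: dict = field(default_factory=dict)
    include_vergence: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown model family {self.family!r}")

    def feature_names(self) -> list[str]:
        if self.include_vergence:
            return list(FEATURE_NAMES)
        return [f for f in FEATURE_NAMES if f not in VERGENCE_FEATURES]


def build_model(spec: ModelSpec):
    """Instantiate the scikit-learn / xgboost estimator for a spec."""
    params = {**DEFAULT_HYPERPARAMETERS[spec.family], **spec.hyperparameters}
    if spec.family == "random-forest":
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **params)
    if spec.family == "svm":
        return SVC(probability=True, random_state=spec.seed, **params)
    if spec.family == "gradient-boosted-trees":
        return XGBClassifier(
            random_state=spec.seed, n_jobs=1, eval_metric="logloss", **params
        )
    return MLPClassifier(solver="sgd", random_state=spec.seed, max_iter=300, **params)


def make_folds(
    participants, n_folds: int = 3, seed: int | np.random.Generator = 0
) -> list[list[str]]:
    """Random partition of participants into ``n_folds`` near-equal groups."""
    ids = list(dict.fromkeys(participants))
    if len(ids) < n_folds:
        raise ConfigError(f"need at least {n_folds} participants, got {len(ids)}")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    )
    order = list(rng.permutation(ids))
    return [sorted(order[i::n_folds]) for i in range(n_folds)]


def evaluate(scores, labels) -> dict[str, float | None]:
    """Classification metrics from MW-class probabilities and string labels.

    AUC is the rank (Mann–Whitney) statistic with tie handling; weighted F1
    covers both classes weighted by support; FP rate, precision and recall
    treat MW as the positive class at threshold 0.5.  With single-class
    labels the AUC is undefined and reported as ``None``.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == MW_LABEL else 0 for l in labels])
    pred = (scores >= 0.5).astype(int)
    auc = float(roc_auc_score(y, scores)) if len(np.unique(y)) == 2 else None
    tn, fp, fn, tp = confusion_matrix(y, pred, labels=[0, 1]).ravel()
    return {
        "auc": auc,
        "f1_weighted": float(f1_score(y, pred, average="weighted", zero_division=0)),
        "fp_rate": float(fp / (fp + tn)) if (fp + tn) else 0.0,
        "precision_mw": float(precision_score(y, pred, zero_division=0)),
        "recall_mw": float(recall_score(y, pred, zero_division=0)),
    }


METRICS = ("auc", "f1_weighted", "fp_rate", "precision_mw", "recall_mw")


@dataclass
class CVReport:
    """Per-fold results plus mean/SD aggregation of a grouped CV run."""

    fold_results: list[dict] = field(default_factory=list)

    def metric_values(self, name: str) -> np.ndarray:
        vals = [fr[name] for fr in self.fold_results if fr[name] is not None]
        return np.asarray(vals, dtype=float)

    def mean(self, name: str) -> float:
        return float(self.metric_values(name).mean())

    def sd(self, name: str) -> float:
        v = self.metric_values(name)
        return float(v.std(ddof=1)) if len(v) >= 2 else 0.0

    def summary(self) -> dict[str, dict[str, float]]:
        return {m: {"mean": self.mean(m), "sd": self.sd(m)} for m in METRICS}


def null_calibration(
    matrix: pd.DataFrame,
    spec: ModelSpec | None = None,
    iterations: int = 5,
    n_folds: int = 3,
    seed: int = 0,
) -> CVReport:
    """Grouped CV under the label-permutation null (chance calibration).

    Each iteration draws a *fresh* global permutation of the labels before
    its fold sweep, so permutation-specific chance alignments between a
    participant's feature profile and its shuffled base rate average out
    across iterations; the mean AUC of the pooled fold results then sits
    tightly at 0.5 for any cohort with no true signal.
    """
    spec = spec or ModelSpec()
    labeled = matrix[matrix["label"].isin([MW_LABEL, FOCUSED_LABEL])].reset_index(
        drop=True
    )
    report = CVReport()
    root = np.random.SeedSequence(seed)
    for it, ss in enumerate(root.spawn(iterations)):
        rng = np.random.Generator(np.random.PCG64(ss))
        shuffled = labeled.copy()
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        sub = cross_validate(
            shuffled, spec, iterations=1, n_folds=n_folds,
            seed=int(rng.integers(2**31 - 1)),
        )
        for fr in sub.fold_results:
            fr["iteration"] = it
            report.fold_results.append(fr)
    return report


def _training_frame(matrix: pd.DataFrame, feature_names: list[str]) -> pd.DataFrame:
    labeled = matrix[matrix["label"].isin([MW_LABEL, FOCUSED_LABEL])]
    missing = [f for f in feature_names if f not in labeled.columns]
    if missing:
        raise ConfigError(f"feature matrix lacks columns: {missing}")
    return labeled


def cross_validate(
    matrix: pd.DataFrame,
    spec: ModelSpec | None = None,
    iterations: int = 5,
    n_folds: int = 3,
    seed: int = 0,
) -> CVReport:
    """Five iterations of participant-grouped 3-fold CV (15 fold results).

    Each iteration redraws the participant partition; within a fold the
    model trains on the out-of-test participants only (leakage is asserted
    structurally) and is scored on every labelled window of the held-out
    participants.
    """
    spec = spec or ModelSpec()
    feats = spec.feature_names()
    data = _training_frame(matrix, feats)
    ids = sorted(data["participant"].unique())
    report = CVReport()
    root = np.random.SeedSequence(seed)
    for it, ss in enumerate(root.spawn(iterations)):
        rng = np.random.Generator(np.random.PCG64(ss))
        folds = make_folds(ids, n_folds, rng)
        for fold_idx, test_ids in enumerate(folds):
            test_mask = data["participant"].isin(test_ids)
            train = data[~test_mask]
            test = data[test_mask]
            assert not set(train["participant"]) & set(test["participant"]), (
                "participant leakage between train and test"
            )
            if train["label"].nunique() < 2 or test.empty:
                continue
            model = build_model(replace(spec, seed=spec.seed + 1000 * it + fold_idx))
            model.fit(train[feats].to_numpy(), (train["label"] == MW_LABEL).astype(int))
            mw_col = list(model.classes_).index(1)
            scores = model.predict_proba(test[feats].to_numpy())[:, mw_col]
            result = evaluate(scores, test["label"])
            result.update({"iteration": it, "fold": fold_idx, "test_participants": test_ids})
            report.fold_results.append(result)
    return report


def tune(
    matrix: pd.DataFrame,
    family: str,
    grid: list[dict] | None = None,
    iterations: int = 5,
    n_folds: int = 3,
    seed: int = 0,
) -> dict:
    """Pick hyperparameters by modal choice across the 15 CV trials.

    Per fold, every grid point is trained and scored by AUC; the grid point
    winning most folds is returned.  Ties resolve toward the earliest grid
    entry, so listing the published values first keeps them preferred.
    ``grid=None`` uses :data:`DEFAULT_TUNING_GRIDS` for the family.
    """
    if grid is None:
        grid = DEFAULT_TUNING_GRIDS[family]
    if not grid:
        raise ConfigError("hyperparameter grid is empty")
    spec0 = ModelSpec(family=family)
    feats = spec0.feature_names()
    data = _training_frame(matrix, feats)
    ids = sorted(data["participant"].unique())
    wins: Counter[int] = Counter()
    root = np.random.SeedSequence(seed)
    for it, ss in enumerate(root.spawn(iterations)):
        rng = np.random.Generator(np.random.PCG64(ss))
        for fold_idx, test_ids in enumerate(make_folds(ids, n_folds, rng)):
            test_mask = data["participant"].isin(test_ids)
            train, test = data[~test_mask], data[test_mask]
            if train["label"].nunique() < 2 or test["label"].nunique() < 2:
                continue
            best, best_auc = None, -np.inf
            for gi, params in enumerate(grid):
                spec = ModelSpec(family=family, hyperparameters=params,
                                 seed=1000 * it + fold_idx)
                model = build_model(spec)
                model.fit(
                    train[feats].to_numpy(),
                    (train["label"] == MW_LABEL).astype(int),
                )
                mw_col = list(model.classes_).index(1)
                scores = model.predict_proba(test[feats].to_numpy())[:, mw_col]
                auc = evaluate(scores, test["label"])["auc"]
                if auc is not None and auc > best_auc:
                    best, best_auc = gi, auc
            if best is not None:
                wins[best] += 1
    winner = min(wins, key=lambda gi: (-wins[gi], gi))
    return grid[winner]


# ---------------------------------------------------------------------------
# Information gain with MDL discretisation


def _entropy(counts) -> float:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _class_counts(y: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(y, minlength=n_classes)


def _mdl_cut_points(x: np.ndarray, y: np.ndarray, n_classes: int) -> list[float]:
    """Recursive entropy-minimisation cut points with the MDL stop rule."""
    order = np.argsort(x, kind="mergesort")
    x, y = x[order], y[order]

    def recurse(lo: int, hi: int) -> list[float]:
        n = hi - lo
        if n < 2:
            return []
        xs, ys = x[lo:hi], y[lo:hi]
        total_counts = _class_counts(ys, n_classes)
        ent = _entropy(total_counts)
        if ent == 0.0:
            return []
        # candidate boundaries: midpoints between distinct adjacent values
        best_gain, best_i, best_cut = 0.0, None, None
        left = np.zeros(n_classes)
        for i in range(1, n):
            left[ys[i - 1]] += 1
            if xs[i] == xs[i - 1]:
                continue
            right = total_counts - left
            e1, e2 = _entropy(left), _entropy(right)
            gain = ent - (i / n) * e1 - ((n - i) / n) * e2
            if gain > best_gain + 1e-12:
                best_gain, best_i, best_cut = gain, i, (xs[i - 1] + xs[i]) / 2.0
        if best_i is None:
            return []
        k = int((total_counts > 0).sum())
        left = _class_counts(ys[:best_i], n_classes)
        right = total_counts - left
        k1 = int((left > 0).sum())
        k2 = int((right > 0).sum())
        delta = (
            math.log2(3**k - 2)
            - (k * ent - k1 * _entropy(left) - k2 * _entropy(right))
        )
        threshold = (math.log2(n - 1) + delta) / n
        if best_gain <= threshold:
            return []
        return recurse(lo, lo + best_i) + [best_cut] + recurse(lo + best_i, hi)

    return recurse(0, len(x))


def info_gain_ranking(matrix: pd.DataFrame, feature_names=None) -> pd.DataFrame:
    """Rank features by information gain after MDL discretisation.

    IG = H(class) − H(class | bins); features for which no cut passes the
    MDL criterion (including constants) score 0.  Returns a data frame
    sorted by descending gain, ties broken alphabetically.
    """
    feature_names = list(feature_names or FEATURE_NAMES)
    data = _training_frame(matrix, feature_names)
    y = (data["label"] == MW_LABEL).astype(int).to_numpy()
    n_classes = 2
    h_class = _entropy(_class_counts(y, n_classes))
    rows = []
    for name in feature_names:
        x = data[name].to_numpy(dtype=float)
        cuts = _mdl_cut_points(x, y, n_classes)
        if not cuts:
            rows.append({"feature": name, "info_gain": 0.0, "n_bins": 1})
            continue
        bins = np.digitize(x, cuts)
        cond = 0.0
        for b in np.unique(bins):
            sel = y[bins == b]
            cond += len(sel) / len(y) * _entropy(_class_counts(sel, n_classes))
        rows.append(
            {"feature": name, "info_gain": h_class - cond, "n_bins": len(cuts) + 1}
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["info_gain", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def ablate(
    matrix: pd.DataFrame,
    feature_names_to_drop: list[str],
    spec: ModelSpec | None = None,
    iterations: int = 5,
    seed: int = 0,
) -> tuple[CVReport, CVReport, dict[str, float]]:
    """CV with and without the named features, identical folds and seeds.

    Returns ``(full_report, ablated_report, deltas)`` with
    ``delta = ablated_mean − full_mean`` per metric.
    """
    spec = spec or ModelSpec()
    unknown = set(feature_names_to_drop) - set(FEATURE_NAMES)
    if unknown:
        raise ConfigError(f"unknown feature name(s): {sorted(unknown)}")
    full = cross_validate(matrix, spec, iterations=iterations, seed=seed)
    kept = [c for c in matrix.columns if c not in feature_names_to_drop]
    ablated_matrix = matrix[kept]
    ablated_spec = spec

    # temporarily narrow the feature list seen by cross_validate
    keep_feats = [f for f in spec.feature_names() if f not in feature_names_to_drop]

    class _NarrowSpec(ModelSpec):
        def feature_names(self) -> list[str]:  # type: ignore[override]
            return keep_feats

    narrow = _NarrowSpec(
        family=spec.family,
        hyperparameters=spec.hyperparameters,
        include_vergence=spec.include_vergence,
        seed=spec.seed,
    )
    ablated = cross_validate(ablated_matrix, narrow, iterations=iterations, seed=seed)
    deltas = {
        m: ablated.mean(m) - full.mean(m)
        for m in METRICS
        if len(full.metric_values(m)) and len(ablated.metric_values(m))
    }
    return full, ablated, deltas
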