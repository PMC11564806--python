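"""Validation statistics: correctness encoding, rmcorr, point-biserial.

The quiz-based validation asks whether seconds classified as mind wandering
during the critical sentence of an audio clip predict answering its quiz
question incorrectly.  Because every participant contributes many clips,
ordinary correlation would violate independence; the repeated-measures
correlation (rmcorr) removes between-participant variance with an analysis
of covariance — participant as factor, the covariate's common slope shared
across participants — and reports the common within-participant
correlation with df = N − k − 1 for N observations from k participants.
As a robustness companion, the point-biserial route first averages within
participants and correlates the k aggregated pairs (df = k − 2).

Binary variables (correct/incorrect) enter both statistics as 0/1 numerics.
Confidence intervals use the Fisher z transform with SE = 1/sqrt(df − 1);
p-values come from the t transform of r at the respective df.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gaze_io import NOT_SURE, QuizResponse

logger = logging.getLogger(__name__)


def encode_correctness(responses: list[QuizResponse]) -> pd.DataFrame:
    """Binary outcomes from quiz responses: 1 iff the correct option was chosen.

    Choosing any other option — including the "I am not sure" escape that
    discourages random guessing — encodes as 0.  Missing responses
    (``chosen_option`` is None) are excluded and the exclusion count logged.
    Returns a frame with columns ``clip_id, correct``.
    """
    rows, excluded = [], 0
    for r in responses:
        if r.chosen_option is None:
            excluded += 1
            continue
        correct = int(r.chosen_option != NOT_SURE and r.chosen_option == r.correct_option)
        rows.append({"clip_id": r.clip_id, "correct": correct})
    if excluded:
        logger.warning("excluded %d quiz response(s) with missing choice", excluded)
    return pd.DataFrame(rows, columns=["clip_id", "correct"])


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation with its df, two-sided p and 95% CI."""

    r: float
    df: int
    p: float
    ci95: tuple[float, float]


def _fisher_ci(r: float, se_n: int, level: float = 0.95) -> tuple[float, float]:
    if se_n <= 0:
        return (float("nan"), float("nan"))
    z = math.atanh(max(min(r, 1 - 1e-15), -1 + 1e-15))
    zc = sps.norm.ppf(0.5 + level / 2.0)
    half = zc / math.sqrt(se_n)
    return (math.tanh(z - half), math.tanh(z + half))


def _r_to_p(r: float, df: int) -> float:
    if df <= 0 or abs(r) >= 1:
        return 0.0 if abs(r) >= 1 else float("nan")
    t = r * math.sqrt(df / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df))


def rmcorr_df(n_observations: int, n_participants: int) -> int:
    """Error degrees of freedom of rmcorr: N − k − 1."""
    return n_observations - n_participants - 1


def rmcorr(x, y, participants) -> CorrelationResult:
    """Repeated-measures correlation of x and y across participants.

    ANCOVA with participant as factor and x as covariate: removing each
    participant's mean from both variables leaves the within-participant
    variation, whose pooled correlation (sign taken from the common slope)
    is r_rm with df = N − k − 1.  Equivalent to
    r = sign(b) * sqrt(SS_covariate / (SS_covariate + SS_error)).
    """
    df_in = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float),
                          "p": np.asarray(participants)}).dropna()
    if df_in["p"].nunique() < 2 or len(df_in) < 4:
        raise ValueError("rmcorr needs >=2 participants with >=2 observations")
    singletons = df_in.groupby("p").size()
    n_single = int((singletons < 2).sum())
    if n_single:
        logger.warning(
            "%d participant(s) with <2 observations contribute no "
            "within-participant information", n_single,
        )
    xc = df_in["x"] - df_in.groupby("p")["x"].transform("mean")
    yc = df_in["y"] - df_in.groupby("p")["y"].transform("mean")
    ss_x = float(xc @ xc)
    if ss_x == 0.0:
        raise ValueError("covariate has no within-participant variance")
    slope = float(xc @ yc) / ss_x
    ss_cov = slope * float(xc @ yc)  # regression SS of the common slope
    ss_err = float(yc @ yc) - ss_cov
    n, k = len(df_in), df_in["p"].nunique()
    dof = rmcorr_df(n, k)
    if ss_cov + ss_err == 0.0:
        raise ValueError("response has no within-participant variance")
    r = math.copysign(math.sqrt(ss_cov / (ss_cov + ss_err)), slope)
    return CorrelationResult(
        r=r, df=dof, p=_r_to_p(r, dof), ci95=_fisher_ci(r, dof - 1)
    )


def point_biserial_aggregate(x_means, y_means) -> CorrelationResult:
    """Pearson correlation of per-participant aggregates (df = k − 2).

    ``x_means`` and ``y_means`` hold one value per participant, e.g. the
    mean MW percentage and the proportion of incorrect answers.
    """
    x = np.asarray(x_means, float)
    y = np.asarray(y_means, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need aligned aggregates for >=3 participants")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in an aggregate")
    r, _ = sps.pearsonr(x, y)
    k = len(x)
    dof = k - 2
    return CorrelationResult(
        r=float(r), df=dof, p=_r_to_p(float(r), dof), ci95=_fisher_ci(float(r), k - 3)
    )
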