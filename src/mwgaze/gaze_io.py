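"""File formats and validated containers for gaze recordings and session events.

All timestamps are seconds since recording start (floating point, t = 0 at
start).  Gaze coordinates are 0-based wall pixels with y increasing downward.
Durations inside feature values are milliseconds; everything else stays in
seconds so units never mix across modules.

Formats
-------
Gaze log
    CSV with header ``t,lx,ly,rx,ry,cx,cy,valid`` (``valid`` in {0, 1}).
    The combined columns ``cx, cy`` are optional; when absent the combined
    point is recomputed as the mean of the left and right gaze points.
Session events
    JSON object with keys ``trials``, ``fades``, ``critical_sentences``,
    ``quiz`` (see :class:`SessionEvents`).
Feature matrix
    CSV with the metadata columns ``participant, trial_id, window_start,
    label`` followed by the 37 feature columns in the fixed order defined by
    :data:`mwgaze.features.FEATURE_NAMES`.
Config
    YAML with viewing geometry, I-DT thresholds, the assumed fade reaction
    time, and seeds (see :func:`load_config`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

NOMINAL_RATE_HZ = 120.0
#: "I am not sure" sentinel in quiz responses.
NOT_SURE = "not_sure"


class FormatError(ValueError):
    """File does not conform to the documented schema."""


class DataError(ValueError):
    """File parses but violates a data invariant."""


class ReferenceError_(DataError):
    """Cross-reference (trial_id / clip_id) does not resolve."""


class ConfigError(ValueError):
    """Invalid or missing configuration value."""


@dataclass(frozen=True)
class ViewingGeometry:
    """Viewing geometry linking visual angle to wall pixels.

    Parameters
    ----------
    viewer_distance : float
        Distance from the eyes to the wall, metres.
    pixels_per_metre : float
        Wall resolution, px/m.
    tracker_accuracy_deg : float
        Reported accuracy of the eye tracker, degrees of visual angle.
    """

    viewer_distance: float = 1.8
    pixels_per_metre: float = 1000.0
    tracker_accuracy_deg: float = 0.5

    def __post_init__(self) -> None:
        if (
            self.viewer_distance <= 0
            or self.pixels_per_metre <= 0
            or self.tracker_accuracy_deg <= 0
        ):
            raise ConfigError("viewing geometry values must be strictly positive")


@dataclass(frozen=True)
class GazeSample:
    """One binocular gaze measurement in wall coordinates."""

    t: float
    left: tuple[float, float]
    right: tuple[float, float]
    combined: tuple[float, float]
    valid: bool


class GazeData:
    """Time-ordered series of binocular gaze samples (column arrays).

    Stored as parallel numpy arrays for speed; :meth:`samples` yields
    :class:`GazeSample` records when per-sample access is clearer.
    Invalid samples are retained with ``valid=False`` and their coordinates
    are ignored downstream.
    """

    __slots__ = ("t", "lx", "ly", "rx", "ry", "cx", "cy", "valid")

    def __init__(self, t, lx, ly, rx, ry, cx, cy, valid):
        arrays = [np.asarray(a, dtype=float) for a in (t, lx, ly, rx, ry, cx, cy)]
        n = len(arrays[0])
        if any(len(a) != n for a in arrays):
            raise FormatError("gaze columns have unequal lengths")
        dt = np.diff(arrays[0])
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise DataError(f"timestamps not strictly increasing at row {row}")
        self.t, self.lx, self.ly, self.rx, self.ry, self.cx, self.cy = arrays
        self.valid = np.asarray(valid, dtype=bool)
        if len(self.valid) != n:
            raise FormatError("valid column length mismatch")

    def __len__(self) -> int:
        return len(self.t)

    def samples(self) -> Iterable[GazeSample]:
        for i in range(len(self)):
            yield GazeSample(
                t=float(self.t[i]),
                left=(float(self.lx[i]), float(self.ly[i])),
                right=(float(self.rx[i]), float(self.ry[i])),
                combined=(float(self.cx[i]), float(self.cy[i])),
                valid=bool(self.valid[i]),
            )

    def slice_time(self, start: float, end: float) -> "GazeData":
        """Samples with ``start <= t < end`` (cheap view-copy)."""
        i0, i1 = np.searchsorted(self.t, [start, end])
        return GazeData(
            self.t[i0:i1], self.lx[i0:i1], self.ly[i0:i1],
            self.rx[i0:i1], self.ry[i0:i1], self.cx[i0:i1], self.cy[i0:i1],
            self.valid[i0:i1],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t, "lx": self.lx, "ly": self.ly,
                "rx": self.rx, "ry": self.ry, "cx": self.cx, "cy": self.cy,
                "valid": self.valid.astype(int),
            }
        )


GAZE_COLUMNS = ["t", "lx", "ly", "rx", "ry", "cx", "cy", "valid"]


def read_gaze_log(path, geometry: ViewingGeometry | None = None) -> GazeData:
    """Read a gaze-log CSV into a :class:`GazeData` series.

    Rows are kept in time order; rows whose coordinates fail to parse are
    rejected (never imputed) and the rejected count is logged so that
    ``input rows == parsed + rejected`` can always be reconciled.
    When the combined columns are absent, the combined point is the mean of
    the left and right points.
    """
    df = pd.read_csv(path)
    required = {"t", "lx", "ly", "rx", "ry", "valid"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"gaze log {path} missing column(s): {sorted(missing)}")
    n_input = len(df)
    numeric_cols = [c for c in GAZE_COLUMNS if c in df.columns]
    coerced = df[numeric_cols].apply(pd.to_numeric, errors="coerce")
    # invalid rows may legitimately carry NaN coordinates; only reject rows
    # that claim validity but are unparseable
    valid_flag = coerced["valid"].fillna(0).astype(bool)
    coord_cols = [c for c in numeric_cols if c not in ("t", "valid")]
    bad = coerced["t"].isna() | (valid_flag & coerced[coord_cols].isna().any(axis=1))
    n_rejected = int(bad.sum())
    if n_rejected:
        logger.warning(
            "%s: rejected %d malformed row(s), parsed %d of %d",
            path, n_rejected, n_input - n_rejected, n_input,
        )
    df = coerced[~bad].copy()
    df["valid"] = valid_flag[~bad]
    df.loc[~df["valid"], coord_cols] = np.nan
    if "cx" not in df.columns or "cy" not in df.columns:
        df["cx"] = (df["lx"] + df["rx"]) / 2.0
        df["cy"] = (df["ly"] + df["ry"]) / 2.0
    return GazeData(
        df["t"], df["lx"], df["ly"], df["rx"], df["ry"],
        df["cx"], df["cy"], df["valid"],
    )


def write_gaze_log(gaze: GazeData, path) -> None:
    gaze.to_frame().to_csv(path, index=False, float_format="%.9f")


# ---------------------------------------------------------------------------
# Session events


@dataclass(frozen=True)
class Trial:
    trial_id: str
    kind: str  # "focused_short" | "mw_long"
    start: float
    end: float


@dataclass(frozen=True)
class FadeEvent:
    trial_id: str
    effect_start: float
    keypress: float


@dataclass(frozen=True)
class CriticalSentence:
    trial_id: str
    clip_id: str
    start: float
    end: float


@dataclass(frozen=True)
class QuizResponse:
    clip_id: str
    chosen_option: str | None
    correct_option: str


TRIAL_KINDS = {"focused_short", "mw_long"}


@dataclass
class SessionEvents:
    """Event stream of one recording session.

    Invariants (checked in :meth:`validate`): events lie inside their trial,
    ``keypress >= effect_start``, fade intervals within a trial do not
    overlap, every ``trial_id`` / ``clip_id`` reference resolves.
    """

    trials: list[Trial] = field(default_factory=list)
    fades: list[FadeEvent] = field(default_factory=list)
    critical_sentences: list[CriticalSentence] = field(default_factory=list)
    quiz: list[QuizResponse] = field(default_factory=list)

    def trial(self, trial_id: str) -> Trial:
        for tr in self.trials:
            if tr.trial_id == trial_id:
                return tr
        raise ReferenceError_(f"unknown trial_id {trial_id!r}")

    def validate(self) -> "SessionEvents":
        ids = [tr.trial_id for tr in self.trials]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate trial_id")
        for tr in self.trials:
            if tr.kind not in TRIAL_KINDS:
                raise DataError(f"unknown trial kind {tr.kind!r}")
            if tr.end <= tr.start:
                raise DataError(f"trial {tr.trial_id}: end <= start")
        by_trial: dict[str, list[FadeEvent]] = {}
        for fd in self.fades:
            tr = self.trial(fd.trial_id)
            if fd.keypress < fd.effect_start:
                raise DataError(
                    f"trial {fd.trial_id}: keypress {fd.keypress} before "
                    f"effect_start {fd.effect_start}"
                )
            if not (tr.start <= fd.effect_start and fd.keypress <= tr.end):
                raise DataError(f"fade outside trial {fd.trial_id} bounds")
            by_trial.setdefault(fd.trial_id, []).append(fd)
        for trial_id, fds in by_trial.items():
            fds = sorted(fds, key=lambda f: f.effect_start)
            for a, b in zip(fds, fds[1:]):
                if b.effect_start < a.keypress:
                    raise DataError(f"overlapping fades in trial {trial_id}")
        clip_ids = set()
        for cs in self.critical_sentences:
            tr = self.trial(cs.trial_id)
            if not (tr.start <= cs.start <= cs.end <= tr.end):
                raise DataError(f"critical sentence outside trial {cs.trial_id}")
            clip_ids.add(cs.clip_id)
        for q in self.quiz:
            if q.clip_id not in clip_ids:
                raise ReferenceError_(f"quiz references unknown clip_id {q.clip_id!r}")
        return self

    def to_dict(self) -> dict:
        return {
            "trials": [vars(tr).copy() for tr in self.trials],
            "fades": [vars(fd).copy() for fd in self.fades],
            "critical_sentences": [vars(cs).copy() for cs in self.critical_sentences],
            "quiz": [vars(q).copy() for q in self.quiz],
        }


def read_session_events(path) -> SessionEvents:
    """Read and validate a session-event JSON document."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        ev = SessionEvents(
            trials=[Trial(**tr) for tr in doc.get("trials", [])],
            fades=[FadeEvent(**fd) for fd in doc.get("fades", [])],
            critical_sentences=[
                CriticalSentence(**cs) for cs in doc.get("critical_sentences", [])
            ],
            quiz=[QuizResponse(**q) for q in doc.get("quiz", [])],
        )
    except TypeError as exc:
        raise FormatError(f"session events {path}: {exc}") from exc
    return ev.validate()


def write_session_events(events: SessionEvents, path) -> None:
    events.validate()
    with open(path, "w") as fh:
        json.dump(events.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# Feature matrix

METADATA_COLUMNS = ["participant", "trial_id", "window_start", "label"]


def write_feature_matrix(rows: Sequence, path) -> None:
    """Write :class:`~mwgaze.features.WindowFeatures` rows to CSV.

    Columns: ``participant, trial_id, window_start, label`` then the 37
    features in their fixed documented order.  All rows must share one
    feature schema.
    """
    from .features import FEATURE_NAMES  # cycle-free: features imports nothing IO

    records = []
    for row in rows:
        if list(row.features.keys()) != FEATURE_NAMES:
            raise FormatError("feature schema mismatch across rows")
        rec = {
            "participant": row.participant,
            "trial_id": row.trial_id,
            "window_start": row.window_start,
            "label": row.label,
        }
        rec.update(row.features)
        records.append(rec)
    df = pd.DataFrame(records, columns=METADATA_COLUMNS + FEATURE_NAMES)
    df.to_csv(path, index=False, float_format="%.12g")


def read_feature_matrix(path) -> pd.DataFrame:
    """Read a feature-matrix CSV; validates the 37-column schema."""
    from .features import FEATURE_NAMES

    df = pd.read_csv(path)
    expected = METADATA_COLUMNS + FEATURE_NAMES
    if list(df.columns) != expected:
        raise FormatError(f"feature matrix {path}: unexpected column set")
    if df.empty:
        # preserve dtypes for a header-only file
        df = df.astype({c: float for c in FEATURE_NAMES} | {"window_start": float})
    return df


# ---------------------------------------------------------------------------
# Config


@dataclass
class PipelineConfig:
    """Thresholds shared by the batch and streaming pipelines."""

    geometry: ViewingGeometry = field(default_factory=ViewingGeometry)
    dispersion_deg: float = 1.0
    min_duration_ms: float = 100.0
    gap_tolerance_ms: float = 75.0
    saccade_max_gap_ms: float = 200.0
    min_valid_fraction: float = 0.5
    reaction_time_s: float = 3.59
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_valid_fraction <= 1.0):
            raise ConfigError("min_valid_fraction must lie in [0, 1]")
        for name in ("dispersion_deg", "min_duration_ms", "reaction_time_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config; absent keys keep their defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    geo = ViewingGeometry(**doc.pop("geometry", {}))
    try:
        return PipelineConfig(geometry=geo, **doc)
    except TypeError as exc:
        raise ConfigError(f"config {path}: {exc}") from exc


def save_config(config: PipelineConfig, path) -> None:
    doc = {k: v for k, v in vars(config).items() if k != "geometry"}
    doc["geometry"] = vars(config.geometry).copy()
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)
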