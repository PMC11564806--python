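"""Focused/MW labels from the audio fade-out probe protocol.

During long trials the audio volume starts to fade at random times; the
listener presses a key once they notice.  Subtracting an assumed reaction
time (3.59 s, the fast-fade mean from the calibration experiment) from the
keypress gives the moment the fade was *noticed*; everything between the
fade onset and that moment is labelled mind wandering (MW), and the
reaction interval itself (notice → keypress) is excluded from training
because the listener was busy reacting, not necessarily wandering.  Short
trials with explicit attention instructions are labelled focused in full.

A 1-s feature window receives a label only when it is *fully contained* in a
span of that label, which prevents label bleed across the window grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaze_io import DataError, SessionEvents
from .features import WindowFeatures

#: Mean reaction time (s) to the fast volume fade-out, from the calibration
#: experiment; the annotation default.
DEFAULT_REACTION_TIME_S = 3.59

FADE_SPEEDS = {"fast": 5.0, "medium": 2.5, "slow": 1.67}  # volume %/s
WPM_SPEEDS = {"fast": 9.0, "medium": 4.5, "slow": 3.0}  # speech wpm/s
VOLUME_FLOOR_PCT = 0.01


@dataclass(frozen=True)
class FadeParams:
    """Fade-out envelope parameters.

    ``mode`` selects what degrades (volume, speech speed, or both);
    ``volume_decrement`` is in percentage points per second, ``wpm_decrement``
    in words-per-minute per second.  The study default is the fast volume
    fade (5 %/s) with the 3.59 s mean reaction time.
    """

    mode: str = "volume"  # volume | speed | both
    speed_class: str = "fast"
    volume_decrement: float = FADE_SPEEDS["fast"]
    wpm_decrement: float = WPM_SPEEDS["fast"]
    floor: float = VOLUME_FLOOR_PCT
    reaction_time: float = DEFAULT_REACTION_TIME_S

    def __post_init__(self) -> None:
        if self.volume_decrement <= 0 or self.wpm_decrement <= 0:
            raise ValueError("fade decrements must be positive")
        if self.reaction_time <= 0:
            raise ValueError("reaction_time must be positive")

    @classmethod
    def for_speed(cls, speed_class: str, mode: str = "volume") -> "FadeParams":
        return cls(
            mode=mode,
            speed_class=speed_class,
            volume_decrement=FADE_SPEEDS[speed_class],
            wpm_decrement=WPM_SPEEDS[speed_class],
        )


def fade_envelope(t_since_effect: float, params: FadeParams | None = None) -> float:
    """Volume (%) ``t_since_effect`` seconds after fade onset.

    Linear in percentage points, clamped at the 0.01 % floor:
    ``max(100 - decrement * t, floor)``.
    """
    if params is None:
        params = FadeParams()
    t = np.asarray(t_since_effect, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_effect must be non-negative")
    out = np.maximum(100.0 - params.volume_decrement * t, params.floor)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class LabeledSpan:
    """A labelled time interval inside one trial."""

    trial_id: str
    start: float
    end: float
    label: str  # focused | mw | excluded_reaction

    def contains_window(self, t0: float, t1: float) -> bool:
        return self.start <= t0 and t1 <= self.end


def label_mw_spans(
    events: SessionEvents,
    reaction_time: float = DEFAULT_REACTION_TIME_S,
) -> list[LabeledSpan]:
    """MW and excluded-reaction spans from the fade events of long trials.

    Per fade: ``notice = keypress - reaction_time``.  If the notice time
    falls after the fade onset, [effect_start, notice] is MW and
    [notice, keypress] is excluded; otherwise the whole
    [effect_start, keypress] interval is excluded (the listener reacted
    within the assumed reaction time, so no MW can be claimed).
    """
    spans: list[LabeledSpan] = []
    for fade in events.fades:
        trial = events.trial(fade.trial_id)
        if trial.kind != "mw_long":
            continue
        if not (trial.start <= fade.effect_start and fade.keypress <= trial.end):
            raise DataError(f"fade outside trial {fade.trial_id} bounds")
        notice = fade.keypress - reaction_time
        if notice > fade.effect_start:
            spans.append(LabeledSpan(fade.trial_id, fade.effect_start, notice, "mw"))
            spans.append(
                LabeledSpan(fade.trial_id, notice, fade.keypress, "excluded_reaction")
            )
        else:
            spans.append(
                LabeledSpan(
                    fade.trial_id, fade.effect_start, fade.keypress,
                    "excluded_reaction",
                )
            )
    return spans


def label_focused_trials(events: SessionEvents) -> list[LabeledSpan]:
    """One focused span covering each short attention trial in full."""
    return [
        LabeledSpan(tr.trial_id, tr.start, tr.end, "focused")
        for tr in events.trials
        if tr.kind == "focused_short"
    ]


def label_session(
    events: SessionEvents,
    reaction_time: float = DEFAULT_REACTION_TIME_S,
) -> list[LabeledSpan]:
    """All labelled spans of a session (focused trials + fade-derived MW)."""
    return label_focused_trials(events) + label_mw_spans(events, reaction_time)


def assign_labels(
    windows: list[WindowFeatures],
    spans: list[LabeledSpan],
    containment: bool = True,
) -> list[WindowFeatures]:
    """Label windows in place by span containment (default) or overlap.

    A window gets ``mw`` or ``focused`` only when fully contained in a span
    of that label (or merely overlapping, with ``containment=False``);
    windows touching an excluded-reaction span, or contained in no span,
    stay ``unlabeled``.  Contradictory spans raise :class:`DataError`.
    """
    by_trial: dict[str, list[LabeledSpan]] = {}
    for sp in spans:
        if sp.end < sp.start:
            raise DataError("span end before start")
        by_trial.setdefault(sp.trial_id, []).append(sp)
    for trial_id, sps in by_trial.items():
        informative = sorted(
            (s for s in sps if s.label in ("mw", "focused")), key=lambda s: s.start
        )
        for a, b in zip(informative, informative[1:]):
            if b.start < a.end and a.label != b.label:
                raise DataError(f"contradictory overlapping spans in {trial_id}")
    for w in windows:
        t0, t1 = w.window_start, w.window_start + 1.0
        w.label = "unlabeled"
        hit = None
        for sp in by_trial.get(w.trial_id, ()):
            qualifies = (
                sp.contains_window(t0, t1)
                if containment
                else (sp.start < t1 and sp.end > t0)
            )
            if qualifies and sp.label in ("mw", "focused"):
                hit = sp.label if hit in (None, sp.label) else "conflict"
            elif not containment and qualifies and sp.label == "excluded_reaction":
                hit = hit or "excluded"
        if hit == "conflict":
            raise DataError("window matched by spans of both labels")
        w.label = hit if hit in ("mw", "focused") else "unlabeled"
    return windows


def assemble_dataset(
    windows: list[WindowFeatures],
    spans: list[LabeledSpan],
    containment: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Labelled feature matrix + per-participant class report.

    Returns ``(matrix, report)``: the matrix holds every window (labelled
    ones carry ``mw``/``focused``; the rest ``unlabeled`` and excluded from
    training downstream); the report gives per-participant window counts and
    MW percentage ``mw / (mw + focused)``.
    """
    from .gaze_io import METADATA_COLUMNS
    from .features import FEATURE_NAMES

    assign_labels(windows, spans, containment=containment)
    records = []
    for w in windows:
        rec = {
            "participant": w.participant,
            "trial_id": w.trial_id,
            "window_start": w.window_start,
            "label": w.label,
        }
        rec.update(w.features)
        records.append(rec)
    matrix = pd.DataFrame(records, columns=METADATA_COLUMNS + FEATURE_NAMES)
    if matrix.empty:
        report = pd.DataFrame(columns=["participant", "mw", "focused", "unlabeled", "mw_pct"])
        return matrix, report
    counts = (
        matrix.groupby("participant")["label"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["mw", "focused", "unlabeled"], fill_value=0)
    )
    denom = (counts["mw"] + counts["focused"]).replace(0, np.nan)
    report = counts.reset_index()
    report["mw_pct"] = (100.0 * counts["mw"] / denom).to_numpy()
    return matrix, report
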