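"""Streaming per-second mind-wandering classification.

The stream classifier replays the batch pipeline incrementally: samples are
pushed one at a time, the I-DT state machine closes fixations as the data
arrive, and a 1-s window is finalised as soon as every oculomotor event
overlapping it is decided — which is also the earliest moment its feature
vector could be identical to the batch pipeline's.  Consequently the
per-second labels of a streamed replay are bit-identical to batch scoring
of the same recording.  The finalisation delay is typically a fraction of a
second (one saccade plus the ongoing fixation); an unusually long stable
fixation delays the seconds it covers until it ends, and a final flush
resolves everything at end of stream.

A second with too few valid samples is reported as ``unknown`` and excluded
from the percent-MW measure, which divides MW-classified seconds by *all
classified* seconds inside a critical-sentence span.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, valid_fraction, window_features
from .gaze_io import (
    GazeData,
    GazeSample,
    NOMINAL_RATE_HZ,
    PipelineConfig,
    SessionEvents,
)
from .oculomotor import Fixation, IDTState, Saccade, derive_saccades, px_to_deg


class StreamError(ValueError):
    """Violation of the streaming contract (e.g. time regression)."""


class ModelSchemaError(ValueError):
    """Loaded model does not match the 37-feature schema."""


@dataclass(frozen=True)
class SecondResult:
    """Classification of one whole second ``[t, t + 1)``."""

    t: float
    label: str  # mw | focused | unknown
    probability: float | None


def _check_model_schema(model) -> None:
    n = getattr(model, "n_features_in_", None)
    if n is not None and n != len(FEATURE_NAMES):
        raise ModelSchemaError(
            f"model expects {n} features, pipeline produces {len(FEATURE_NAMES)}"
        )


class StreamState:
    """Incremental per-second classifier over one trial's sample stream.

    Parameters
    ----------
    model
        Fitted scikit-learn style classifier over the 37-feature vector
        (class 1 = MW).
    config : PipelineConfig
        Shared thresholds (I-DT, gap tolerance, minimum valid fraction).
    t0 : float
        Trial start; windows are anchored at ``t0 + k`` seconds.
    t_end : float or None
        Trial end; the trailing partial window is discarded, matching batch.
    """

    def __init__(self, model, config: PipelineConfig | None = None,
                 t0: float = 0.0, t_end: float | None = None):
        self.config = config or PipelineConfig()
        _check_model_schema(model)
        self.model = model
        self.t0 = t0
        self.t_end = t_end
        geo = self.config.geometry
        self._idt = IDTState(
            self.config.dispersion_deg, self.config.min_duration_ms, geo,
            self.config.gap_tolerance_ms,
        )
        self._geometry = geo
        # column buffers of every pushed sample (events overlapping a window
        # may extend beyond it, so feature computation needs history)
        self._cols: list[list[float]] = [[] for _ in range(7)]
        self._valid: list[bool] = []
        self._fixations: list[Fixation] = []
        self._saccades: list[Saccade] = []
        self._last_t = -math.inf
        self._next_window = 0  # index k of the next window to finalise
        self.results: list[SecondResult] = []

    # -- ingestion ----------------------------------------------------------

    def push_sample(self, sample: GazeSample) -> list[SecondResult]:
        """Absorb one sample; return any newly finalised second results."""
        if sample.t < self._last_t:
            raise StreamError(
                f"time regression: {sample.t} after {self._last_t}"
            )
        self._last_t = sample.t
        for col, value in zip(
            self._cols,
            (sample.t, sample.left[0], sample.left[1], sample.right[0],
             sample.right[1], sample.combined[0], sample.combined[1]),
        ):
            col.append(value)
        self._valid.append(sample.valid)
        closed = self._idt.feed(
            sample.t, sample.combined[0], sample.combined[1], sample.valid
        )
        self._absorb(closed)
        return self._finalise(now=sample.t, frontier=self._frontier())

    def finish(self) -> list[SecondResult]:
        """End of stream: close the open window and finalise all seconds.

        With a known trial end every remaining window up to it is emitted
        (matching batch segmentation even when samples stop early); without
        one, emission stops at the last completed second seen.
        """
        self._absorb(self._idt.finish())
        if self.t_end is not None:
            now = math.inf  # _finalise stops at t_end
        elif math.isfinite(self._last_t):
            now = self._last_t
        else:
            now = self.t0  # nothing was pushed
        return self._finalise(now=now, frontier=math.inf)

    # -- internals ----------------------------------------------------------

    def _absorb(self, closed: list[Fixation]) -> None:
        for fx in closed:
            if self._fixations:
                self._saccades.extend(
                    derive_saccades(
                        [self._fixations[-1], fx], self._geometry,
                        self.config.saccade_max_gap_ms,
                    )
                )
            self._fixations.append(fx)

    def _frontier(self) -> float:
        """Earliest time before which no event can change any more."""
        open_t = self._idt.open_start_t
        frontier = self._last_t if open_t is None else open_t
        if self._fixations:
            last_end = self._fixations[-1].end
            gap_ms = (frontier - last_end) * 1000.0
            # a saccade ending at the still-open fixation may reach back to
            # the last closed fixation's end
            if 0 < gap_ms <= self.config.saccade_max_gap_ms and open_t is not None:
                frontier = last_end
        return frontier

    def _finalise(self, now: float, frontier: float) -> list[SecondResult]:
        out = []
        while True:
            t0 = self.t0 + self._next_window
            t1 = t0 + 1.0
            if self.t_end is not None and t1 > self.t_end + 1e-9:
                break
            if now < t1 or frontier < t1:
                break
            out.append(self._classify(t0, t1))
            self._next_window += 1
        self.results.extend(out)
        return out

    def _classify(self, t0: float, t1: float) -> SecondResult:
        overlapping = [f for f in self._fixations if f.overlaps(t0, t1)]
        lo = min([t0] + [f.start for f in overlapping])
        hi = max([t1] + [f.end for f in overlapping])
        gaze = self._slice(lo, np.nextafter(hi, np.inf))
        vf = valid_fraction(gaze, t0, t1)
        if vf < self.config.min_valid_fraction:
            return SecondResult(t=t0, label="unknown", probability=None)
        feats, _ = window_features(t0, t1, gaze, overlapping, self._saccades)
        vec = np.array([[feats[name] for name in FEATURE_NAMES]])
        mw_col = list(self.model.classes_).index(1)
        p = float(self.model.predict_proba(vec)[0, mw_col])
        return SecondResult(t=t0, label="mw" if p >= 0.5 else "focused", probability=p)


    def _slice(self, t0: float, t1: float) -> GazeData:
        ts = self._cols[0]
        i0 = bisect_left(ts, t0)
        i1 = bisect_left(ts, t1)
        return GazeData(
            *[col[i0:i1] for col in self._cols], self._valid[i0:i1]
        )


def stream_recording(
    model,
    gaze: GazeData,
    events: SessionEvents,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Streamed replay of a full recording, one StreamState per trial.

    Returns the per-second table ``t, trial_id, label, probability``.
    """
    config = config or PipelineConfig()
    rows = []
    for trial in events.trials:
        state = StreamState(model, config, t0=trial.start, t_end=trial.end)
        tg = gaze.slice_time(trial.start, trial.end)
        results: list[SecondResult] = []
        for sample in tg.samples():
            results.extend(state.push_sample(sample))
        results.extend(state.finish())
        for r in results:
            rows.append(
                {
                    "t": r.t, "trial_id": trial.trial_id,
                    "label": r.label, "probability": r.probability,
                }
            )
    return pd.DataFrame(rows, columns=["t", "trial_id", "label", "probability"])


def classify_recording_batch(
    model,
    gaze: GazeData,
    events: SessionEvents,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Batch counterpart of :func:`stream_recording` (same output schema).

    Windows below the valid-fraction threshold are reported as ``unknown``
    rather than dropped so the two tables align second for second.
    """
    from .features import extract_features

    config = config or PipelineConfig()
    _check_model_schema(model)
    rows = []
    windows = extract_features(
        gaze, events, config=config, drop_low_valid=False
    )
    mw_col = list(model.classes_).index(1)
    for w in windows:
        if w.valid_fraction < config.min_valid_fraction:
            rows.append(
                {"t": w.window_start, "trial_id": w.trial_id,
                 "label": "unknown", "probability": None}
            )
            continue
        p = float(model.predict_proba(w.vector().reshape(1, -1))[0, mw_col])
        rows.append(
            {"t": w.window_start, "trial_id": w.trial_id,
             "label": "mw" if p >= 0.5 else "focused", "probability": p}
        )
    return pd.DataFrame(rows, columns=["t", "trial_id", "label", "probability"])


def percent_mw(results: pd.DataFrame, span_start: float, span_end: float) -> float | None:
    """Percent of classified seconds labelled MW inside a span.

    A second counts when its window start lies within ``[span_start,
    span_end)``.  ``unknown`` seconds are excluded from numerator and
    denominator; with zero classified seconds the measure is undefined and
    ``None`` is returned.
    """
    sel = results[(results["t"] >= span_start) & (results["t"] < span_end)]
    classified = sel[sel["label"].isin(["mw", "focused"])]
    if classified.empty:
        return None
    return 100.0 * float((classified["label"] == "mw").mean())
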