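"""Windowed gaze features: 37 values per non-overlapping 1-s window.

The feature set covers three oculomotor channels:

* fixation (11): seven summary statistics of fixation duration (ms), number
  of fixations per second, percentage of fixation duration, duration ratio
  of fixation over saccade, and the mean radius of the fixations' minimal
  bounding circles (px);
* saccade (22): seven summary statistics each of saccade duration (ms),
  length (px) and velocity (deg/s), plus number of saccades per second;
* vergence (4): mean and SD of the per-sample binocular disparity (px) and
  mean and SD of the per-fixation distance between the left-eye and
  right-eye sample centroids (px).

The seven summary statistics are mean, min, max, median, sample SD,
moment skewness and excess kurtosis.  Events are assigned to a window by
temporal overlap; duration *statistics* use the full (unclipped) event
durations, while the bounded *percentage* and *ratio* features clip event
time to the window.  Windows without events are zero-filled and flagged
``event_free`` so the streaming path always emits a vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .gaze_io import (
    ConfigError,
    GazeData,
    NOMINAL_RATE_HZ,
    PipelineConfig,
    SessionEvents,
    ViewingGeometry,
)
from .oculomotor import Fixation, Saccade, derive_saccades, detect_fixations

STAT_NAMES = ["mean", "min", "max", "median", "sd", "skew", "kurt"]

FIXATION_FEATURES = (
    [f"fix_duration_{s}" for s in STAT_NAMES]
    + ["fix_count_per_sec", "fix_duration_pct", "fix_sacc_duration_ratio",
       "fix_mec_radius_mean"]
)
SACCADE_FEATURES = (
    [f"sacc_duration_{s}" for s in STAT_NAMES]
    + [f"sacc_length_{s}" for s in STAT_NAMES]
    + [f"sacc_velocity_{s}" for s in STAT_NAMES]
    + ["sacc_count_per_sec"]
)
VERGENCE_FEATURES = [
    "verg_disparity_mean", "verg_disparity_sd",
    "verg_centroid_dist_mean", "verg_centroid_dist_sd",
]

#: Fixed documented feature order: 11 fixation + 22 saccade + 4 vergence = 37.
FEATURE_NAMES = FIXATION_FEATURES + SACCADE_FEATURES + VERGENCE_FEATURES
assert len(FEATURE_NAMES) == 37

WINDOW_S = 1.0


@dataclass
class WindowFeatures:
    """One 1-s window's feature vector plus metadata."""

    participant: str
    trial_id: str
    window_start: float
    valid_fraction: float
    label: str = "unlabeled"  # focused | mw | unlabeled
    event_free: bool = False
    features: dict[str, float] = field(default_factory=dict)

    def vector(self) -> np.ndarray:
        return np.array([self.features[name] for name in FEATURE_NAMES])


@dataclass(frozen=True)
class StatSeven:
    """Seven-number summary of a value list.

    Sample SD uses n-1; skewness is the moment coefficient g1 and kurtosis
    the excess moment coefficient g2.  Moments that are undefined for the
    sample size (SD for n<2, skewness n<3, kurtosis n<4) are reported as 0,
    as is everything for an empty list.
    """

    mean: float
    min: float
    max: float
    median: float
    sd: float
    skewness: float
    kurtosis: float

    def as_list(self) -> list[float]:
        return [self.mean, self.min, self.max, self.median, self.sd,
                self.skewness, self.kurtosis]


def describe(values) -> StatSeven:
    """Seven-number summary (see :class:`StatSeven` for conventions)."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n == 0:
        return StatSeven(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    sd = float(np.std(v, ddof=1)) if n >= 2 else 0.0
    skew = float(sps.skew(v, bias=True)) if n >= 3 and np.ptp(v) > 0 else 0.0
    kurt = float(sps.kurtosis(v, bias=True)) if n >= 4 and np.ptp(v) > 0 else 0.0
    # denormal variances underflow inside the moment ratios; report them as
    # the undefined-moment convention rather than NaN
    skew = skew if np.isfinite(skew) else 0.0
    kurt = kurt if np.isfinite(kurt) else 0.0
    return StatSeven(
        mean=float(v.mean()), min=float(v.min()), max=float(v.max()),
        median=float(np.median(v)), sd=sd, skewness=skew, kurtosis=kurt,
    )


def segment_windows(start: float, end: float) -> list[tuple[float, float]]:
    """Consecutive [start + k, start + k + 1) s windows; partial tail dropped."""
    if end <= start:
        return []
    n = int(math.floor((end - start) / WINDOW_S + 1e-9))
    return [(start + k * WINDOW_S, start + (k + 1) * WINDOW_S) for k in range(n)]


def _clipped_time(events, t0: float, t1: float) -> float:
    return sum(max(0.0, min(e.end, t1) - max(e.start, t0)) for e in events)


def fixation_features(
    t0: float,
    t1: float,
    fixations: list[Fixation],
    saccades: list[Saccade],
) -> dict[str, float]:
    """The 11 fixation features of window [t0, t1)."""
    fix = [f for f in fixations if f.overlaps(t0, t1)]
    sac = [s for s in saccades if s.overlaps(t0, t1)]
    stats = describe([f.duration for f in fix])
    window_len = t1 - t0
    fix_time = _clipped_time(fix, t0, t1)
    sacc_time = _clipped_time(sac, t0, t1)
    sample_period = 1.0 / NOMINAL_RATE_HZ
    out = dict(zip([f"fix_duration_{s}" for s in STAT_NAMES], stats.as_list()))
    out["fix_count_per_sec"] = len(fix) / window_len
    out["fix_duration_pct"] = fix_time / window_len
    out["fix_sacc_duration_ratio"] = (
        fix_time / max(sacc_time, sample_period) if fix else 0.0
    )
    out["fix_mec_radius_mean"] = (
        float(np.mean([f.mec_radius for f in fix])) if fix else 0.0
    )
    return out


def saccade_features(t0: float, t1: float, saccades: list[Saccade]) -> dict[str, float]:
    """The 22 saccade features of window [t0, t1)."""
    sac = [s for s in saccades if s.overlaps(t0, t1)]
    out: dict[str, float] = {}
    for attr, values in [
        ("duration", [s.duration for s in sac]),
        ("length", [s.length for s in sac]),
        ("velocity", [s.velocity for s in sac]),
    ]:
        stats = describe(values)
        out.update(zip([f"sacc_{attr}_{s}" for s in STAT_NAMES], stats.as_list()))
    out["sacc_count_per_sec"] = len(sac) / (t1 - t0)
    return out


def vergence_features(
    t0: float,
    t1: float,
    samples: GazeData,
    fixations: list[Fixation],
) -> dict[str, float]:
    """The 4 vergence features of window [t0, t1).

    Disparity is the per-sample Euclidean distance between the left and
    right gaze points of valid binocular samples in the window.  The
    centroid distance is computed per fixation overlapping the window as the
    distance between the centroid of its left-eye samples and the centroid
    of its right-eye samples.
    """
    win = samples.slice_time(t0, t1)
    m = win.valid
    disparity = np.hypot(win.lx[m] - win.rx[m], win.ly[m] - win.ry[m])
    out = {
        "verg_disparity_mean": float(disparity.mean()) if disparity.size else 0.0,
        "verg_disparity_sd": (
            float(np.std(disparity, ddof=1)) if disparity.size >= 2 else 0.0
        ),
    }
    dists = []
    for f in fixations:
        if not f.overlaps(t0, t1):
            continue
        fs = samples.slice_time(f.start, np.nextafter(f.end, np.inf))
        fm = fs.valid
        if not fm.any():
            continue
        dists.append(
            math.hypot(
                fs.lx[fm].mean() - fs.rx[fm].mean(),
                fs.ly[fm].mean() - fs.ry[fm].mean(),
            )
        )
    out["verg_centroid_dist_mean"] = float(np.mean(dists)) if dists else 0.0
    out["verg_centroid_dist_sd"] = (
        float(np.std(dists, ddof=1)) if len(dists) >= 2 else 0.0
    )
    return out


def window_features(
    t0: float,
    t1: float,
    samples: GazeData,
    fixations: list[Fixation],
    saccades: list[Saccade],
) -> tuple[dict[str, float], bool]:
    """All 37 features of one window; returns (features, event_free)."""
    feats = fixation_features(t0, t1, fixations, saccades)
    feats.update(saccade_features(t0, t1, saccades))
    feats.update(vergence_features(t0, t1, samples, fixations))
    ordered = {name: feats[name] for name in FEATURE_NAMES}
    event_free = not any(f.overlaps(t0, t1) for f in fixations)
    return ordered, event_free


def valid_fraction(samples: GazeData, t0: float, t1: float, rate_hz: float = NOMINAL_RATE_HZ) -> float:
    """Fraction of the window's nominal sample slots carrying a valid sample."""
    win = samples.slice_time(t0, t1)
    expected = max(1, round((t1 - t0) * rate_hz))
    return min(1.0, float(win.valid.sum()) / expected)


def extract_features(
    gaze: GazeData,
    events: SessionEvents,
    geometry: ViewingGeometry | None = None,
    config: PipelineConfig | None = None,
    participant: str = "p0",
    drop_low_valid: bool = True,
) -> list[WindowFeatures]:
    """Batch feature extraction over every trial of a recording.

    Fixations and saccades are detected per trial (events never span trial
    boundaries), windows are anchored at each trial's start, and windows
    whose valid-sample fraction falls below ``config.min_valid_fraction``
    are dropped (batch) — the streaming path instead reports them as
    ``unknown``.
    """
    if config is None:
        config = PipelineConfig(geometry=geometry or ViewingGeometry())
    if geometry is None:
        geometry = config.geometry
    if geometry is None:
        raise ConfigError("viewing geometry is required")
    rows: list[WindowFeatures] = []
    for trial in events.trials:
        tg = gaze.slice_time(trial.start, trial.end)
        fixations = detect_fixations(
            tg,
            dispersion_deg=config.dispersion_deg,
            min_duration_ms=config.min_duration_ms,
            geometry=geometry,
            gap_tolerance_ms=config.gap_tolerance_ms,
        )
        saccades = derive_saccades(fixations, geometry, config.saccade_max_gap_ms)
        for t0, t1 in segment_windows(trial.start, trial.end):
            vf = valid_fraction(tg, t0, t1)
            if drop_low_valid and vf < config.min_valid_fraction:
                continue
            feats, event_free = window_features(t0, t1, tg, fixations, saccades)
            rows.append(
                WindowFeatures(
                    participant=participant,
                    trial_id=trial.trial_id,
                    window_start=t0,
                    valid_fraction=vf,
                    event_free=event_free,
                    features=feats,
                )
            )
    return rows
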