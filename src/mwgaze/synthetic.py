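"""Synthetic sessions: attention dynamics, binocular gaze, fade-out probes.

The generator emulates the study protocol — a seated viewer 1.8 m from a
projection wall, 120 Hz binocular eye tracking, short clips under explicit
attention instructions followed by long clips during which the audio fades
out at random 15–30 s intervals until a keypress — so the full pipeline can
be exercised end to end without human recordings.

Attention is a two-state semi-Markov process: focused dwells are
exponential with hazard ``mw_hazard``; mind-wandering (MW) dwells are
log-normal around ``mw_dwell_mean``.  Gaze is an alternating
fixation/saccade synthesis whose MW state multiplies fixation duration
(``duration_ratio``), divides fixation rate (``rate_ratio``), inflates
within-fixation jitter (``dispersion_ratio``) and shifts binocular
disparity (``disparity_shift_px``) — the oculomotor signatures reported for
MW (fewer, longer, more dispersed fixations).  The keypress latency to a
fade is a truncated normal draw around the calibrated 3.59 s mean when the
viewer is focused at fade onset, and the MW-episode remainder plus such a
draw otherwise.

What it does **not** emulate: head movement, saccade main-sequence realism
beyond amplitude/velocity consistency, audio itself, or any systematic
drift of tracker calibration over a session.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import DEFAULT_REACTION_TIME_S, FadeParams
from .gaze_io import (
    CriticalSentence,
    FadeEvent,
    GazeData,
    NOMINAL_RATE_HZ,
    QuizResponse,
    SessionEvents,
    Trial,
    ViewingGeometry,
    NOT_SURE,
)
from .oculomotor import deg_to_px


@dataclass(frozen=True)
class ParticipantProfile:
    """Generative parameters of one simulated participant.

    Rates are per second, durations in seconds unless suffixed ``_ms``.
    ``noise_precision_deg`` is the tracker's sample-to-sample RMS jitter in
    degrees (distinct from its accuracy, which acts as a per-fixation
    systematic offset).
    """

    participant: str = "p00"
    reaction_mean: float = DEFAULT_REACTION_TIME_S
    reaction_sd: float = 1.56
    mw_hazard: float = 1.0 / 30.0
    mw_dwell_mean: float = 15.0
    fix_duration_median_ms: float = 250.0
    fix_duration_sigma: float = 0.4
    fix_rate_hz: float = 3.0
    duration_ratio: float = 2.0
    rate_ratio: float = 0.5
    dispersion_ratio: float = 1.5
    disparity_shift_px: float = 6.0
    base_disparity_px: float = 8.0
    noise_precision_deg: float = 0.1
    saccade_amplitude_median_deg: float = 4.0
    dropout_rate_hz: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.reaction_mean, self.mw_dwell_mean, self.fix_duration_median_ms,
            self.fix_rate_hz, self.duration_ratio, self.rate_ratio,
            self.dispersion_ratio,
        ) <= 0 or self.mw_hazard < 0:
            raise ValueError("profile rates, durations and ratios must be positive")


@dataclass(frozen=True)
class ProtocolConfig:
    """Session protocol: trial counts/lengths and fade scheduling.

    Defaults mirror the study session: eight ~30 s short clips under
    explicit attention instructions, four ~600 s long clips with volume
    fades scheduled at uniform 15–30 s gaps at the fast speed.
    """

    n_focused_trials: int = 8
    n_mw_trials: int = 4
    short_clip_s: float = 30.0
    long_clip_s: float = 600.0
    fade_interval: tuple[float, float] = (15.0, 30.0)
    fade_params: FadeParams = field(default_factory=FadeParams)
    rate_hz: float = NOMINAL_RATE_HZ
    critical_sentence_s: float = 12.0
    inter_trial_gap_s: float = 2.0

    def __post_init__(self) -> None:
        lo, hi = self.fade_interval
        if not (0 < lo < hi):
            raise ValueError("fade interval must satisfy 0 < low < high")
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")


FOCUSED, MW = "focused", "mw"

# reaction-latency truncation bounds (s): keeps draws physiologically plausible
REACTION_BOUNDS = (0.5, 15.0)


@dataclass
class GroundTruth:
    """Per-trial attention track: episodes and a per-second label array."""

    trial_id: str
    start: float
    end: float
    episodes: list[tuple[str, float, float]]  # (state, start, end)
    seconds: np.ndarray  # one label per whole second, anchored at trial start

    def state_at(self, t: float) -> str:
        for state, s, e in self.episodes:
            if s <= t < e:
                return state
        return self.episodes[-1][0] if self.episodes else FOCUSED

    def episode_end(self, t: float) -> float:
        for _, s, e in self.episodes:
            if s <= t < e:
                return e
        return self.end

    def mw_fraction(self, t0: float, t1: float) -> float:
        total = max(t1 - t0, 1e-12)
        mw = sum(
            max(0.0, min(e, t1) - max(s, t0))
            for state, s, e in self.episodes
            if state == MW
        )
        return mw / total


def _truncated_normal(rng, mean, sd, lo, hi) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def simulate_attention(
    profile: ParticipantProfile,
    trial_id: str,
    start: float,
    length: float,
    rng: np.random.Generator,
) -> GroundTruth:
    """Alternating focused/MW episodes over ``[start, start + length)``.

    Focused dwells ~ Exponential(1 / mw_hazard); MW dwells ~ LogNormal with
    mean ``mw_dwell_mean`` (log-sd 0.6).  ``mw_hazard = 0`` gives an
    all-focused track.
    """
    end = start + length
    episodes: list[tuple[str, float, float]] = []
    t, state = start, FOCUSED
    sigma = 0.6
    mu = np.log(profile.mw_dwell_mean) - sigma**2 / 2.0
    while t < end:
        if state == FOCUSED:
            dwell = (
                np.inf if profile.mw_hazard == 0
                else rng.exponential(1.0 / profile.mw_hazard)
            )
        else:
            dwell = rng.lognormal(mu, sigma)
        e = min(t + dwell, end)
        episodes.append((state, t, e))
        t, state = e, (MW if state == FOCUSED else FOCUSED)
    n_sec = int(np.floor(length))
    truth = GroundTruth(trial_id, start, end, episodes, np.empty(n_sec, dtype=object))
    for k in range(n_sec):
        truth.seconds[k] = truth.state_at(start + k + 0.5)
    return truth


def _mw_gap_mean_ms(profile: ParticipantProfile) -> float:
    """Inter-fixation gap mean (ms) in MW so the fixation rate hits
    ``fix_rate_hz * rate_ratio`` given the inflated durations."""
    dur_f = profile.fix_duration_median_ms * np.exp(profile.fix_duration_sigma**2 / 2)
    cycle_f = 1000.0 / profile.fix_rate_hz
    gap_f = max(cycle_f - dur_f, 16.0)
    cycle_mw = (dur_f + gap_f) / profile.rate_ratio
    return max(cycle_mw - dur_f * profile.duration_ratio, 16.0), gap_f


def simulate_gaze(
    truth: GroundTruth,
    profile: ParticipantProfile,
    geometry: ViewingGeometry,
    rate_hz: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Binocular 120 Hz gaze over one trial as a gaze-log data frame.

    Alternates fixations (log-normal durations, Gaussian within-fixation
    jitter) and saccadic transitions (linear interpolation between fixation
    targets).  The MW multipliers of ``profile`` act on every cycle whose
    fixation starts inside an MW episode.  Tracker accuracy enters as a
    per-fixation systematic offset; ``noise_precision_deg`` as per-sample
    jitter.  Track loss appears as Poisson bursts of invalid samples.
    """
    wall_w = 5.0 * geometry.pixels_per_metre
    wall_h = 3.0 * geometry.pixels_per_metre
    jitter_sd = deg_to_px(profile.noise_precision_deg, geometry) / 2.0
    offset_sd = deg_to_px(geometry.tracker_accuracy_deg, geometry) / 2.0
    amp_med_px = deg_to_px(profile.saccade_amplitude_median_deg, geometry)
    gap_mw_ms, gap_f_ms = _mw_gap_mean_ms(profile)

    period = 1.0 / rate_hz
    n0 = int(np.ceil(truth.start / period - 1e-9))
    n1 = int(np.floor(truth.end / period + 1e-9))
    tgrid = np.arange(n0, n1 + 1) * period
    tgrid = tgrid[(tgrid >= truth.start) & (tgrid < truth.end)]
    cx = np.empty_like(tgrid)
    cy = np.empty_like(tgrid)
    disparity = np.empty_like(tgrid)

    centre = np.array([wall_w / 2, wall_h / 2]) + rng.normal(0, 100.0, 2)
    t = truth.start
    i = 0  # cursor into tgrid
    mu_dur = np.log(profile.fix_duration_median_ms / 1000.0)
    while t < truth.end and i < len(tgrid):
        mw = truth.state_at(t) == MW
        dur = rng.lognormal(mu_dur, profile.fix_duration_sigma)
        if mw:
            dur *= profile.duration_ratio
        sd = jitter_sd * (profile.dispersion_ratio if mw else 1.0)
        disp = profile.base_disparity_px + (profile.disparity_shift_px if mw else 0.0)
        offset = rng.normal(0.0, offset_sd, 2)
        fix_end = min(t + dur, truth.end)
        j = i + int(np.searchsorted(tgrid[i:], fix_end))
        k = j - i
        if k > 0:
            cx[i:j] = centre[0] + offset[0] + rng.normal(0, sd, k)
            cy[i:j] = centre[1] + offset[1] + rng.normal(0, sd, k)
            disparity[i:j] = np.maximum(disp + rng.normal(0, 1.0, k), 0.0)
        i = j
        # saccadic transition to a new target
        gap_mean = gap_mw_ms if mw else gap_f_ms
        gap = rng.lognormal(np.log(gap_mean / 1000.0) - 0.3**2 / 2, 0.3)
        amp = amp_med_px * rng.lognormal(0.0, 0.5)
        theta = rng.uniform(0, 2 * np.pi)
        target = centre + amp * np.array([np.cos(theta), np.sin(theta)])
        margin = 0.05
        target[0] = np.clip(target[0], margin * wall_w, (1 - margin) * wall_w)
        target[1] = np.clip(target[1], margin * wall_h, (1 - margin) * wall_h)
        sac_end = min(fix_end + gap, truth.end)
        j = i + int(np.searchsorted(tgrid[i:], sac_end))
        k = j - i
        if k > 0:
            frac = (tgrid[i:j] - fix_end) / max(gap, 1e-9)
            cx[i:j] = centre[0] + frac * (target[0] - centre[0]) + rng.normal(0, sd, k)
            cy[i:j] = centre[1] + frac * (target[1] - centre[1]) + rng.normal(0, sd, k)
            disparity[i:j] = np.maximum(disp + rng.normal(0, 1.0, k), 0.0)
        i = j
        centre = target
        t = sac_end

    valid = np.ones(len(tgrid), dtype=bool)
    n_bursts = rng.poisson(profile.dropout_rate_hz * (truth.end - truth.start))
    for _ in range(n_bursts):
        b0 = rng.uniform(truth.start, truth.end)
        b1 = b0 + rng.uniform(0.05, 0.15)
        valid &= ~((tgrid >= b0) & (tgrid < b1))

    half = disparity / 2.0
    df = pd.DataFrame(
        {
            "t": tgrid,
            "lx": cx - half, "ly": cy,
            "rx": cx + half, "ry": cy,
            "cx": cx, "cy": cy,
            "valid": valid.astype(int),
        }
    )
    df.loc[~valid, ["lx", "ly", "rx", "ry", "cx", "cy"]] = np.nan
    return df


QUIZ_OPTIONS = ("a", "b", "c", "d")


def simulate_session(
    profile: ParticipantProfile,
    protocol: ProtocolConfig | None = None,
    geometry: ViewingGeometry | None = None,
    seed: int | None = None,
) -> tuple[GazeData, SessionEvents, dict[str, GroundTruth]]:
    """One full session: gaze log, event log, and the attention ground truth.

    Short focused trials come first, then the long MW trials.  Fade onsets
    follow each other at U(fade_interval)-second gaps (pushed past any
    still-pending keypress); the keypress
    latency is a truncated-normal reaction draw when focused at onset and
    the MW-episode remainder plus such a draw otherwise.  Each long trial
    ends with a critical sentence span and a quiz response whose
    correctness probability decreases with the true MW fraction inside that
    span.  Reproducible: one seed fans out to per-trial streams via
    ``numpy.random.SeedSequence.spawn``.
    """
    protocol = protocol or ProtocolConfig()
    geometry = geometry or ViewingGeometry()
    root = np.random.SeedSequence(
        profile.seed if seed is None else seed
    )
    n_trials = protocol.n_focused_trials + protocol.n_mw_trials
    streams = [np.random.Generator(np.random.PCG64(s)) for s in root.spawn(n_trials + 1)]
    quiz_rng = streams[-1]

    trials: list[Trial] = []
    fades: list[FadeEvent] = []
    sentences: list[CriticalSentence] = []
    quiz: list[QuizResponse] = []
    truths: dict[str, GroundTruth] = {}
    frames: list[pd.DataFrame] = []

    t0 = 0.0
    for idx in range(n_trials):
        rng = streams[idx]
        is_mw = idx >= protocol.n_focused_trials
        kind = "mw_long" if is_mw else "focused_short"
        length = protocol.long_clip_s if is_mw else protocol.short_clip_s
        trial_id = f"t{idx:02d}"
        trials.append(Trial(trial_id, kind, t0, t0 + length))
        if is_mw:
            truth = simulate_attention(profile, trial_id, t0, length, rng)
        else:
            truth = GroundTruth(
                trial_id, t0, t0 + length,
                [(FOCUSED, t0, t0 + length)],
                np.array([FOCUSED] * int(np.floor(length)), dtype=object),
            )
        truths[trial_id] = truth
        frames.append(simulate_gaze(truth, profile, geometry, protocol.rate_hz, rng))

        if is_mw:
            lo, hi = protocol.fade_interval
            t = t0 + rng.uniform(lo, hi)
            while True:
                if truth.state_at(t) == FOCUSED:
                    latency = _truncated_normal(
                        rng, profile.reaction_mean, profile.reaction_sd,
                        *REACTION_BOUNDS,
                    )
                else:
                    latency = (truth.episode_end(t) - t) + _truncated_normal(
                        rng, profile.reaction_mean, profile.reaction_sd,
                        *REACTION_BOUNDS,
                    )
                keypress = t + latency
                if keypress > t0 + length - 0.5:
                    break
                fades.append(FadeEvent(trial_id, t, keypress))
                # fade onsets follow each other at U(lo, hi) gaps; a long MW
                # episode can delay the next onset past the keypress
                t = max(t + rng.uniform(lo, hi), keypress + 2.0)
                if t >= t0 + length - 1.0:
                    break
            cs_start = t0 + length - protocol.critical_sentence_s
            clip_id = f"{trial_id}_clip"
            sentences.append(
                CriticalSentence(trial_id, clip_id, cs_start, t0 + length)
            )
            frac = truth.mw_fraction(cs_start, t0 + length)
            p_correct = float(np.clip(0.92 - 0.75 * frac, 0.05, 0.95))
            correct_opt = QUIZ_OPTIONS[quiz_rng.integers(4)]
            if quiz_rng.random() < p_correct:
                chosen = correct_opt
            else:
                others = [o for o in QUIZ_OPTIONS if o != correct_opt] + [NOT_SURE]
                chosen = others[quiz_rng.integers(len(others))]
            quiz.append(QuizResponse(clip_id, chosen, correct_opt))
        t0 += length + protocol.inter_trial_gap_s

    gaze_df = pd.concat(frames, ignore_index=True)
    gaze = GazeData(
        gaze_df["t"], gaze_df["lx"], gaze_df["ly"], gaze_df["rx"], gaze_df["ry"],
        gaze_df["cx"], gaze_df["cy"], gaze_df["valid"].astype(bool),
    )
    events = SessionEvents(trials, fades, sentences, quiz).validate()
    return gaze, events, truths


def cohort_profiles(
    n_participants: int,
    seed: int,
    base: ParticipantProfile | None = None,
    heterogeneity: float = 0.15,
) -> list[ParticipantProfile]:
    """Participant profiles with mild between-participant heterogeneity.

    Each multiplicative parameter is jittered by a log-normal factor with
    log-sd ``heterogeneity``; seeds fan out from ``seed``.
    """
    base = base or ParticipantProfile()
    root = np.random.SeedSequence(seed)
    profiles = []
    for i, ss in enumerate(root.spawn(n_participants)):
        rng = np.random.Generator(np.random.PCG64(ss))
        jit = lambda v: float(v * rng.lognormal(0.0, heterogeneity))  # noqa: E731
        profiles.append(
            replace(
                base,
                participant=f"p{i:02d}",
                reaction_mean=jit(base.reaction_mean),
                mw_hazard=jit(base.mw_hazard),
                mw_dwell_mean=jit(base.mw_dwell_mean),
                fix_duration_median_ms=jit(base.fix_duration_median_ms),
                fix_rate_hz=jit(base.fix_rate_hz),
                seed=int(rng.integers(2**31 - 1)),
            )
        )
    return profiles


def simulate_quiz_outcomes(
    n_participants: int = 31,
    n_obs_per_participant: int = 13,
    effect: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Study-2-style outcome table for validating the correlation statistics.

    Each participant contributes quiz instances with a per-participant MW
    baseline; within a participant, the probability of answering
    incorrectly increases with the instance's MW percentage at strength
    ``effect``.  Perceived difficulty is a noisy companion of
    incorrectness.  Columns: participant, clip_id, percent_mw, correct,
    perceived_difficulty.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    rows = []
    for i in range(n_participants):
        baseline = rng.normal(35.0, 12.0)
        for j in range(n_obs_per_participant):
            pct = float(np.clip(baseline + rng.uniform(-25.0, 25.0), 0.0, 100.0))
            z = effect * (pct - baseline) / 10.0 - 0.2
            p_incorrect = 1.0 / (1.0 + np.exp(-z))
            correct = int(rng.random() >= p_incorrect)
            difficulty = float(
                np.clip(round((1 - correct) * 2.5 + rng.normal(0, 2.0)), -5, 5)
            )
            rows.append(
                {
                    "participant": f"p{i:02d}",
                    "clip_id": f"c{j:02d}",
                    "percent_mw": pct,
                    "correct": correct,
                    "perceived_difficulty": difficulty,
                }
            )
    return pd.DataFrame(rows)
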