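"""Oculomotor event detection: I-DT fixations, saccades, angle conversion, MEC.

Fixations are detected with the dispersion-threshold (I-DT) algorithm on the
combined gaze signal: a temporal window grows while its spatial dispersion

    D = (max x - min x) + (max y - min y)

stays at or below the pixel equivalent of the angular threshold; a maximal
window spanning at least the minimum duration is emitted as a fixation.
Invalid samples are skipped; a gap between consecutive valid samples longer
than ``gap_tolerance_ms`` terminates the current window (blinks and track
loss are indistinguishable in this signal, so a bridging tolerance is
required).

Saccades are derived from consecutive fixation pairs whose inter-fixation gap
does not exceed ``max_gap_ms``; longer gaps are treated as track loss.

The detector is written as an incremental state machine (:class:`IDTState`)
so that the streaming classifier replays exactly the decisions the batch
path makes; :func:`detect_fixations` simply feeds a whole recording through
it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely import MultiPoint, minimum_bounding_radius

from .gaze_io import ConfigError, GazeData, ViewingGeometry


@dataclass(frozen=True)
class Fixation:
    """A detected fixation. Times in seconds, duration in ms, geometry in px."""

    start: float
    end: float
    duration: float  # ms
    centroid: tuple[float, float]
    sample_count: int
    mec_radius: float

    def overlaps(self, t0: float, t1: float) -> bool:
        return self.start < t1 and self.end > t0


@dataclass(frozen=True)
class Saccade:
    """A saccade between two consecutive fixations.

    ``length`` is the Euclidean distance between the bounding fixation
    centroids (px), ``amplitude`` its visual angle (deg), ``velocity`` the
    mean angular velocity amplitude/duration (deg/s).
    """

    start: float
    end: float
    duration: float  # ms
    length: float  # px
    amplitude: float  # deg
    velocity: float  # deg/s

    def overlaps(self, t0: float, t1: float) -> bool:
        return self.start < t1 and self.end > t0


def deg_to_px(angle_deg: float, geometry: ViewingGeometry) -> float:
    """Visual angle to on-wall chord length in pixels (exact, not small-angle).

    px = pixels_per_metre * 2 * viewer_distance * tan(angle/2)
    """
    if geometry is None:
        raise ConfigError("viewing geometry is required")
    a = np.asarray(angle_deg, dtype=float)
    if np.any(a < 0):
        raise ValueError("angle must be non-negative")
    out = geometry.pixels_per_metre * 2.0 * geometry.viewer_distance * np.tan(
        np.deg2rad(a) / 2.0
    )
    return out if out.ndim else float(out)


def px_to_deg(px: float, geometry: ViewingGeometry) -> float:
    """Inverse of :func:`deg_to_px` (exact round-trip)."""
    if geometry is None:
        raise ConfigError("viewing geometry is required")
    p = np.asarray(px, dtype=float)
    out = np.rad2deg(
        2.0 * np.arctan(p / (2.0 * geometry.viewer_distance * geometry.pixels_per_metre))
    )
    return out if out.ndim else float(out)


def minimal_enclosing_circle(points) -> tuple[tuple[float, float], float]:
    """Smallest circle containing all points: ``((cx, cy), radius)`` in px.

    Exact minimum bounding circle; the result is independent of point order.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("minimal_enclosing_circle requires at least one point")
    pts = pts.reshape(-1, 2)
    if len(pts) == 1:
        return (float(pts[0, 0]), float(pts[0, 1])), 0.0
    geom = MultiPoint(pts)
    radius = float(minimum_bounding_radius(geom))
    if radius == 0.0:
        return (float(pts[0, 0]), float(pts[0, 1])), 0.0
    # centre: the point equidistant (= radius) from the support set; recover
    # it from the bounding circle polygon's centroid
    from shapely import minimum_bounding_circle as _mbc

    centre = _mbc(geom).centroid
    return (float(centre.x), float(centre.y)), radius


class IDTState:
    """Incremental greedy I-DT over a stream of (t, x, y, valid) samples.

    Decisions are identical to running the batch greedy algorithm over the
    full recording: the window start pointer only advances once the maximal
    window from it is decided, so feeding samples one at a time or all at
    once yields the same segmentation.

    Attributes
    ----------
    fixations : list[Fixation]
        Closed fixations, final and immutable.
    open_start_t : float or None
        Start time of the still-growing candidate window (events before it
        are final).
    """

    def __init__(
        self,
        dispersion_deg: float,
        min_duration_ms: float,
        geometry: ViewingGeometry,
        gap_tolerance_ms: float = 75.0,
    ):
        if geometry is None:
            raise ConfigError("viewing geometry is required")
        self._thr_px = deg_to_px(dispersion_deg, geometry)
        self._min_dur_s = min_duration_ms / 1000.0
        self._gap_s = gap_tolerance_ms / 1000.0
        # buffered valid samples (lists for O(1) append)
        self._t: list[float] = []
        self._x: list[float] = []
        self._y: list[float] = []
        self._s = 0  # window start index into the buffers
        self._e = 0  # next index to absorb
        self._minx = self._maxx = self._miny = self._maxy = 0.0
        self.fixations: list[Fixation] = []

    @property
    def open_start_t(self) -> float | None:
        if self._s < len(self._t) and self._s < self._e:
            return self._t[self._s]
        return None

    def feed(self, t: float, x: float, y: float, valid: bool) -> list[Fixation]:
        """Absorb one sample; return fixations that just closed."""
        if not valid:
            return []
        self._t.append(float(t))
        self._x.append(float(x))
        self._y.append(float(y))
        return self._advance(final=False)

    def finish(self) -> list[Fixation]:
        """Flush: decide every remaining window. Returns newly closed fixations."""
        return self._advance(final=True)

    # -- internals ----------------------------------------------------------

    def _dispersion_with(self, x: float, y: float) -> float:
        return (
            max(self._maxx, x) - min(self._minx, x)
            + max(self._maxy, y) - min(self._miny, y)
        )

    def _reset_window(self) -> None:
        """Recompute running extrema for the (possibly shrunk) window [s, e)."""
        if self._s < self._e:
            xs = self._x[self._s:self._e]
            ys = self._y[self._s:self._e]
            self._minx, self._maxx = min(xs), max(xs)
            self._miny, self._maxy = min(ys), max(ys)

    def _advance(self, final: bool) -> list[Fixation]:
        t, x, y = self._t, self._x, self._y
        closed: list[Fixation] = []
        while True:
            if self._s >= len(t):
                break
            if self._e <= self._s:  # (re)start window at s
                self._e = self._s + 1
                self._minx = self._maxx = x[self._s]
                self._miny = self._maxy = y[self._s]
            # grow while the next sample fits (dispersion and gap rules)
            while (
                self._e < len(t)
                and t[self._e] - t[self._e - 1] <= self._gap_s
                and self._dispersion_with(x[self._e], y[self._e]) <= self._thr_px
            ):
                self._minx = min(self._minx, x[self._e])
                self._maxx = max(self._maxx, x[self._e])
                self._miny = min(self._miny, y[self._e])
                self._maxy = max(self._maxy, y[self._e])
                self._e += 1
            if self._e >= len(t) and not final:
                return closed  # window still open: wait for more samples
            # maximal window [s, e) decided
            if t[self._e - 1] - t[self._s] >= self._min_dur_s:
                closed.append(self._emit(self._s, self._e))
                self._s = self._e
            else:
                self._s += 1
                self._e = max(self._e, self._s)
                self._reset_window()
        return closed

    def _emit(self, s: int, e: int) -> Fixation:
        xs = np.array(self._x[s:e])
        ys = np.array(self._y[s:e])
        _, radius = minimal_enclosing_circle(np.column_stack([xs, ys]))
        return Fixation(
            start=self._t[s],
            end=self._t[e - 1],
            duration=(self._t[e - 1] - self._t[s]) * 1000.0,
            centroid=(float(xs.mean()), float(ys.mean())),
            sample_count=e - s,
            mec_radius=radius,
        )


def detect_fixations(
    samples: GazeData,
    dispersion_deg: float = 1.0,
    min_duration_ms: float = 100.0,
    geometry: ViewingGeometry | None = None,
    gap_tolerance_ms: float = 75.0,
) -> list[Fixation]:
    """Detect fixations in a recording with I-DT (see module docstring)."""
    state = IDTState(dispersion_deg, min_duration_ms, geometry, gap_tolerance_ms)
    out: list[Fixation] = []
    mask = samples.valid
    for t, x, y in zip(samples.t[mask], samples.cx[mask], samples.cy[mask]):
        out.extend(state.feed(t, x, y, True))
    out.extend(state.finish())
    return out


def derive_saccades(
    fixations: list[Fixation],
    geometry: ViewingGeometry,
    max_gap_ms: float = 200.0,
) -> list[Saccade]:
    """One saccade per consecutive fixation pair with gap <= ``max_gap_ms``."""
    sacc: list[Saccade] = []
    for a, b in zip(fixations, fixations[1:]):
        gap_s = b.start - a.end
        if gap_s <= 0 or gap_s * 1000.0 > max_gap_ms:
            continue
        length = math.dist(a.centroid, b.centroid)
        amplitude = px_to_deg(length, geometry)
        sacc.append(
            Saccade(
                start=a.end,
                end=b.start,
                duration=gap_s * 1000.0,
                length=length,
                amplitude=amplitude,
                velocity=amplitude / gap_s,
            )
        )
    return sacc
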