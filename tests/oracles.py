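"""Independent reference implementations used only as test oracles.

These deliberately favour clarity and exhaustiveness over speed and share
no code with the package: brute-force I-DT that re-measures every candidate
window from scratch, combinatorial minimal-enclosing-circle search over all
pair- and triple-defined circles, and textbook moment formulas.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_idt(t, x, y, thr_px, min_dur_s, gap_s):
    """Greedy dispersion-threshold segmentation, recomputed from scratch.

    Returns (start_index, end_index_exclusive) windows over the given valid
    samples.  For every candidate start, every candidate extension is
    re-measured with a full max/min pass.
    """
    t, x, y = np.asarray(t), np.asarray(x), np.asarray(y)
    n = len(t)
    windows = []
    s = 0
    while s < n:
        e = s + 1
        while e < n:
            if t[e] - t[e - 1] > gap_s:
                break
            xs, ys = x[s:e + 1], y[s:e + 1]
            if (xs.max() - xs.min()) + (ys.max() - ys.min()) > thr_px:
                break
            e += 1
        if t[e - 1] - t[s] >= min_dur_s:
            windows.append((s, e))
            s = e
        else:
            s += 1
    return windows


def _circle_from_two(a, b):
    centre = ((a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0)
    return centre, math.dist(a, b) / 2.0


def _circle_from_three(a, b, c):
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-14:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    centre = (ux, uy)
    return centre, math.dist(centre, a)

def brute_force_mec_radius(points, tol=1e-9):
    """Smallest enclosing circle radius by checking every pair/triple circle."""
    pts = [tuple(map(float, p)) for p in np.asarray(points, float).reshape(-1, 2)]
    if len(pts) == 1:
        return 0.0
    best = math.inf
    candidates = []
    for a, b in itertools.combinations(pts, 2):
        candidates.append(_circle_from_two(a, b))
    for a, b, c in itertools.combinations(pts, 3):
        circ = _circle_from_three(a, b, c)
        if circ is not None:
            candidates.append(circ)
    for centre, radius in candidates:
        if radius >= best:
            continue
        if all(math.dist(centre, p) <= radius + tol for p in pts):
            best = radius
    return best


def textbook_seven(values):
    """Mean/min/max/median, sample SD, moment skewness g1, excess kurtosis g2."""
    v = [float(u) for u in values]
    n = len(v)
    mean = sum(v) / n
    m2 = sum((u - mean) ** 2 for u in v) / n
    m3 = sum((u - mean) ** 3 for u in v) / n
    m4 = sum((u - mean) ** 4 for u in v) / n
    sd = math.sqrt(sum((u - mean) ** 2 for u in v) / (n - 1)) if n >= 2 else 0.0
    skew = m3 / m2**1.5 if n >= 3 and m2**1.5 > 0 else 0.0
    kurt = m4 / m2**2 - 3.0 if n >= 4 and m2**2 > 0 else 0.0
    srt = sorted(v)
    median = (srt[(n - 1) // 2] + srt[n // 2]) / 2.0
    return [mean, min(v), max(v), median, sd, skew, kurt]


def pair_counting_auc(scores, labels):
    """Mann–Whitney AUC by exhaustive pair counting (ties count half)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def ancova_rmcorr(x, y, subjects):
    """Repeated-measures correlation via explicit dummy-coded ANCOVA.

    Builds the design matrix [intercept | subject dummies | x], solves by
    least squares, and derives r from the covariate and error sums of
    squares of the sequential decomposition.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    subjects = np.asarray(subjects)
    uniq = list(dict.fromkeys(subjects))
    k = len(uniq)
    n = len(x)
    dummies = np.column_stack([(subjects == u).astype(float) for u in uniq[1:]])
    base = np.column_stack([np.ones(n), dummies])
    full = np.column_stack([base, x])
    rss = lambda design: float(
        np.sum((y - design @ np.linalg.lstsq(design, y, rcond=None)[0]) ** 2)
    )
    ss_err = rss(full)
    ss_cov = rss(base) - ss_err
    slope = np.linalg.lstsq(full, y, rcond=None)[0][-1]
    r = math.copysign(math.sqrt(ss_cov / (ss_cov + ss_err)), slope)
    return r, n - k - 1
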