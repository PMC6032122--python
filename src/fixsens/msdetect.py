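"""Velocity-threshold microsaccade detection (Engbert-Kliegl style).

Per eye and velocity component, a robust noise scale is estimated with
the median-based standard deviation

    sigma = sqrt( median(v^2) - median(v)^2 )

over all valid samples, and a sample is supra-threshold when it exceeds
the elliptic criterion ``(vx/eta_x)^2 + (vy/eta_y)^2 > 1`` with
``eta = multiplier * sigma`` (default multiplier 6).  Maximal
supra-threshold runs are candidate saccades; same-eye candidates with an
offset-to-onset gap below 50 ms are merged (fusing overshoots), events
shorter than 6 ms or with net onset-to-offset displacement outside
3-60 arcmin are discarded, and surviving events must overlap in time
across both eyes.  The left eye's parameters are reported for binocular
events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import compute_velocity, mask_blinks
from .trace import ARCMIN_PER_DEG, GazeTrace, Microsaccade, VelocityTrace

__all__ = [
    "Candidate", "median_sd", "detect_candidates", "filter_and_merge",
    "binocular_filter", "detect_microsaccades", "main_sequence",
    "direction_histogram",
]

EYE_NAMES = ("left", "right")


@dataclass
class Candidate:
    """A supra-threshold run in one eye (sample index bounds inclusive)."""

    eye: int
    i0: int
    i1: int
    onset: float
    offset: float


def median_sd(v: np.ndarray) -> float:
    """Median-based standard deviation over finite samples."""
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no valid samples")
    var = float(np.median(v ** 2) - np.median(v) ** 2)
    return float(np.sqrt(max(var, 0.0)))


def detect_candidates(vel: VelocityTrace, multiplier: float = 6.0):
    """Per-eye candidate lists from the elliptic velocity criterion."""
    out = ([], [])
    for eye in (0, 1):
        ok = vel.valid[:, eye]
        if not ok.any():
            continue
        sx = median_sd(vel.vx[ok, eye])
        sy = median_sd(vel.vy[ok, eye])
        if sx == 0.0 or sy == 0.0:
            raise ValueError("degenerate (flat) trace: zero velocity noise scale")
        eta_x = multiplier * sx
        eta_y = multiplier * sy
        crit = np.zeros(vel.time.size, dtype=bool)
        crit[ok] = ((vel.vx[ok, eye] / eta_x) ** 2
                    + (vel.vy[ok, eye] / eta_y) ** 2) > 1.0
        edges = np.diff(crit.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1)
        if crit[0]:
            starts = np.concatenate([[0], starts])
        if crit[-1]:
            ends = np.concatenate([ends, [crit.size - 1]])
        for i0, i1 in zip(starts, ends):
            out[eye].append(Candidate(eye=eye, i0=int(i0), i1=int(i1),
                                      onset=float(vel.time[i0]),
                                      offset=float(vel.time[i1])))
    return out


def _event_from_run(trace: GazeTrace, vel: VelocityTrace, eye: int,
                    i0: int, i1: int) -> Microsaccade:
    dx = trace.x[i1, eye] - trace.x[i0, eye]
    dy = trace.y[i1, eye] - trace.y[i0, eye]
    amp = float(np.hypot(dx, dy)) * ARCMIN_PER_DEG
    pv = float(np.nanmax(vel.radial[i0:i1 + 1, eye]))
    direction = float(np.degrees(np.arctan2(dy, dx)) % 360.0)
    return Microsaccade(onset=float(trace.time[i0]), offset=float(trace.time[i1]),
                        amplitude=amp, peak_velocity=pv, direction=direction,
                        eye=EYE_NAMES[eye])


def filter_and_merge(candidates, trace: GazeTrace, vel: VelocityTrace,
                     merge_gap: float = 0.05, min_duration: float = 0.006,
                     amplitude_bounds=(3.0, 60.0)):
    """Merge same-eye candidates closer than ``merge_gap`` (offset to
    onset, transitively), then apply the duration and amplitude filters.
    Event parameters are recomputed on the merged runs."""
    events = []
    cands = sorted(candidates, key=lambda c: c.i0)
    if not cands:
        return events
    runs = [[cands[0].i0, cands[0].i1, cands[0].eye]]
    for c in cands[1:]:
        if c.onset - trace.time[runs[-1][1]] < merge_gap and c.eye == runs[-1][2]:
            runs[-1][1] = max(runs[-1][1], c.i1)
        else:
            runs.append([c.i0, c.i1, c.eye])
    lo, hi = amplitude_bounds
    for i0, i1, eye in runs:
        ev = _event_from_run(trace, vel, eye, i0, i1)
        if ev.duration < min_duration:
            continue
        if not (lo <= ev.amplitude <= hi):
            continue
        events.append(ev)
    return events


def binocular_filter(left, right):
    """Retain left-eye events whose [onset, offset] interval intersects
    any right-eye event (any overlap suffices); left-eye parameters are
    reported."""
    out = []
    for ev in left:
        for other in right:
            if ev.onset <= other.offset and other.onset <= ev.offset:
                out.append(Microsaccade(
                    onset=ev.onset, offset=ev.offset, amplitude=ev.amplitude,
                    peak_velocity=ev.peak_velocity, direction=ev.direction,
                    eye="binocular"))
                break
    return out


def detect_microsaccades(trace: GazeTrace, multiplier: float = 6.0,
                         merge_gap: float = 0.05, min_duration: float = 0.006,
                         amplitude_bounds=(3.0, 60.0), blink_buffer: float = 0.2):
    """Full detection chain: blink masking, velocity computation,
    elliptic thresholding per eye, merge + filters, binocular overlap."""
    masked = mask_blinks(trace, buffer=blink_buffer)
    vel = compute_velocity(masked)
    cand_l, cand_r = detect_candidates(vel, multiplier=multiplier)
    left = filter_and_merge(cand_l, masked, vel, merge_gap, min_duration,
                            amplitude_bounds)
    right = filter_and_merge(cand_r, masked, vel, merge_gap, min_duration,
                             amplitude_bounds)
    return binocular_filter(left, right)


def main_sequence(events):
    """Pearson correlation and slope of log10 peak velocity vs log10
    amplitude over detected events (the main-sequence power law)."""
    if len(events) < 3:
        raise ValueError("need at least 3 events for a main-sequence fit")
    from scipy import stats

    la = np.log10([e.amplitude / ARCMIN_PER_DEG for e in events])
    lv = np.log10([e.peak_velocity for e in events])
    r = float(stats.pearsonr(la, lv).statistic)
    slope = float(np.polyfit(la, lv, 1)[0])
    return r, slope


def direction_histogram(events, n_bins: int = 8):
    """Angular histogram of event directions as proportions (sum to 1).
    Bins are centered on 0, 360/n, ... so bin 0 captures rightward."""
    if len(events) == 0:
        raise ValueError("no events")
    width = 360.0 / n_bins
    d = np.array([e.direction for e in events])
    idx = np.floor(((d + width / 2) % 360.0) / width).astype(int)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    centers = width * np.arange(n_bins)
    return centers, counts / counts.sum()
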