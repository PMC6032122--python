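"""Gaze-trace cleaning and trial/microsaccade latency bookkeeping.

Blink samples (pupil = 0) are invalidated together with a 200-ms buffer
on either side; no interpolation is performed.  Velocities come from the
5-sample moving-window differentiator used by velocity-threshold
microsaccade detection,

    v_n = (p_{n+2} + p_{n+1} - p_{n-1} - p_{n-2}) / (6 * dt),

which is exact for linear position signals; velocities are undefined
(invalid) wherever the window spans an invalid sample, rather than
falling back to shortened windows.  Radial velocity additionally gets a
5-point moving average for the drift analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trace import GazeTrace, VelocityTrace

__all__ = [
    "mask_blinks", "blink_intervals", "compute_velocity",
    "attach_latency", "exclude_blink_trials",
]


def blink_intervals(trace: GazeTrace, buffer: float = 0.2) -> np.ndarray:
    """Merged [start, end] time intervals covering pupil==0 samples of
    either eye plus ``buffer`` seconds each side; shape (k, 2)."""
    blink = np.any(trace.pupil == 0, axis=1)
    if not blink.any():
        return np.empty((0, 2))
    idx = np.flatnonzero(blink)
    t = trace.time
    starts = t[idx] - buffer
    ends = t[idx] + buffer
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged)


def mask_blinks(trace: GazeTrace, buffer: float = 0.2) -> GazeTrace:
    """Invalidate pupil==0 samples and everything within ``buffer`` s of
    them (both eyes jointly: a blink compromises the binocular record).
    Idempotent; returns a copy."""
    out = trace.copy()
    intervals = blink_intervals(trace, buffer)
    if intervals.size == 0:
        return out
    for s, e in intervals:
        m = (out.time >= s) & (out.time <= e)
        out.valid[m, :] = False
    if not out.valid.any():
        import warnings
        warnings.warn("trace entirely invalid after blink masking")
    return out


def _window_diff(p: np.ndarray, valid: np.ndarray, dt: float):
    """5-sample differentiator with validity propagation (1-D)."""
    n = p.size
    v = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    if n < 5:
        return v, ok
    pz = np.where(valid, p, 0.0)
    num = pz[4:] + pz[3:-1] - pz[1:-3] - pz[:-4]
    v[2:-2] = num / (6.0 * dt)
    w = (valid[4:] & valid[3:-1] & valid[2:-2] & valid[1:-3] & valid[:-4])
    ok[2:-2] = w
    v[~ok] = np.nan
    return v, ok


def _smooth5(v: np.ndarray, ok: np.ndarray):
    """5-point moving average, valid only where the whole window is valid."""
    n = v.size
    out = np.full(n, np.nan)
    good = np.zeros(n, dtype=bool)
    if n < 5:
        return out, good
    vz = np.where(ok, v, 0.0)
    s = vz[4:] + vz[3:-1] + vz[2:-2] + vz[1:-3] + vz[:-4]
    w = ok[4:] & ok[3:-1] & ok[2:-2] & ok[1:-3] & ok[:-4]
    out[2:-2] = s / 5.0
    good[2:-2] = w
    out[~good] = np.nan
    return out, good


def compute_velocity(trace: GazeTrace) -> VelocityTrace:
    """Per-eye component, radial, and smoothed radial velocities."""
    n = trace.n_samples
    dt = trace.dt
    vx = np.full((n, 2), np.nan)
    vy = np.full((n, 2), np.nan)
    ok = np.zeros((n, 2), dtype=bool)
    for eye in (0, 1):
        valid = trace.valid[:, eye]
        vx[:, eye], okx = _window_diff(trace.x[:, eye], valid, dt)
        vy[:, eye], oky = _window_diff(trace.y[:, eye], valid, dt)
        ok[:, eye] = okx & oky
    radial = np.sqrt(vx ** 2 + vy ** 2)
    radial_smooth = np.full_like(radial, np.nan)
    for eye in (0, 1):
        radial_smooth[:, eye], _ = _smooth5(radial[:, eye], ok[:, eye])
    return VelocityTrace(time=trace.time, vx=vx, vy=vy, radial=radial,
                         radial_smooth=radial_smooth, valid=ok)


def attach_latency(trials: pd.DataFrame, events,
                   exclude_zone=(-0.1, 0.5)) -> pd.DataFrame:
    """Attach microsaccade-latency metadata to trials.

    Adds:

    * ``tau_s`` — t_stim minus the onset of the nearest microsaccade
      (positive: stimulus after onset); ties at equal |tau| resolve to
      the later event; +inf when the session has no events;
    * ``event_direction_deg`` — direction of that nearest event;
    * ``is_baseline`` — True when *no* event onset falls inside the
      perisaccadic zone, i.e. every event has
      tau <= exclude_zone[0] or tau >= exclude_zone[1].
    """
    out = trials.copy()
    onsets = np.array(sorted(e.onset for e in events))
    by_onset = sorted(events, key=lambda e: e.onset)
    t_stim = out["t_stim_s"].to_numpy(dtype=float)
    if onsets.size == 0:
        out["tau_s"] = np.inf
        out["event_direction_deg"] = np.nan
        out["is_baseline"] = True
        return out
    k = np.searchsorted(onsets, t_stim)
    lo = np.clip(k - 1, 0, onsets.size - 1)
    hi = np.clip(k, 0, onsets.size - 1)
    d_lo = np.abs(t_stim - onsets[lo])
    d_hi = np.abs(t_stim - onsets[hi])
    pick_hi = d_hi <= d_lo  # tie -> following (later) event
    nearest_idx = np.where(pick_hi, hi, lo)
    out["tau_s"] = t_stim - onsets[nearest_idx]
    out["event_direction_deg"] = [by_onset[i].direction for i in nearest_idx]
    # baseline: no onset in (t_stim - zone_hi, t_stim - zone_lo)
    z_lo, z_hi = exclude_zone
    left = np.searchsorted(onsets, t_stim - z_hi, side="right")
    right = np.searchsorted(onsets, t_stim - z_lo, side="left")
    out["is_baseline"] = right <= left
    return out


def exclude_blink_trials(trials: pd.DataFrame, blink_ivals: np.ndarray,
                         window: float = 0.1):
    """Drop trials with any blink sample within ``window`` s of the
    stimulus; returns (filtered trials, exclusion fraction).

    ``blink_ivals`` are the *unbuffered* pupil==0 intervals, shape (k, 2).
    """
    if len(trials) == 0:
        return trials, 0.0
    blink_ivals = np.asarray(blink_ivals, dtype=float).reshape(-1, 2)
    t = trials["t_stim_s"].to_numpy(dtype=float)
    hit = np.zeros(t.size, dtype=bool)
    for s, e in blink_ivals:
        hit |= (t + window >= s) & (t - window <= e)
    return trials[~hit], float(hit.mean())
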