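"""Post-microsaccadic drift: epoch-averaged radial velocity and box count.

Left-eye positions are collated in epochs from 1 s before to 1 s after
each microsaccade onset; samples falling inside *any* detected event are
removed.  Two drift magnitudes are computed on the epoch grid:

* mean radial eye velocity (5-point-smoothed) per sample;
* the number of distinct 0.01-deg square grid cells the trajectory
  visits per 50-ms bin (box counting), grid anchored at the coordinate
  origin.

Both are normalized by their baseline mean, where baseline samples are
those further than 0.1 s before and 0.5 s after every microsaccade
onset; SE bands are computed across events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import compute_velocity, mask_blinks
from .trace import GazeTrace

__all__ = [
    "EpochStack", "epoch_positions", "box_count", "box_count_bins",
    "drift_timecourse", "baseline_sample_mask", "normalize_drift",
]

LEFT = 0


@dataclass
class EpochStack:
    """Event-aligned left-eye position segments.

    ``x``/``y``/``valid`` are shaped (n_events, n_rel); ``rel_time`` is
    the common grid relative to each event's onset.  ``truncated`` flags
    epochs clipped by the recording edge.
    """

    rel_time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    truncated: np.ndarray


def _event_sample_mask(trace: GazeTrace, events) -> np.ndarray:
    """True at samples inside any event's [onset, offset]."""
    m = np.zeros(trace.n_samples, dtype=bool)
    t0 = trace.time[0]
    dt = trace.dt
    for e in events:
        i0 = max(int(np.ceil((e.onset - t0) / dt)), 0)
        i1 = min(int(np.floor((e.offset - t0) / dt)), trace.n_samples - 1)
        if i1 >= i0:
            m[i0:i1 + 1] = True
    return m


def epoch_positions(trace: GazeTrace, events, window=(-1.0, 1.0)) -> EpochStack:
    """Collate left-eye positions around each onset, with samples during
    any microsaccade (its own or a neighbor's) invalidated."""
    dt = trace.dt
    k0 = int(round(window[0] / dt))
    k1 = int(round(window[1] / dt))
    rel = np.arange(k0, k1 + 1) * dt
    in_event = _event_sample_mask(trace, events)
    base_valid = trace.valid[:, LEFT] & ~in_event
    n_ev = len(events)
    nrel = rel.size
    x = np.full((n_ev, nrel), np.nan)
    y = np.full((n_ev, nrel), np.nan)
    valid = np.zeros((n_ev, nrel), dtype=bool)
    truncated = np.zeros(n_ev, dtype=bool)
    t0 = trace.time[0]
    for j, e in enumerate(events):
        c = int(round((e.onset - t0) / dt))
        a, b = c + k0, c + k1
        src0, src1 = max(a, 0), min(b, trace.n_samples - 1)
        if src0 > a or src1 < b:
            truncated[j] = True
        if src1 < src0:
            continue
        d0 = src0 - a
        d1 = d0 + (src1 - src0)
        x[j, d0:d1 + 1] = trace.x[src0:src1 + 1, LEFT]
        y[j, d0:d1 + 1] = trace.y[src0:src1 + 1, LEFT]
        valid[j, d0:d1 + 1] = base_valid[src0:src1 + 1]
    valid &= np.isfinite(x) & np.isfinite(y)
    return EpochStack(rel_time=rel, x=x, y=y, valid=valid, truncated=truncated)


def box_count(x, y, box: float = 0.01) -> int:
    """Number of distinct square grid cells (edge ``box``, anchored at
    the origin) containing at least one of the given positions."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if not ok.any():
        raise ValueError("no valid positions")
    ix = np.floor(x[ok] / box).astype(np.int64)
    iy = np.floor(y[ok] / box).astype(np.int64)
    return int(np.unique(np.stack([ix, iy], axis=1), axis=0).shape[0])


def box_count_bins(stack: EpochStack, box: float = 0.01, bin_width: float = 0.05):
    """Per-epoch box counts in consecutive ``bin_width`` time bins.

    Returns ``(bin_centers, counts)`` with counts shaped
    (n_events, n_bins); empty bins are NaN and excluded from averages.
    """
    dt = stack.rel_time[1] - stack.rel_time[0]
    per_bin = max(int(round(bin_width / dt)), 1)
    n_bins = stack.rel_time.size // per_bin
    centers = np.array([
        stack.rel_time[i * per_bin: (i + 1) * per_bin].mean()
        for i in range(n_bins)
    ])
    n_ev = stack.x.shape[0]
    counts = np.full((n_ev, n_bins), np.nan)
    used = per_bin * n_bins
    ok = stack.valid[:, :used]
    if ok.any():
        # flatten to one unique-count over (epoch, bin, cell) triples
        ev_idx, s_idx = np.nonzero(ok)
        bin_idx = s_idx // per_bin
        ix = np.floor(stack.x[ev_idx, s_idx] / box).astype(np.int64)
        iy = np.floor(stack.y[ev_idx, s_idx] / box).astype(np.int64)
        key = np.stack([ev_idx, bin_idx, ix, iy], axis=1)
        uniq = np.unique(key, axis=0)
        flat = uniq[:, 0] * n_bins + uniq[:, 1]
        bc = np.bincount(flat, minlength=n_ev * n_bins).reshape(n_ev, n_bins)
        nonempty = np.zeros((n_ev, n_bins), dtype=bool)
        has = np.unique(np.stack([ev_idx, bin_idx], axis=1), axis=0)
        nonempty[has[:, 0], has[:, 1]] = True
        counts[nonempty] = bc[nonempty]
    return centers, counts


def baseline_sample_mask(trace: GazeTrace, events, pre: float = 0.1,
                         post: float = 0.5) -> np.ndarray:
    """Samples further than ``pre`` before and ``post`` after every onset."""
    m = np.ones(trace.n_samples, dtype=bool)
    t0 = trace.time[0]
    dt = trace.dt
    for e in events:
        i0 = max(int(np.ceil((e.onset - pre - t0) / dt)), 0)
        i1 = min(int(np.floor((e.onset + post - t0) / dt)), trace.n_samples - 1)
        if i1 >= i0:
            m[i0:i1 + 1] = False
    return m


def drift_timecourse(trace: GazeTrace, events, window=(-1.0, 1.0),
                     box: float = 0.01, bin_width: float = 0.05,
                     blink_buffer: float = 0.2) -> pd.DataFrame:
    """Epoch-averaged radial velocity and box count around microsaccade
    onset, normalized to the baseline window, with SE across events.

    Returns a tidy DataFrame with separate grids for the two metrics
    (sample grid for velocity, 50-ms bins for box count) identified by a
    ``metric`` column: t_rel_s, metric, value_norm, se_norm, n_events.
    """
    masked = mask_blinks(trace, buffer=blink_buffer)
    vel = compute_velocity(masked)
    in_event = _event_sample_mask(masked, events)
    rv = vel.radial_smooth[:, LEFT].copy()
    rv_ok = vel.valid[:, LEFT] & ~in_event & np.isfinite(rv)

    base = baseline_sample_mask(masked, events)
    base_v = rv[base & rv_ok]
    if base_v.size == 0 or not np.isfinite(base_v.mean()) or base_v.mean() == 0:
        raise ValueError("empty or degenerate baseline for radial velocity")
    v0 = float(base_v.mean())

    # epoch the velocity like the positions
    stack = epoch_positions(masked, events, window=window)
    dt = masked.dt
    t0 = masked.time[0]
    k0 = int(round(window[0] / dt))
    nrel = stack.rel_time.size
    vmat = np.full((len(events), nrel), np.nan)
    for j, e in enumerate(events):
        c = int(round((e.onset - t0) / dt))
        a = c + k0
        src0 = max(a, 0)
        src1 = min(a + nrel - 1, masked.n_samples - 1)
        if src1 < src0:
            continue
        d0 = src0 - a
        seg = rv[src0:src1 + 1].copy()
        seg[~rv_ok[src0:src1 + 1]] = np.nan
        vmat[j, d0:d0 + seg.size] = seg
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        v_mean = np.nanmean(vmat, axis=0)
        v_n = np.sum(np.isfinite(vmat), axis=0)
        v_se = np.nanstd(vmat, axis=0, ddof=1) / np.sqrt(np.maximum(v_n, 1))
    rows = pd.DataFrame({
        "t_rel_s": stack.rel_time, "metric": "radial_velocity",
        "value_norm": v_mean / v0, "se_norm": v_se / v0, "n_events": v_n,
    })

    # box count: baseline from baseline-run bins of the whole trace
    centers, counts = box_count_bins(stack, box=box, bin_width=bin_width)
    base_counts = _baseline_box_counts(masked, base & masked.valid[:, LEFT]
                                       & ~in_event, box, bin_width)
    if base_counts.size == 0 or base_counts.mean() == 0:
        raise ValueError("empty or degenerate baseline for box count")
    b0 = float(base_counts.mean())
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        b_mean = np.nanmean(counts, axis=0)
        b_n = np.sum(np.isfinite(counts), axis=0)
        b_se = np.nanstd(counts, axis=0, ddof=1) / np.sqrt(np.maximum(b_n, 1))
    rows_b = pd.DataFrame({
        "t_rel_s": centers, "metric": "box_count",
        "value_norm": b_mean / b0, "se_norm": b_se / b0, "n_events": b_n,
    })
    return pd.concat([rows, rows_b], ignore_index=True)


def _baseline_box_counts(trace: GazeTrace, mask: np.ndarray, box: float,
                         bin_width: float) -> np.ndarray:
    """Box counts over consecutive bins of fully-baseline samples."""
    dt = trace.dt
    per_bin = max(int(round(bin_width / dt)), 1)
    counts = []
    n = trace.n_samples
    for start in range(0, n - per_bin + 1, per_bin):
        sl = slice(start, start + per_bin)
        if mask[sl].all():
            counts.append(box_count(trace.x[sl, LEFT], trace.y[sl, LEFT], box=box))
    return np.asarray(counts, dtype=float)


def normalize_drift(values: np.ndarray, baseline_mask: np.ndarray) -> np.ndarray:
    """Divide a metric by the mean of its baseline samples."""
    v = np.asarray(values, dtype=float)
    base = v[np.asarray(baseline_mask, bool)]
    base = base[np.isfinite(base)]
    if base.size == 0:
        raise ValueError("baseline is empty")
    m = float(base.mean())
    if m == 0.0:
        raise ValueError("zero baseline mean")
    return v / m
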