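"""Seeded synthetic fixation sessions with ground-truth microsaccades.

The generator emulates the statistical structure the downstream analyses
assume: 500-Hz binocular gaze traces containing 2-D Brownian drift,
microsaccades whose peak velocity follows a power-law main sequence
(``V = k * A**b`` with multiplicative log-normal noise), occasional
blinks (pupil = 0), and a detection task driven by five interleaved
1-up-3-down staircases, one per spatial frequency (0.1, 0.33, 1, 2,
5 cycles/deg).  The observer's log10 contrast threshold at each trial is
shifted by a suppression + facilitation template evaluated at the
trial's latency to the nearest (ground-truth) microsaccade, so the full
pipeline can be checked by parameter recovery.

Every draw derives from a single :class:`numpy.random.Generator`;
identical seed + config gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gainmodel import DEFAULT_POLY, sf_profile
from .psychofit import predict
from .trace import ARCMIN_PER_DEG, GazeTrace, Microsaccade, TRIAL_COLUMNS

__all__ = [
    "SynthConfig", "SensitivityTemplate", "SynthSession",
    "template_sr", "generate_trace", "simulate_session", "simulate_study",
    "STUDY_SFS",
]

#: spatial frequencies of the study, cycles/deg
STUDY_SFS = (0.1, 0.33, 1.0, 2.0, 5.0)


def _default_suppression():
    # ground-truth suppression depth per sf: the empirical third-order
    # polynomial over log10 sf evaluated at the five studied frequencies
    return {sf: float(sf_profile(np.log10(sf), DEFAULT_POLY)) for sf in STUDY_SFS}


def _default_facilitation():
    # facilitation largest at 2 cycles/deg, present only at >=1 cycle/deg
    return {0.1: 0.0, 0.33: 0.0, 1.0: 0.05, 2.0: 0.08, 5.0: 0.03}


@dataclass
class SensitivityTemplate:
    """Ground-truth perturbation of log10 sensitivity around a microsaccade.

    ``sr(tau, sf)`` is the sum of a negative suppression Gaussian and a
    positive facilitation Gaussian in tau = t_stim - t_onset (seconds);
    depths/amplitudes are log10 sensitivity-ratio units.
    """

    suppression_depth_by_sf: dict = field(default_factory=_default_suppression)
    suppression_center: float = 0.02
    suppression_width: float = 0.067
    facilitation_amp_by_sf: dict = field(default_factory=_default_facilitation)
    facilitation_center: float = 0.125
    facilitation_width: float = 0.05

    def __post_init__(self):
        if self.suppression_width <= 0 or self.facilitation_width <= 0:
            raise ValueError("template widths must be positive")
        if any(v > 0 for v in self.suppression_depth_by_sf.values()):
            raise ValueError("suppression depths must be <= 0")
        if any(v < 0 for v in self.facilitation_amp_by_sf.values()):
            raise ValueError("facilitation amplitudes must be >= 0")

    @classmethod
    def zero(cls, sfs=STUDY_SFS):
        return cls(suppression_depth_by_sf={sf: 0.0 for sf in sfs},
                   facilitation_amp_by_sf={sf: 0.0 for sf in sfs})


def template_sr(tau, sf, template: SensitivityTemplate):
    """Log10 sensitivity ratio at latency ``tau`` for spatial frequency ``sf``."""
    if sf not in template.suppression_depth_by_sf:
        raise KeyError(f"unknown spatial frequency {sf}")
    tau = np.asarray(tau, dtype=float)
    sup = template.suppression_depth_by_sf[sf] * np.exp(
        -((tau - template.suppression_center) / template.suppression_width) ** 2)
    fac = template.facilitation_amp_by_sf.get(sf, 0.0) * np.exp(
        -((tau - template.facilitation_center) / template.facilitation_width) ** 2)
    out = sup + fac
    return out if out.ndim else float(out)


def _default_mu():
    # baseline log10 contrast thresholds: CSF peaking near 1-2 cycles/deg
    return {0.1: -1.3, 0.33: -1.7, 1.0: -2.0, 2.0: -2.1, 5.0: -1.8}


def _default_slopes():
    return {sf: 0.08 for sf in STUDY_SFS}


@dataclass
class SynthConfig:
    """Generator configuration; defaults are the study conditions."""

    sampling_rate: float = 500.0          # Hz
    session_duration: float = 300.0       # s (ignored when n_trials is set)
    n_trials: int | None = None           # stop after this many trials

    # microsaccades
    ms_rate: float = 1.5                  # events/s, population range 0.3-2.3
    ms_refractory: float = 0.15           # s, min onset gap beyond prior offset
    amplitude_log_median: float = 12.0    # arcmin, log-normal median
    amplitude_log_sd: float = 0.5         # sd of ln(amplitude)
    amplitude_bounds: tuple = (3.0, 60.0)  # arcmin, hard clip
    main_sequence_k: float = 70.0         # deg/s at 1 deg amplitude
    main_sequence_b: float = 0.9          # power-law exponent
    main_sequence_noise_sd: float = 0.1   # sd of ln multiplicative noise
    direction_kappa: float = 4.0          # von Mises concentration at 0/180 deg

    # drift, tracker noise, blinks
    drift_diffusion: float = 0.004        # deg^2/s per axis (Brownian walk)
    eye_noise_sd: float = 0.002           # deg, independent per-eye sample noise
    blink_rate: float = 0.1               # events/s
    blink_duration: float = 0.15          # s

    # task timing
    iti_range: tuple = (0.8, 4.0)         # s, uniform
    response_latency_range: tuple = (0.2, 0.6)  # s, uniform

    # staircases (log10 contrast units)
    staircase_initial: float = 0.3        # above baseline threshold
    staircase_step_up: float = 0.05
    staircase_step_down: float = 0.05

    # observer
    observer_mu: dict = field(default_factory=_default_mu)       # log10 contrast
    observer_slope: dict = field(default_factory=_default_slopes)
    observer_lapse: float = 0.055
    template: SensitivityTemplate = field(default_factory=SensitivityTemplate)

    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.session_duration <= 0:
            raise ValueError("session_duration must be positive")
        if self.ms_rate < 0:
            raise ValueError("ms_rate must be >= 0")
        lo, hi = self.amplitude_bounds
        if not (3.0 <= lo < hi <= 60.0):
            raise ValueError("amplitude bounds must lie within [3, 60] arcmin")
        if self.staircase_step_up <= 0 or self.staircase_step_down <= 0:
            raise ValueError("staircase steps must be positive")
        if isinstance(self.template, dict):
            self.template = SensitivityTemplate(**self.template)

    @property
    def sfs(self):
        return tuple(sorted(self.observer_mu))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        for key in ("iti_range", "response_latency_range", "amplitude_bounds"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "observer_mu" in d and d["observer_mu"] is not None:
            d["observer_mu"] = {float(k): float(v) for k, v in d["observer_mu"].items()}
        if "observer_slope" in d and d["observer_slope"] is not None:
            d["observer_slope"] = {float(k): float(v) for k, v in d["observer_slope"].items()}
        if "template" in d and isinstance(d["template"], dict):
            t = dict(d["template"])
            for key in ("suppression_depth_by_sf", "facilitation_amp_by_sf"):
                if key in t:
                    t[key] = {float(k): float(v) for k, v in t[key].items()}
            d["template"] = SensitivityTemplate(**t)
        return cls(**d)


@dataclass
class SynthSession:
    """One generated session: trace, ground-truth events and trial table."""

    trace: GazeTrace
    events: list
    trials: pd.DataFrame
    config: SynthConfig


def _draw_events(cfg: SynthConfig, rng, duration):
    """Poisson-like event stream with refractory gaps; returns list of
    (onset, duration, amplitude_deg, peak_velocity, direction_deg)."""
    events = []
    if cfg.ms_rate <= 0:
        return events
    t = 0.3  # settle-in
    prev_offset = 0.0
    while True:
        gap = rng.exponential(1.0 / cfg.ms_rate)
        onset = max(t + gap, prev_offset + cfg.ms_refractory)
        amp_arcmin = float(np.clip(
            np.exp(rng.normal(np.log(cfg.amplitude_log_median), cfg.amplitude_log_sd)),
            *cfg.amplitude_bounds))
        amp = amp_arcmin / ARCMIN_PER_DEG
        vpeak = cfg.main_sequence_k * amp ** cfg.main_sequence_b
        if cfg.main_sequence_noise_sd > 0:
            vpeak *= float(np.exp(rng.normal(0.0, cfg.main_sequence_noise_sd)))
        dur = 2.0 * amp / vpeak  # raised-cosine: mean velocity = vpeak/2
        theta = float(rng.vonmises(0.0, cfg.direction_kappa))
        if rng.random() < 0.5:
            theta += np.pi
        direction = float(np.degrees(theta) % 360.0)
        if onset + dur > duration - 0.1:
            break
        events.append((onset, dur, amp, vpeak, direction))
        t = onset
        prev_offset = onset + dur
    return events


def generate_trace(cfg: SynthConfig, rng=None, duration=None, events=None):
    """Binocular gaze trace plus the ground-truth microsaccade list.

    ``events`` may inject a preset list of ``(onset, duration,
    amplitude_deg, peak_velocity, direction_deg)`` tuples (used by tests
    for noiseless main-sequence checks); otherwise the stream is drawn
    from the configured rate/amplitude/main-sequence distributions.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    duration = cfg.session_duration if duration is None else duration
    if duration <= 0:
        raise ValueError("duration must be positive")
    dt = 1.0 / cfg.sampling_rate
    n = int(round(duration * cfg.sampling_rate))
    time = np.arange(n) * dt

    if events is None:
        events = _draw_events(cfg, rng, duration)

    # one generative trajectory rendered into both eyes
    incr_x = np.zeros(n)
    incr_y = np.zeros(n)
    if cfg.drift_diffusion > 0:
        sd = np.sqrt(cfg.drift_diffusion * dt)
        incr_x += rng.normal(0.0, sd, n)
        incr_y += rng.normal(0.0, sd, n)
    true_events = []
    for onset, dur, amp, vpeak, direction in events:
        i0 = int(np.ceil(onset / dt))
        i1 = min(int(np.floor((onset + dur) / dt)), n - 1)
        if i1 <= i0:
            continue
        idx = np.arange(i0, i1 + 1)
        u = np.clip((time[idx] - onset) / dur, 0.0, 1.0)
        disp = amp * (u - np.sin(2 * np.pi * u) / (2 * np.pi))
        prev = np.concatenate([[0.0], disp[:-1]])
        step = disp - prev
        step[-1] += amp - disp[-1]  # land exactly on the full amplitude
        th = np.radians(direction)
        incr_x[idx] += step * np.cos(th)
        incr_y[idx] += step * np.sin(th)
        true_events.append(Microsaccade(
            onset=onset, offset=onset + dur,
            amplitude=amp * ARCMIN_PER_DEG, peak_velocity=vpeak,
            direction=direction, eye="binocular"))
    base_x = np.cumsum(incr_x)
    base_y = np.cumsum(incr_y)

    x = np.column_stack([base_x, base_x])
    y = np.column_stack([base_y, base_y])
    if cfg.eye_noise_sd > 0:
        x = x + rng.normal(0.0, cfg.eye_noise_sd, (n, 2))
        y = y + rng.normal(0.0, cfg.eye_noise_sd, (n, 2))
    pupil = np.full((n, 2), 1000.0)

    if cfg.blink_rate > 0:
        t = 0.0
        while True:
            t += rng.exponential(1.0 / cfg.blink_rate)
            if t >= duration:
                break
            j0 = int(t / dt)
            j1 = min(int((t + cfg.blink_duration) / dt), n)
            pupil[j0:j1, :] = 0.0
            x[j0:j1, :] = np.nan
            y[j0:j1, :] = np.nan

    return GazeTrace(time=time, x=x, y=y, pupil=pupil), true_events


def _nearest_tau(t_stim, onsets):
    """tau = t_stim - onset of the nearest event; ties go to the later
    event (negative tau); +inf when there are no events."""
    if onsets.size == 0:
        return np.full(np.size(t_stim), np.inf)
    t_stim = np.atleast_1d(np.asarray(t_stim, dtype=float))
    k = np.searchsorted(onsets, t_stim)
    lo = np.clip(k - 1, 0, onsets.size - 1)
    hi = np.clip(k, 0, onsets.size - 1)
    d_lo = np.abs(t_stim - onsets[lo])
    d_hi = np.abs(t_stim - onsets[hi])
    pick_hi = d_hi <= d_lo  # tie -> later event
    nearest = np.where(pick_hi, onsets[hi], onsets[lo])
    return t_stim - nearest


def simulate_session(cfg: SynthConfig, rng=None, subject: str = "s01") -> SynthSession:
    """Full session: trace + ground-truth events + staircase-driven trials.

    Each trial's correctness is Bernoulli from the logistic psychometric
    with the observer's log10 threshold shifted by ``-template_sr`` at
    the trial's latency to the nearest ground-truth microsaccade (a
    negative SR elevates the threshold).  The stimulus is treated as
    instantaneous at onset (one 85-Hz frame).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    sfs = cfg.sfs
    duration = cfg.session_duration
    if cfg.n_trials is not None:
        # generous sizing: mean trial period = response latency + mean ITI
        period = (np.mean(cfg.response_latency_range) + np.mean(cfg.iti_range))
        duration = cfg.n_trials * period * 1.1 + 10.0
    trace, events = generate_trace(cfg, rng=rng, duration=duration)
    onsets = np.array([e.onset for e in events])

    state = {sf: {"c": cfg.observer_mu[sf] + cfg.staircase_initial, "streak": 0}
             for sf in sfs}
    rows = []
    t = 1.0
    while t < duration - 1.0:
        if cfg.n_trials is not None and len(rows) >= cfg.n_trials:
            break
        sf = sfs[rng.integers(len(sfs))]
        st = state[sf]
        c = st["c"]
        tau = float(_nearest_tau(t, onsets)[0])
        sr = template_sr(tau, sf, cfg.template) if np.isfinite(tau) else 0.0
        mu_eff = cfg.observer_mu[sf] - sr
        p = predict(c, mu_eff, cfg.observer_slope[sf], cfg.observer_lapse)
        correct = bool(rng.random() < p)
        orientation = 45.0 if rng.random() < 0.5 else -45.0
        rows.append((subject, t, sf, c, orientation, int(correct)))
        if correct:
            st["streak"] += 1
            if st["streak"] >= 3:
                st["c"] -= cfg.staircase_step_down
                st["streak"] = 0
        else:
            st["c"] += cfg.staircase_step_up
            st["streak"] = 0
        t += rng.uniform(*cfg.response_latency_range) + rng.uniform(*cfg.iti_range)

    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    counts = trials["sf_cpd"].value_counts()
    if len(counts) < len(sfs) or counts.min() < 1:
        raise ValueError("session too short: not every staircase received a trial")
    return SynthSession(trace=trace, events=events, trials=trials, config=cfg)


def simulate_study(cfg: SynthConfig, n_subjects: int = 15, seed: int | None = None,
                   rate_range=(0.8, 2.2)):
    """Multi-subject study: per-subject sessions with microsaccade rates
    drawn uniformly from ``rate_range`` (within the population's
    0.3-2.3/s span).  Returns a list of :class:`SynthSession`."""
    seed = cfg.seed if seed is None else seed
    master = np.random.default_rng(seed)
    sessions = []
    for i in range(n_subjects):
        sub_cfg = dataclasses.replace(
            cfg,
            ms_rate=float(master.uniform(*rate_range)) if cfg.ms_rate > 0 else 0.0,
            seed=int(master.integers(2 ** 31 - 1)),
        )
        rng = np.random.default_rng(sub_cfg.seed)
        sessions.append(simulate_session(sub_cfg, rng=rng, subject=f"s{i + 1:02d}"))
    return sessions
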