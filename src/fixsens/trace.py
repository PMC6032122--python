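"""Containers for binocular gaze recordings and detected microsaccades.

Conventions used throughout the package:

* time in seconds on a uniform sampling grid (500 Hz by default);
* gaze position in degrees of visual angle, screen coordinates
  (0 deg = rightward, angles counterclockwise positive);
* microsaccade amplitudes in arcmin, peak velocities in deg/s;
* eye index 0 = left, 1 = right.  The empirical analyses report
  left-eye parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ARCMIN_PER_DEG = 60.0

#: column order of the on-disk gaze format
TRACE_COLUMNS = [
    "time_s", "xL_deg", "yL_deg", "pupilL", "xR_deg", "yR_deg", "pupilR",
]

EVENT_COLUMNS = [
    "onset_s", "offset_s", "duration_ms", "amplitude_arcmin",
    "peak_velocity_dps", "direction_deg",
]

TRIAL_COLUMNS = [
    "subject", "t_stim_s", "sf_cpd", "log10_contrast",
    "stim_orientation_deg", "correct",
]


@dataclass
class GazeTrace:
    """Binocular 500-Hz gaze samples with pupil channel.

    Arrays are shaped ``(n_samples, 2)`` with eye 0 = left, 1 = right,
    except ``time`` which is ``(n_samples,)``.  ``valid`` marks samples
    usable for analysis; it starts as ``pupil > 0`` and is further
    restricted by blink masking.
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1:
            raise ValueError("time must be 1-D")
        for name in ("x", "y", "pupil"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.time.size, 2):
                raise ValueError(f"{name} must have shape (n, 2)")
            setattr(self, name, arr)
        dt = np.diff(self.time)
        if self.time.size > 1 and (dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("time must be strictly increasing on a uniform grid")
        if self.valid is None:
            self.valid = (self.pupil > 0) & np.isfinite(self.x) & np.isfinite(self.y)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.pupil.shape:
                raise ValueError("valid must match pupil shape")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt

    def copy(self) -> "GazeTrace":
        return replace(
            self, time=self.time.copy(), x=self.x.copy(), y=self.y.copy(),
            pupil=self.pupil.copy(), valid=self.valid.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time,
            "xL_deg": self.x[:, 0], "yL_deg": self.y[:, 0], "pupilL": self.pupil[:, 0],
            "xR_deg": self.x[:, 1], "yR_deg": self.y[:, 1], "pupilR": self.pupil[:, 1],
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GazeTrace":
        return cls(
            time=df["time_s"].to_numpy(),
            x=np.column_stack([df["xL_deg"], df["xR_deg"]]),
            y=np.column_stack([df["yL_deg"], df["yR_deg"]]),
            pupil=np.column_stack([df["pupilL"], df["pupilR"]]),
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def read(cls, path) -> "GazeTrace":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class VelocityTrace:
    """Eye velocities on the gaze grid, from a 5-sample moving-window
    differentiator; ``radial_smooth`` carries the 5-point moving average
    of radial velocity used by the drift analyses."""

    time: np.ndarray
    vx: np.ndarray          # (n, 2) deg/s
    vy: np.ndarray          # (n, 2) deg/s
    radial: np.ndarray      # (n, 2) deg/s, sqrt(vx^2 + vy^2)
    radial_smooth: np.ndarray
    valid: np.ndarray       # (n, 2) bool, False at run edges/invalid samples

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class Microsaccade:
    """A detected (or generated ground-truth) microsaccade."""

    onset: float            # s
    offset: float           # s
    amplitude: float        # arcmin, net onset->offset displacement
    peak_velocity: float    # deg/s
    direction: float        # deg in [0, 360), 0 = rightward
    eye: str = "binocular"  # "left" | "right" | "binocular"

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def events_to_frame(events) -> pd.DataFrame:
    return pd.DataFrame({
        "onset_s": [e.onset for e in events],
        "offset_s": [e.offset for e in events],
        "duration_ms": [1e3 * e.duration for e in events],
        "amplitude_arcmin": [e.amplitude for e in events],
        "peak_velocity_dps": [e.peak_velocity for e in events],
        "direction_deg": [e.direction for e in events],
    }, columns=EVENT_COLUMNS)


def events_from_frame(df: pd.DataFrame, eye: str = "binocular"):
    return [
        Microsaccade(
            onset=r.onset_s, offset=r.offset_s,
            amplitude=r.amplitude_arcmin, peak_velocity=r.peak_velocity_dps,
            direction=r.direction_deg, eye=eye,
        )
        for r in df.itertuples(index=False)
    ]


def write_events(events, path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events(path):
    return events_from_frame(pd.read_csv(path, sep="\t"))


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
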