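"""Core containers for trunk-accelerometer gait analysis.

Conventions used throughout the package:

* accelerations are stored in units of *g* (1 g = 9.80665 m/s^2);
* channel order is (AP, ML, vertical), i.e. the vertical axis is the third
  column of the acceleration array;
* event and bout times are seconds from the start of the recording;
* bout intervals are half-open ``[start_s, end_s)``;
* a stride spans two consecutive same-foot initial contacts (every second
  initial contact of the merged event train).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: standard gravity, m/s^2
GRAVITY_MPS2 = 9.80665

#: columns of a per-stride parameter table
STRIDE_COLUMNS = [
    "subject",
    "visit",
    "task",
    "location",
    "bout_id",
    "ic_time_s",
    "stride_time_s",
    "stride_length_m",
    "gait_speed_mps",
    "cadence_spm",
    "vertical_excursion_m",
    "pendulum_length_m",
]

#: gait endpoints compared between devices
ENDPOINTS = ["gait_speed_mps", "cadence_spm", "stride_time_s", "stride_length_m"]


def empty_stride_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object if c in
                                      ("subject", "visit", "task", "location") else float)
                         for c in STRIDE_COLUMNS})


@dataclass
class AccelRecording:
    """One tri-axial accelerometer channel with study metadata.

    ``accel`` has shape (n, 3) in g; ``fs`` is the sampling rate in Hz.
    ``sensor_height`` is the inverted-pendulum length (m) used for spatial
    reconstruction at this wearing location.
    """

    time: np.ndarray
    accel: np.ndarray
    fs: float
    location: str = "chest"
    subject: str | None = None
    visit: int | None = None
    task: str | None = None
    sensor_height: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValueError("accel must have shape (n, 3)")
        if self.time.shape[0] != self.accel.shape[0]:
            raise ValueError("time and accel length mismatch")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.time.size > 1:
            dt = np.diff(self.time)
            if np.any(np.abs(dt - 1.0 / self.fs) > 1e-6):
                raise ValueError("time grid is not uniform at the stated rate")

    @property
    def duration_s(self) -> float:
        return self.accel.shape[0] / self.fs

    @property
    def vertical(self) -> np.ndarray:
        """Vertical channel in g (third column)."""
        return self.accel[:, 2]

    def replace(self, **kw) -> "AccelRecording":
        return dataclasses.replace(self, **kw)


@dataclass
class GaitEvents:
    """Initial-contact (heel strike) and final-contact (toe off) times, s."""

    initial_contacts: np.ndarray = field(default_factory=lambda: np.empty(0))
    final_contacts: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.initial_contacts = np.asarray(self.initial_contacts, dtype=float)
        self.final_contacts = np.asarray(self.final_contacts, dtype=float)
        for arr in (self.initial_contacts, self.final_contacts):
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise ValueError("event times must be strictly increasing")

    @property
    def n_initial(self) -> int:
        return int(self.initial_contacts.size)

    def check_alternation(self) -> bool:
        """True iff every final contact falls between successive initial contacts."""
        ics = self.initial_contacts
        for fc in self.final_contacts:
            i = np.searchsorted(ics, fc)
            if i == 0 or i >= ics.size:
                ok = ics.size and (fc > ics[-1] or fc < ics[0])
                if not ok:
                    return False
                return False
            # fc strictly inside (ics[i-1], ics[i])
            if not (ics[i - 1] < fc < ics[i]):
                return False
        return True


@dataclass
class GaitBout:
    """A contiguous walking interval, half-open [start_s, end_s)."""

    start_s: float
    end_s: float
    window_flags: np.ndarray | None = None
    events: GaitEvents | None = None

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("bout end must exceed start")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def n_cycles(self) -> int:
        """Complete gait cycles (strides) contained in the bout.

        k initial contacts delimit k-1 steps = (k-1)//2 full cycles.
        """
        if self.events is None:
            return 0
        return max(0, (self.events.n_initial - 1) // 2)


@dataclass
class GroundTruth:
    """Per-recording simulation truth: events, bouts and per-stride parameters."""

    events: GaitEvents
    bouts: list[tuple[float, float]]
    strides: pd.DataFrame  # stride_time_s, stride_length_m, gait_speed_mps, cadence_spm
    step_count: int
    params: dict = field(default_factory=dict)

    def contains_events(self) -> bool:
        """True iff every event lies strictly inside some bout interval."""
        times = np.concatenate([self.events.initial_contacts,
                                self.events.final_contacts])
        for t in times:
            if not any(s < t < e for s, e in self.bouts):
                return False
        return True


@dataclass
class AgreementResult:
    """Method-comparison summary for one endpoint/task pairing."""

    endpoint: str
    n: int
    bias: float
    loa_lower: float
    loa_upper: float
    bias_ci: tuple[float, float]
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    mad: float
    mpe: float
    icc: float
    icc_bounds: tuple[float, float]
    pearson_r: float
    pearson_p: float
    label: str = ""

    def as_row(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "n": self.n,
            "bias": self.bias,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "mad": self.mad,
            "mpe_pct": self.mpe,
            "icc": self.icc,
            "icc_lb": self.icc_bounds[0],
            "icc_ub": self.icc_bounds[1],
            "icc_label": self.label,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
        }
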