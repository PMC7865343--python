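"""Shared data containers for the gait pipeline.

These are deliberately thin: plain arrays plus the metadata needed to keep
streams synchronized (sampling rate, trigger index) and auditable
(ground-truth event frames).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from gaitphase.errors import ShapeError

#: Channel suffixes of one sensor unit, in storage order.
CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz", "p1")

#: Default body locations of the ten feature sensors (master excluded).
SENSOR_LOCATIONS = (
    "l_foot",
    "r_foot",
    "l_tibia",
    "r_tibia",
    "l_thigh",
    "r_thigh",
    "l_hip",
    "r_hip",
    "l_arm",
    "r_arm",
)


class GaitPhase(IntEnum):
    """The five per-frame classes."""

    IC = 0  # initial contact, stretched over ``ic_stretch`` frames
    LR = 1  # loading response: contact+stretch .. first force peak
    MS = 2  # mid stance: first peak .. inter-peak force minimum
    TS = 3  # terminal stance: force minimum .. toe-off
    SW = 4  # swing: zero plate force

    @classmethod
    def from_code(cls, code: str) -> "GaitPhase":
        return cls[code]


N_PHASES = len(GaitPhase)


@dataclass
class ImuRecording:
    """Raw multi-sensor samples for one subject, channels grouped by device.

    ``samples`` has shape [T, N*C] where sensor ``n``'s channel ``c`` sits in
    column ``n*C + c`` (the by-device arrangement).
    """

    subject_id: str
    samples: np.ndarray
    rate_hz: float
    trigger_frame: int = 0
    sensor_locations: tuple[str, ...] = SENSOR_LOCATIONS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ShapeError(
                f"samples must be 2-D [T x channels], got {self.samples.ndim}-D"
            )
        expected = len(self.sensor_locations) * len(CHANNELS)
        if self.samples.shape[1] != expected:
            raise ShapeError(
                f"samples has {self.samples.shape[1]} columns, expected "
                f"{len(self.sensor_locations)} sensors x {len(CHANNELS)} "
                f"channels = {expected}"
            )

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def n_sensors(self) -> int:
        return len(self.sensor_locations)

    @property
    def column_names(self) -> list[str]:
        return [
            f"{loc}_{ch}" for loc in self.sensor_locations for ch in CHANNELS
        ]


@dataclass
class PressureTrace:
    """Total vertical force on the plate over time (arbitrary units, >= 0)."""

    force: np.ndarray
    rate_hz: float
    trigger_frame: int = 0

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        if self.force.ndim != 1:
            raise ShapeError(f"force must be 1-D, got {self.force.ndim}-D")

    @property
    def n_frames(self) -> int:
        return self.force.shape[0]


@dataclass
class StepEvents:
    """Frame indices of one step's labeled events (0-based, half-open use)."""

    contact: int
    peak1: int
    valley: int
    peak2: int
    toe_off: int

    def __post_init__(self) -> None:
        self.contact = int(self.contact)
        self.peak1 = int(self.peak1)
        self.valley = int(self.valley)
        self.peak2 = int(self.peak2)
        self.toe_off = int(self.toe_off)

    def ordered(self) -> bool:
        return self.contact <= self.peak1 < self.valley < self.peak2 < self.toe_off


@dataclass
class PhaseLabels:
    """Per-frame phase classes plus the step events they were derived from."""

    labels: np.ndarray
    event_frames: list[StepEvents] = field(default_factory=list)
    ic_stretch: int = 10

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    def phase_codes(self) -> list[str]:
        return [GaitPhase(int(v)).name for v in self.labels]


@dataclass
class AlignmentInfo:
    """Bookkeeping for stream synchronization."""

    imu_trigger_frame: int
    pressure_trigger_frame: int
    max_sync_error_ms: float = 16.0

    def __post_init__(self) -> None:
        if self.max_sync_error_ms < 0:
            raise ValueError("max_sync_error_ms must be >= 0")
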