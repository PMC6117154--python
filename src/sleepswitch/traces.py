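"""In-memory containers for behavioral and electrophysiological recordings.

All containers are thin dataclasses over numpy arrays: behavioral traces are
1-D tube positions sampled on a uniform grid (the tracker reports position
along a 65 mm glass tube), electrophysiological traces are voltage series
with light-stimulation annotations attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .errors import FormatError

TUBE_LENGTH_MM = 65.0

#: Mechanical stimulus train delivered by the tracking platform: five 0.2 s
#: 2.4 g vibrations separated by 0.8 s.  Analyses key on the train onset only
#: (train span 4.2 s, far shorter than the 60 s response window).
VIBRATION_TRAIN = {"n_pulses": 5, "pulse_s": 0.2, "gap_s": 0.8, "intensity_g": 2.4}


@dataclass
class ActivityTrace:
    """Per-fly 1-D position time series on a uniform grid.

    ``speed`` is derived (mm/s, forward difference magnitude) and is None
    until :func:`sleepswitch.behavior.compute_speed` has run.
    """

    fly_id: str
    t: np.ndarray          # seconds since experiment start (ZT0), uniform
    x: np.ndarray          # position along tube, mm
    speed: np.ndarray | None = None
    tube_length_mm: float = TUBE_LENGTH_MM

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.x.shape:
            raise FormatError("t and x must be 1-D arrays of equal length")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise FormatError(f"non-uniform or non-increasing time grid for fly {self.fly_id}")

    @property
    def dt(self) -> float:
        if len(self.t) < 2:
            raise FormatError("trace too short to define a sampling interval")
        return float(self.t[1] - self.t[0])

    @property
    def duration_s(self) -> float:
        return float(len(self.t) * self.dt)


@dataclass(frozen=True)
class StimulusEvent:
    stim_id: int
    onset_s: float
    light_on: bool = False


@dataclass
class StimulusSchedule:
    """Vibration-train onsets plus red-light intervals for a cohort."""

    events: list[StimulusEvent]
    light_windows: list[tuple[float, float]] = field(default_factory=list)
    train: dict = field(default_factory=lambda: dict(VIBRATION_TRAIN))

    def __post_init__(self) -> None:
        onsets = [e.onset_s for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise FormatError("stimulus onsets must be strictly increasing")

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset_s for e in self.events], dtype=float)


@dataclass
class LightAnnotation:
    """Optogenetic stimulation annotation for an electrophysiology trace."""

    mode: Literal["constant", "pulsed_1hz_5ms", "none"]
    onset_s: float = 0.0
    duration_s: float = 0.0
    pulse_onsets_s: np.ndarray | None = None   # for pulsed mode

    def __post_init__(self) -> None:
        if self.pulse_onsets_s is not None:
            self.pulse_onsets_s = np.asarray(self.pulse_onsets_s, dtype=float)


@dataclass
class VmTrace:
    """Whole-cell membrane potential recording (current clamp), mV at ``fs`` Hz."""

    fs: float
    vm: np.ndarray
    light: LightAnnotation
    holding_current_pa: float | None = None

    def __post_init__(self) -> None:
        self.vm = np.asarray(self.vm, dtype=float)
        if self.fs <= 0:
            raise FormatError("fs must be positive")
        if self.light.mode != "none":
            if self.light.onset_s + self.light.duration_s > self.duration_s + 1e-9:
                raise FormatError("light annotation extends past end of trace")

    @property
    def duration_s(self) -> float:
        return len(self.vm) / self.fs

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.vm)) / self.fs


@dataclass
class LFPTrace:
    """Extracellular local field potential, recording units at ``fs`` Hz."""

    fs: float
    signal: np.ndarray
    light: LightAnnotation

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise FormatError("fs must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.signal) / self.fs

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.signal)) / self.fs
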