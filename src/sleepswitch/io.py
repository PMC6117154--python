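"""Readers and writers for the package's on-disk formats.

Tracking data travel as tidy CSV (fly_id, t_s, x_mm), stimulus schedules as
CSV (stim_id, onset_s, light_on), light windows as CSV (start_s, end_s,
mode).  Electrophysiology traces use HDF5 (datasets ``signal`` and ``fs``,
light annotations as attributes) or two-column CSV (t_s, value).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError
from .traces import (ActivityTrace, LFPTrace, LightAnnotation, StimulusEvent,
                     StimulusSchedule, VmTrace)


def write_tracking_csv(path, traces: list[ActivityTrace]) -> None:
    frames = [
        pd.DataFrame({"fly_id": tr.fly_id, "t_s": tr.t, "x_mm": tr.x})
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tracking_csv(path) -> list[ActivityTrace]:
    df = pd.read_csv(path)
    for col in ("fly_id", "t_s", "x_mm"):
        if col not in df.columns:
            raise FormatError(f"tracking CSV missing column {col!r}")
    return [
        ActivityTrace(fly_id=str(fid), t=g["t_s"].to_numpy(), x=g["x_mm"].to_numpy())
        for fid, g in df.groupby("fly_id", sort=True)
    ]


def write_stimulus_csv(path, schedule: StimulusSchedule) -> None:
    pd.DataFrame({
        "stim_id": [e.stim_id for e in schedule.events],
        "onset_s": [e.onset_s for e in schedule.events],
        "light_on": [int(e.light_on) for e in schedule.events],
    }).to_csv(path, index=False)


def read_stimulus_csv(path) -> StimulusSchedule:
    df = pd.read_csv(path)
    events = [
        StimulusEvent(stim_id=int(r.stim_id), onset_s=float(r.onset_s),
                      light_on=bool(r.light_on))
        for r in df.itertuples()
    ]
    return StimulusSchedule(events=events)


def write_light_csv(path, windows: list[tuple[float, float]], mode: str = "constant") -> None:
    pd.DataFrame({
        "start_s": [a for a, _ in windows],
        "end_s": [b for _, b in windows],
        "mode": mode,
    }).to_csv(path, index=False)


# --- electrophysiology -----------------------------------------------------

def write_ephys_h5(path, trace) -> None:
    """Write a VmTrace or LFPTrace to HDF5."""
    sig = trace.vm if isinstance(trace, VmTrace) else trace.signal
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=sig)
        f.create_dataset("fs", data=float(trace.fs))
        ann = f.create_group("annotations")
        ann.attrs["mode"] = trace.light.mode
        ann.attrs["onset_s"] = trace.light.onset_s
        ann.attrs["duration_s"] = trace.light.duration_s
        if trace.light.pulse_onsets_s is not None:
            ann.create_dataset("pulse_onsets_s", data=trace.light.pulse_onsets_s)


def _read_annotation(f) -> LightAnnotation:
    ann = f["annotations"]
    pulses = ann["pulse_onsets_s"][()] if "pulse_onsets_s" in ann else None
    return LightAnnotation(mode=str(ann.attrs["mode"]),
                           onset_s=float(ann.attrs["onset_s"]),
                           duration_s=float(ann.attrs["duration_s"]),
                           pulse_onsets_s=pulses)


def read_vm_h5(path) -> VmTrace:
    with h5py.File(path, "r") as f:
        return VmTrace(fs=float(f["fs"][()]), vm=f["signal"][()],
                       light=_read_annotation(f))


def read_lfp_h5(path) -> LFPTrace:
    with h5py.File(path, "r") as f:
        return LFPTrace(fs=float(f["fs"][()]), signal=f["signal"][()],
                        light=_read_annotation(f))


def write_trace_csv(path, trace) -> None:
    """Two-column CSV (t_s, value); annotations are NOT preserved."""
    sig = trace.vm if isinstance(trace, VmTrace) else trace.signal
    pd.DataFrame({"t_s": np.arange(len(sig)) / trace.fs, "value": sig}).to_csv(
        path, index=False)
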