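"""Whole-cell membrane-potential analysis: spike detection, cell-class
assignment, and light-evoked depolarization summaries.

Conventions: responses are reported as changes in membrane potential (dVm)
relative to the pre-stimulus baseline rather than absolute values, because
somatic recordings from these unipolar cells overestimate and blur the true
resting potential.  Window means are taken over the raw trace (spike
waveforms are not excised).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import ConfigurationError, InsufficientDataError
from .traces import VmTrace

#: Spike-detection defaults: dV/dt threshold (mV/ms), peak prominence (mV),
#: refractory period (ms).  Declared package defaults; tune per rig.
DVDT_THRESHOLD_MV_MS = 10.0
MIN_PROMINENCE_MV = 5.0
REFRACTORY_MS = 2.0

#: A burst "fails to return to rest": the inter-peak minimum must stay this
#: many mV above the resting potential for two spikes to share a volley.
BURST_RETURN_TOLERANCE_MV = 2.0


@dataclass(frozen=True)
class SpikeEvent:
    peak_time_s: float
    peak_vm_mv: float
    trough_after_mv: float
    burst_id: int | None = None


def detect_spikes(
    trace: VmTrace,
    threshold_dvdt: float = DVDT_THRESHOLD_MV_MS,
    min_prominence: float = MIN_PROMINENCE_MV,
    refractory_ms: float = REFRACTORY_MS,
) -> list[SpikeEvent]:
    """Detect action potentials: dV/dt must exceed ``threshold_dvdt`` within
    1 ms before a local maximum of prominence >= ``min_prominence``; peaks
    closer than the refractory period collapse to the more prominent one."""
    if trace.fs < 1000:
        raise ConfigurationError("sampling rate below 1 kHz cannot resolve spikes")
    fs = trace.fs
    vm = trace.vm
    dvdt = np.diff(vm) * fs / 1000.0  # mV/ms
    distance = max(1, int(round(refractory_ms * fs / 1000.0)))
    peaks, props = find_peaks(vm, prominence=min_prominence, distance=distance)
    pre = max(1, int(round(fs / 1000.0)))  # 1 ms look-back for the upstroke
    events = []
    for i, p in enumerate(peaks):
        lo = max(0, p - pre)
        upstroke = float(np.max(dvdt[lo:p])) if p > lo else 0.0
        if upstroke < threshold_dvdt:
            continue
        nxt = peaks[i + 1] if i + 1 < len(peaks) else len(vm)
        trough = float(np.min(vm[p:nxt])) if nxt > p else float(vm[p])
        events.append(SpikeEvent(float(p / fs), float(vm[p]), trough))
    return events


def estimate_resting_vm(trace: VmTrace, spikes: Sequence[SpikeEvent] | None = None,
                        window_s: float = 60.0) -> float:
    """Median Vm over the pre-light baseline (or the first ``window_s``),
    with +/-5 ms around spike peaks removed — robust to spontaneous firing."""
    fs = trace.fs
    end = trace.light.onset_s if trace.light.mode != "none" else window_s
    end = min(end, trace.duration_s)
    i1 = int(round(end * fs))
    mask = np.ones(i1, dtype=bool)
    if spikes is None:
        spikes = detect_spikes(trace)
    half = int(round(0.005 * fs))
    for sp in spikes:
        p = int(round(sp.peak_time_s * fs))
        if p - half < i1:
            mask[max(0, p - half): min(i1, p + half + 1)] = False
    base = trace.vm[:i1][mask]
    if base.size == 0:
        base = trace.vm[:i1]
    return float(np.median(base))


def group_bursts(
    trace: VmTrace,
    spikes: Sequence[SpikeEvent],
    resting_vm: float,
    tolerance_mv: float = BURST_RETURN_TOLERANCE_MV,
) -> list[SpikeEvent]:
    """Assign burst ids: consecutive spikes whose inter-peak Vm minimum stays
    above ``resting_vm + tolerance`` belong to the same volley."""
    fs = trace.fs
    out: list[SpikeEvent] = []
    burst_id = -1
    new_group = True
    for i, sp in enumerate(spikes):
        if new_group:
            burst_id += 1
        out.append(SpikeEvent(sp.peak_time_s, sp.peak_vm_mv, sp.trough_after_mv, burst_id))
        if i + 1 < len(spikes):
            a = int(round(sp.peak_time_s * fs))
            b = int(round(spikes[i + 1].peak_time_s * fs))
            inter_min = float(np.min(trace.vm[a:b + 1]))
            new_group = inter_min <= resting_vm + tolerance_mv
        else:
            new_group = True
    return out


@dataclass
class StepProtocolResult:
    """Depolarizing current-step record: +10 pA steps up to +150 pA."""

    currents_pa: np.ndarray
    spike_counts: np.ndarray

    def __post_init__(self) -> None:
        self.currents_pa = np.asarray(self.currents_pa, dtype=float)
        self.spike_counts = np.asarray(self.spike_counts, dtype=int)
        if self.currents_pa.shape != self.spike_counts.shape:
            raise ConfigurationError("step currents and counts must align")


CellLabel = Literal["non_spiking", "burst", "single_and_burst", "single", "indeterminate"]


@dataclass
class CellClassification:
    label: CellLabel
    n_single: int
    n_burst: int
    step_protocol: StepProtocolResult | None = None
    flagged: bool = False


def classify_cell(
    trace: VmTrace,
    spikes: Sequence[SpikeEvent] | None = None,
    step_protocol: StepProtocolResult | None = None,
    resting_vm: float | None = None,
    tolerance_mv: float = BURST_RETURN_TOLERANCE_MV,
) -> CellClassification:
    """Assign the firing-pattern label.

    Volleys of >=2 spikes whose inter-peak Vm fails to return to rest are
    bursts; cells with bursts only -> ``burst``, bursts and isolated spikes
    -> ``single_and_burst``, isolated spikes only -> ``single``.  A cell with
    no spikes is ``non_spiking`` only if it also stayed silent through the
    depolarizing step protocol; without that record the label is
    ``indeterminate`` (flagged).
    """
    if spikes is None:
        spikes = detect_spikes(trace)
    if resting_vm is None:
        resting_vm = estimate_resting_vm(trace, spikes)
    if trace.light.mode != "none":
        # light-evoked depolarization holds Vm above rest and would make any
        # firing look burst-like; classify on spontaneous spikes only
        on = trace.light.onset_s
        off = on + trace.light.duration_s + 10.0  # allow the decay to settle
        spikes = [s for s in spikes if not on <= s.peak_time_s < off]
    grouped = group_bursts(trace, spikes, resting_vm, tolerance_mv)
    sizes: dict[int, int] = {}
    for sp in grouped:
        sizes[sp.burst_id] = sizes.get(sp.burst_id, 0) + 1
    n_single = sum(1 for v in sizes.values() if v == 1)
    n_burst = sum(1 for v in sizes.values() if v >= 2)
    if not grouped:
        if step_protocol is None:
            return CellClassification("indeterminate", 0, 0, None, flagged=True)
        if int(step_protocol.spike_counts.sum()) == 0:
            return CellClassification("non_spiking", 0, 0, step_protocol)
        # spiked under current injection but not spontaneously
        return CellClassification("single", 0, 0, step_protocol)
    if n_burst and not n_single:
        label: CellLabel = "burst"
    elif n_burst and n_single:
        label = "single_and_burst"
    else:
        label = "single"
    return CellClassification(label, n_single, n_burst, step_protocol)


@dataclass
class VmResponseSummary:
    """Windowed-mean dVm summary for the constant-light regime."""

    pre_mean_mv: float
    stim_mean_mv: float
    post_mean_mv: float          # NaN when post-light data insufficient
    dvm_stim_mv: float
    dvm_post_mv: float
    regime: Literal["constant", "pulsed"] = "constant"


def vm_response_constant(trace: VmTrace, baseline_s: float = 60.0) -> VmResponseSummary:
    """dVm under constant light.

    pre = mean over the ``baseline_s`` before light onset; stim = mean over
    the first 60 s of light; post = mean over the final 60 s of the trace
    provided that window starts at or after light offset.  Spike samples are
    not excised.  With insufficient post-light data the post fields are NaN
    but dVm_stim is still reported.
    """
    if trace.light.mode != "constant":
        raise ConfigurationError("vm_response_constant requires a constant-light annotation")
    fs = trace.fs
    on = trace.light.onset_s
    off = on + trace.light.duration_s
    i_on, i_off = int(round(on * fs)), int(round(off * fs))
    i_pre = int(round((on - baseline_s) * fs))
    if i_pre < 0:
        raise InsufficientDataError("baseline window precedes trace start")
    pre = float(np.mean(trace.vm[i_pre:i_on]))
    stim = float(np.mean(trace.vm[i_on: i_on + int(round(60.0 * fs))]))
    n = len(trace.vm)
    post_start = n - int(round(60.0 * fs))
    if post_start >= i_off and post_start >= 0:
        post = float(np.mean(trace.vm[post_start:]))
    else:
        post = float("nan")
    return VmResponseSummary(
        pre_mean_mv=pre, stim_mean_mv=stim, post_mean_mv=post,
        dvm_stim_mv=stim - pre, dvm_post_mv=post - pre, regime="constant",
    )


@dataclass
class PulseCompositeVm:
    """Average over the 1-s epochs following each light pulse."""

    composite_mv: np.ndarray      # length = 1 s * fs
    n_pulses: int
    first100ms_mean_mv: float
    pre_mean_mv: float            # 60 s baseline before light onset
    dvm_mv: float                 # first100ms_mean - pre_mean


def composite_pulse_vm(trace: VmTrace, epoch_s: float = 1.0,
                       baseline_s: float = 60.0) -> PulseCompositeVm:
    """Pointwise average of the 1-s epochs aligned to each pulse onset, and
    the mean of that composite over its first 100 ms."""
    if trace.light.mode != "pulsed_1hz_5ms" or trace.light.pulse_onsets_s is None:
        raise ConfigurationError("composite_pulse_vm requires a pulsed-light annotation")
    fs = trace.fs
    n_epoch = int(round(epoch_s * fs))
    epochs = []
    for onset in trace.light.pulse_onsets_s:
        i0 = int(round(onset * fs))
        if i0 + n_epoch <= len(trace.vm):
            epochs.append(trace.vm[i0: i0 + n_epoch])
    if len(epochs) < 2:
        raise InsufficientDataError("need at least 2 complete pulse epochs")
    composite = np.mean(np.asarray(epochs), axis=0)
    first100 = float(np.mean(composite[: int(round(0.1 * fs))]))
    i_on = int(round(trace.light.onset_s * fs))
    i_pre = max(0, i_on - int(round(baseline_s * fs)))
    pre = float(np.mean(trace.vm[i_pre:i_on]))
    return PulseCompositeVm(
        composite_mv=composite, n_pulses=len(epochs),
        first100ms_mean_mv=first100, pre_mean_mv=pre, dvm_mv=first100 - pre,
    )


@dataclass
class SecondarySpikeSummary:
    per_pulse_counts: np.ndarray   # secondary-spike counts, evoked pulses only
    n_evoked_pulses: int
    reliability: float             # fraction of evoked pulses with >=1 secondary


def detect_secondary_spikes(
    trace: VmTrace,
    spikes: Sequence[SpikeEvent] | None = None,
    window_s: tuple[float, float] = (0.1, 0.5),
    evoked_within_s: float = 0.05,
) -> SecondarySpikeSummary:
    """Per-pulse secondary-spike counts.

    A pulse is "evoked" when its first spike falls within 50 ms of the pulse
    onset; secondary spikes are additional spikes 100-500 ms after that first
    evoked spike.  Reliability = fraction of evoked pulses with at least one
    secondary spike; missing (NaN) when no pulse evoked a spike.
    """
    if trace.light.pulse_onsets_s is None:
        raise ConfigurationError("pulse onsets required")
    if spikes is None:
        spikes = detect_spikes(trace)
    times = np.array([s.peak_time_s for s in spikes])
    counts = []
    for onset in trace.light.pulse_onsets_s:
        in_evoke = times[(times >= onset) & (times <= onset + evoked_within_s)]
        if in_evoke.size == 0:
            continue
        first = in_evoke[0]
        lo, hi = first + window_s[0], first + window_s[1]
        counts.append(int(np.sum((times >= lo) & (times <= hi))))
    counts = np.asarray(counts, dtype=int)
    reliability = float(np.mean(counts >= 1)) if counts.size else float("nan")
    return SecondarySpikeSummary(counts, int(counts.size), reliability)


def burst_isi_ms(volley_spikes: Sequence[SpikeEvent]) -> float:
    """Interspike interval of a volley: time between its first and second
    peaks, in ms.  Missing (NaN) with fewer than two spikes."""
    if len(volley_spikes) < 2:
        return float("nan")
    times = sorted(s.peak_time_s for s in volley_spikes)
    return (times[1] - times[0]) * 1000.0
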