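"""Sleep and behavioral-responsiveness metrics from locomotor tracking.

The pipeline mirrors the standard fly arousal-tracking analysis:

* sleep = maximal immobility runs lasting at least 5 minutes;
* responsiveness = stimulus-locked mean speed (2 min pre, 15 min post a
  vibration train) fitted with a single-inactivation exponential,
  ``B + A (1 - e^{-t/tau_r}) e^{-t/tau_d}``, whose analytic peak above
  baseline is the "mean peak responsiveness";
* a fly responded to a stimulus if it travelled at least 3 mm (cumulative
  path length) in the minute after the train onset;
* sleep intensity = fraction of immobile (sleeping) flies that responded,
  optionally binned by how long the fly had been immobile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ContractError, EmptySelectionError, FormatError
from .traces import ActivityTrace, StimulusSchedule

#: Immobility threshold: speeds at or below this (mm/s at the native frame
#: rate) count as "not moving".  Tracking rigs rarely document a movement
#: floor; the default sits at the tracking-noise scale.
IMMOBILITY_EPS_MM_S = 0.5

#: Minimum immobility run counting as sleep (the 5-minute criterion).
MIN_BOUT_S = 300.0

#: Responder displacement threshold (~3 body lengths) and window.
RESPONDER_THRESHOLD_MM = 3.0
RESPONDER_WINDOW_S = 60.0

#: Stimulus-locked averaging window: 2 min pre, 15 min post.
PRE_WINDOW_S = 120.0
POST_WINDOW_S = 900.0


# ---------------------------------------------------------------------------
# speed and sleep
# ---------------------------------------------------------------------------

def compute_speed(trace: ActivityTrace) -> ActivityTrace:
    """Attach the speed series: ``speed[i] = |x[i]-x[i-1]|/dt``, speed[0]=0."""
    if len(trace.t) < 2:
        raise FormatError("need at least 2 samples to compute speed")
    dt = trace.dt
    speed = np.empty_like(trace.x)
    speed[0] = 0.0
    speed[1:] = np.abs(np.diff(trace.x)) / dt
    trace.speed = speed
    return trace


@dataclass(frozen=True)
class SleepBout:
    fly_id: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def detect_sleep_bouts(
    trace: ActivityTrace,
    immobility_eps: float = IMMOBILITY_EPS_MM_S,
    min_bout_s: float = MIN_BOUT_S,
) -> list[SleepBout]:
    """Maximal runs of immobility (speed <= eps) lasting >= ``min_bout_s``.

    A run of k consecutive immobile frames spans ``k * dt`` seconds; the bout
    covers ``[t_first, t_last + dt)``.  Runs are maximal: extending either end
    would include a supra-threshold frame or fall off the trace.
    """
    if trace.speed is None:
        compute_speed(trace)
    if len(trace.t) == 0:
        raise FormatError("empty trace")
    dt = trace.dt
    quiet = trace.speed <= immobility_eps
    # run-length encode the boolean series
    edges = np.flatnonzero(np.diff(quiet.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges, len(quiet) - 1]
    durations = (ends - starts + 1) * dt
    keep = quiet[starts] & (durations >= min_bout_s)
    return [
        SleepBout(trace.fly_id, float(trace.t[s]), float(trace.t[e] + dt))
        for s, e in zip(starts[keep], ends[keep])
    ]


@dataclass
class SleepSummary:
    """Per-fly sleep, per clock hour and aggregated by day/night window."""

    fly_id: str
    hourly_min: pd.Series             # index = clock hour since start; NaN = fully excluded hour
    mean_bout_length_min: float
    day_min_per_hr: float
    night_min_per_hr: float


def _interval_overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def _included_sleep_in(
    win0: float, win1: float, bouts, exclusions
) -> tuple[float, float]:
    """(seconds asleep, seconds of assay time) inside [win0, win1) after
    removing exclusion windows from both numerator and denominator.

    ``bouts`` may be a list of SleepBout or a pair of (start, end) arrays;
    exclusions likewise a list of pairs or a pair of arrays.  Assumes
    non-overlapping bouts and non-overlapping exclusions.
    """
    if isinstance(bouts, tuple):
        b0, b1 = bouts
    else:
        b0 = np.array([b.start_s for b in bouts])
        b1 = np.array([b.end_s for b in bouts])
    if isinstance(exclusions, tuple):
        e0, e1 = exclusions
    else:
        e0 = np.array([a for a, _ in exclusions])
        e1 = np.array([b for _, b in exclusions])
    total = (win1 - win0) - float(
        np.sum(np.maximum(0.0, np.minimum(win1, e1) - np.maximum(win0, e0)))
    ) if e0.size else (win1 - win0)
    lo = np.maximum(win0, b0)
    hi = np.minimum(win1, b1)
    ov = np.maximum(0.0, hi - lo)
    asleep = float(np.sum(ov))
    if e0.size and ov.any():
        sel = ov > 0
        cut = np.maximum(
            0.0,
            np.minimum(hi[sel, None], e1[None, :]) - np.maximum(lo[sel, None], e0[None, :]),
        )
        asleep -= float(np.sum(cut))
    return asleep, total


def summarize_sleep(
    bouts: list[SleepBout],
    total_duration_s: float,
    exclusion_windows: list[tuple[float, float]] | None = None,
    day_window_zt: tuple[float, float] = (0.0, 12.0),
    fly_id: str | None = None,
) -> SleepSummary:
    """Per-clock-hour minutes asleep, with stimulus-response windows excluded.

    Bouts are split at hour boundaries.  Time inside exclusion windows is
    removed from both numerator and denominator and the hourly value rescaled
    to min/hr; an hour that is entirely excluded is reported missing (NaN),
    not zero.  Day/night aggregates assume the trace starts at ZT0 and a
    12:12 cycle.
    """
    exclusions = (
        np.array([a for a, _ in exclusion_windows]),
        np.array([b for _, b in exclusion_windows]),
    ) if exclusion_windows else (np.array([]), np.array([]))
    bout_arr = (np.array([b.start_s for b in bouts]), np.array([b.end_s for b in bouts]))
    fly = fly_id if fly_id is not None else (bouts[0].fly_id if bouts else "?")
    n_hours = int(math.ceil(total_duration_s / 3600.0 - 1e-9))
    hourly = np.full(n_hours, np.nan)
    for h in range(n_hours):
        h0, h1 = h * 3600.0, min((h + 1) * 3600.0, total_duration_s)
        asleep, included = _included_sleep_in(h0, h1, bout_arr, exclusions)
        if included > 1e-9:
            hourly[h] = 60.0 * asleep / included

    def window_rate(zt0: float, zt1: float) -> float:
        num = den = 0.0
        n_days = int(math.ceil(total_duration_s / 86400.0))
        for d in range(n_days):
            w0, w1 = d * 86400.0 + zt0 * 3600.0, d * 86400.0 + zt1 * 3600.0
            w1 = min(w1, total_duration_s)
            if w1 <= w0:
                continue
            a, inc = _included_sleep_in(w0, w1, bout_arr, exclusions)
            num += a
            den += inc
        return 60.0 * num / den if den > 1e-9 else float("nan")

    zt0, zt1 = day_window_zt
    durations = [b.duration_s for b in bouts]
    return SleepSummary(
        fly_id=fly,
        hourly_min=pd.Series(hourly, index=pd.RangeIndex(n_hours, name="hour")),
        mean_bout_length_min=float(np.mean(durations) / 60.0) if durations else 0.0,
        day_min_per_hr=window_rate(zt0, zt1),
        night_min_per_hr=window_rate(zt1, 24.0),
    )


def stimulus_exclusion_windows(
    schedule: StimulusSchedule, post_s: float = POST_WINDOW_S
) -> list[tuple[float, float]]:
    """Response-analysis windows ``[onset, onset + post_s]`` — the epochs
    removed from sleep averaging ("unstimulated epochs" convention)."""
    return [(float(o), float(o) + post_s) for o in schedule.onsets]


# ---------------------------------------------------------------------------
# stimulus-locked responsiveness
# ---------------------------------------------------------------------------

@dataclass
class ResponseCurve:
    """Mean speed across flies x trials aligned to stimulus onset."""

    rel_t: np.ndarray     # seconds relative to onset, uniform grid
    mean_speed: np.ndarray
    n: int                # contributing (fly, trial) pairs

    def __post_init__(self) -> None:
        if self.n < 1:
            raise EmptySelectionError("a response curve needs at least one trial")


def _aligned_window(trace: ActivityTrace, onset: float, pre: float, post: float):
    """Index range of [onset - pre, onset + post] on the trace grid, or None
    if the window is truncated by a trace edge."""
    dt = trace.dt
    i_on = int(round((onset - trace.t[0]) / dt))
    i0 = i_on - int(round(pre / dt))
    i1 = i_on + int(round(post / dt))
    if i0 < 0 or i1 >= len(trace.t):
        return None
    return i0, i_on, i1


def stimulus_locked_mean(
    traces: list[ActivityTrace],
    schedule: StimulusSchedule,
    pre_s: float = PRE_WINDOW_S,
    post_s: float = POST_WINDOW_S,
    trial_filter=None,
) -> ResponseCurve:
    """Mean speed over flies x trials aligned to each train onset.

    ``trial_filter(trace, event) -> bool`` may restrict to light-on/off
    trials or awake/immobile flies.  Trials truncated by trace edges are
    dropped, not padded.
    """
    if not traces:
        raise EmptySelectionError("no traces supplied")
    dt = traces[0].dt
    n_pts = int(round(pre_s / dt)) + int(round(post_s / dt)) + 1
    acc = np.zeros(n_pts)
    n = 0
    for trace in traces:
        if trace.speed is None:
            compute_speed(trace)
        for ev in schedule.events:
            if trial_filter is not None and not trial_filter(trace, ev):
                continue
            idx = _aligned_window(trace, ev.onset_s, pre_s, post_s)
            if idx is None:
                continue
            i0, _, i1 = idx
            acc += trace.speed[i0 : i1 + 1]
            n += 1
    if n == 0:
        raise EmptySelectionError("no trials left after filtering")
    rel_t = (np.arange(n_pts) - int(round(pre_s / dt))) * dt
    return ResponseCurve(rel_t=rel_t, mean_speed=acc / n, n=n)


def response_kernel(t, amplitude, rise_tau, decay_tau):
    """Single-inactivation exponential, zero for t < 0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = amplitude * (1.0 - np.exp(-t[pos] / rise_tau)) * np.exp(-t[pos] / decay_tau)
    return out


def _kernel_jac(t, amplitude, rise_tau, decay_tau):
    t = np.asarray(t, dtype=float)
    J = np.zeros((len(t), 3))
    pos = t >= 0
    tp = t[pos]
    er = np.exp(-tp / rise_tau)
    ed = np.exp(-tp / decay_tau)
    J[pos, 0] = (1.0 - er) * ed
    J[pos, 1] = -amplitude * (tp / rise_tau ** 2) * er * ed
    J[pos, 2] = amplitude * (1.0 - er) * (tp / decay_tau ** 2) * ed
    return J


def kernel_peak(amplitude: float, rise_tau: float, decay_tau: float) -> float:
    """Analytic maximum of the single-inactivation exponential above baseline,
    attained at ``t* = tau_r ln(1 + tau_d/tau_r)``."""
    t_star = rise_tau * math.log(1.0 + decay_tau / rise_tau)
    return amplitude * (1.0 - math.exp(-t_star / rise_tau)) * math.exp(-t_star / decay_tau)


@dataclass
class ResponseFit:
    baseline: float          # B, mm/s (pre-window mean)
    amplitude: float         # A, mm/s
    rise_tau: float          # s
    decay_tau: float         # s
    t0: float                # s, onset (fixed at 0 relative to the train onset)
    peak_mm_s: float         # fitted maximum above B ("mean peak responsiveness")
    converged: bool = True
    clipped: bool = False


def fit_response_peak(
    curve: ResponseCurve,
    p0: tuple[float, float, float] | None = None,
) -> ResponseFit:
    """Least-squares fit of ``B + A (1-e^{-t/tau_r}) e^{-t/tau_d}`` for t >= 0.

    B is the pre-window mean (not a free parameter); the peak is evaluated
    analytically at ``t* = tau_r ln(1 + tau_d/tau_r)`` and reported above
    baseline.  On non-convergence the peak falls back to
    ``max(smoothed post curve) - B`` with ``converged=False``; a negative
    fitted amplitude is clipped to zero with ``clipped=True``.
    """
    pre = curve.rel_t < 0
    post = curve.rel_t >= 0
    if not pre.any() or not post.any():
        raise FormatError("curve must cover both pre- and post-stimulus windows")
    baseline = float(np.mean(curve.mean_speed[pre]))
    t_post = curve.rel_t[post]
    y_post = curve.mean_speed[post] - baseline

    if p0 is None:
        a0 = max(float(np.max(y_post)), 1e-3)
        p0 = (a0 / 0.8, 2.0, 60.0)
    try:
        popt, _ = curve_fit(
            response_kernel,
            t_post,
            y_post,
            p0=p0,
            bounds=([-np.inf, 1e-3, 1e-2], [np.inf, 300.0, 3000.0]),
            jac=_kernel_jac,
            maxfev=5000,
        )
        amp, rise, decay = (float(v) for v in popt)
        converged = True
    except RuntimeError:
        amp, rise, decay = float("nan"), float("nan"), float("nan")
        converged = False

    clipped = False
    if converged and amp < 0:
        amp, clipped = 0.0, True
    if converged:
        peak = kernel_peak(amp, rise, decay) if amp > 0 else 0.0
    else:
        width = max(1, int(round(5.0 / (curve.rel_t[1] - curve.rel_t[0]))))
        smoothed = np.convolve(y_post, np.ones(width) / width, mode="same")
        peak = max(float(np.max(smoothed)), 0.0)
    return ResponseFit(
        baseline=baseline, amplitude=amp, rise_tau=rise, decay_tau=decay,
        t0=0.0, peak_mm_s=float(peak), converged=converged, clipped=clipped,
    )


# ---------------------------------------------------------------------------
# responder calls and sleep intensity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponderCall:
    fly_id: str
    stim_id: int
    immobile_at_stim: bool
    moved_prior_min: bool
    displacement_mm: float       # cumulative path length over (onset, onset+60 s]
    responder: bool
    immobility_duration_s: float = float("nan")  # time immobile before onset
    light_on: bool = False


def call_responder(
    trace: ActivityTrace,
    onset_s: float,
    stim_id: int = 0,
    threshold_mm: float = RESPONDER_THRESHOLD_MM,
    window_s: float = RESPONDER_WINDOW_S,
    immobility_eps: float = IMMOBILITY_EPS_MM_S,
    light_on: bool = False,
) -> ResponderCall | None:
    """Classify one (fly, stimulus) trial.

    Displacement is the cumulative path length over the minute after onset;
    the fly responded if it reaches 3 mm.  ``immobile_at_stim`` means no
    supra-threshold movement in the minute before onset.
    ``immobility_duration_s`` is the time since the last supra-threshold
    frame before onset (capped at the trace start).  Returns None when the
    pre or post window is truncated by a trace edge (call excluded).
    """
    if trace.speed is None:
        compute_speed(trace)
    idx = _aligned_window(trace, onset_s, window_s, window_s)
    if idx is None:
        return None
    i0, i_on, i1 = idx
    dt = trace.dt
    # path length over (onset, onset+window]: speed[i] covers movement in
    # (t[i-1], t[i]], so frames i_on+1 .. i1 lie inside the window
    displacement = float(np.sum(trace.speed[i_on + 1 : i1 + 1]) * dt)
    pre_speeds = trace.speed[i0 + 1 : i_on + 1]
    immobile = bool(np.all(pre_speeds <= immobility_eps))
    moving = trace.speed[1 : i_on + 1] > immobility_eps
    supra = np.flatnonzero(moving)
    if supra.size:
        last_move_t = trace.t[supra[-1] + 1]
        immobility_dur = float(onset_s - last_move_t)
    else:
        immobility_dur = float(onset_s - trace.t[0])
    return ResponderCall(
        fly_id=trace.fly_id,
        stim_id=stim_id,
        immobile_at_stim=immobile,
        moved_prior_min=not immobile,
        displacement_mm=displacement,
        responder=displacement >= threshold_mm,
        immobility_duration_s=immobility_dur,
        light_on=light_on,
    )


def call_responders(
    traces: list[ActivityTrace], schedule: StimulusSchedule, **kwargs
) -> list[ResponderCall]:
    """All (fly, stimulus) responder calls; truncated trials are skipped."""
    calls = []
    for trace in traces:
        for ev in schedule.events:
            c = call_responder(trace, ev.onset_s, stim_id=ev.stim_id,
                               light_on=ev.light_on, **kwargs)
            if c is not None:
                calls.append(c)
    return calls


def sleep_intensity(calls: list[ResponderCall]) -> float:
    """Fraction of immobile (sleeping) flies that responded to the stimulus.

    Missing (NaN) when no immobile calls exist; raises if awake calls are
    mixed in (the caller must pre-filter to immobile trials).
    """
    if any(not c.immobile_at_stim for c in calls):
        raise ContractError("sleep_intensity expects immobile-at-stimulus calls only")
    if not calls:
        return float("nan")
    return sum(c.responder for c in calls) / len(calls)


#: Inactivity bins (minutes) used for sleep intensity as a function of prior
#: immobility: [0,5), [5,10), ..., [25,30), plus a ">=30" overflow bin.
INACTIVITY_BIN_EDGES_MIN = np.arange(0.0, 35.0, 5.0)
OVERFLOW_BIN = "30+"


def intensity_by_inactivity_bin(calls: list[ResponderCall]) -> pd.DataFrame:
    """Response fraction per 5-min prior-immobility bin (first 30 min).

    Bins are half-open ``[lo, hi)``; immobility >= 30 min falls in the
    overflow bin, reported separately.  Only immobile-at-stimulus calls are
    considered.
    """
    rows = []
    imm = [c for c in calls if c.immobile_at_stim]
    edges = INACTIVITY_BIN_EDGES_MIN
    labels = [f"[{int(lo)},{int(hi)})" for lo, hi in zip(edges[:-1], edges[1:])]
    for lo, hi, lab in zip(edges[:-1], edges[1:], labels):
        sel = [c for c in imm if lo * 60.0 <= c.immobility_duration_s < hi * 60.0]
        rows.append({
            "bin": lab, "bin_lo_min": lo, "n": len(sel),
            "fraction_responding": (sum(c.responder for c in sel) / len(sel)) if sel else float("nan"),
        })
    over = [c for c in imm if c.immobility_duration_s >= edges[-1] * 60.0]
    rows.append({
        "bin": OVERFLOW_BIN, "bin_lo_min": edges[-1], "n": len(over),
        "fraction_responding": (sum(c.responder for c in over) / len(over)) if over else float("nan"),
    })
    return pd.DataFrame(rows)


def awake_trial_filter(immobility_eps: float = IMMOBILITY_EPS_MM_S,
                       window_s: float = RESPONDER_WINDOW_S):
    """Trial filter keeping (fly, stimulus) pairs where the fly moved within
    the minute before the stimulus (i.e. was awake)."""

    def _filter(trace: ActivityTrace, ev) -> bool:
        call = call_responder(trace, ev.onset_s, stim_id=ev.stim_id,
                              immobility_eps=immobility_eps, window_s=window_s)
        return call is not None and call.moved_prior_min

    return _filter


def awake_peak_responsiveness(
    traces: list[ActivityTrace], schedule: StimulusSchedule, **fit_kwargs
) -> ResponseFit:
    """Peak responsiveness restricted to awake trials: stimulus-locked mean
    over trials where the fly moved in the prior minute, then the peak fit."""
    curve = stimulus_locked_mean(traces, schedule, trial_filter=awake_trial_filter())
    return fit_response_peak(curve, **fit_kwargs)
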