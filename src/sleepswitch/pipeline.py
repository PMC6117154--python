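"""End-to-end behavioral pipeline: cohort traces -> per-fly arousal table.

This is the composition the correlation analysis runs on: per fly, day and
night sleep duration (min/hr, response windows excluded) and day and night
peak responsiveness (fit of the fly's own stimulus-locked mean curve).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import behavior
from .errors import EmptySelectionError
from .traces import ActivityTrace, StimulusSchedule


def _window_of(onset_s: float, day_window_zt: tuple[float, float]) -> str:
    zt = (onset_s / 3600.0) % 24.0
    return "day" if day_window_zt[0] <= zt < day_window_zt[1] else "night"


def per_fly_peak(trace: ActivityTrace, schedule: StimulusSchedule,
                 window: str, day_window_zt=(0.0, 12.0)) -> float:
    """Peak responsiveness of one fly over its day or night trials; NaN when
    no usable trial or the fit window is truncated."""
    sub = [e for e in schedule.events if _window_of(e.onset_s, day_window_zt) == window]
    if not sub:
        return float("nan")
    try:
        curve = behavior.stimulus_locked_mean([trace], StimulusSchedule(events=sub))
    except EmptySelectionError:
        return float("nan")
    fit = behavior.fit_response_peak(curve)
    return fit.peak_mm_s


def per_fly_arousal_table(
    traces: list[ActivityTrace],
    schedule: StimulusSchedule,
    day_window_zt: tuple[float, float] = (0.0, 12.0),
) -> pd.DataFrame:
    """Per-fly day/night sleep (min/hr) and peak responsiveness (mm/s).

    Sleep averaging excludes the 15-min response window after every
    stimulus ("unstimulated epochs"); responsiveness is the analytic peak
    of the single-inactivation exponential fitted to the fly's mean
    stimulus-locked speed, separately for day and night trials.
    """
    exclusions = behavior.stimulus_exclusion_windows(schedule)
    rows = []
    for trace in traces:
        behavior.compute_speed(trace)
        bouts = behavior.detect_sleep_bouts(trace)
        summary = behavior.summarize_sleep(
            bouts, trace.duration_s, exclusion_windows=exclusions,
            day_window_zt=day_window_zt, fly_id=trace.fly_id)
        rows.append({
            "fly_id": trace.fly_id,
            "day_sleep_min_hr": summary.day_min_per_hr,
            "night_sleep_min_hr": summary.night_min_per_hr,
            "mean_bout_length_min": summary.mean_bout_length_min,
            "day_peak_mm_s": per_fly_peak(trace, schedule, "day", day_window_zt),
            "night_peak_mm_s": per_fly_peak(trace, schedule, "night", day_window_zt),
        })
    return pd.DataFrame(rows)
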