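#!/usr/bin/env python
"""Sleep and responsiveness analysis of the simulated cohorts.

Regenerates the full-scale cohorts recorded by 01_simulate_cohorts.py,
computes per-fly sleep (min/hr) and peak responsiveness (mm/s) for day and
night, the day/night sleep-vs-responsiveness correlations, sleep intensity
by prior-immobility bin, and writes tidy tables, statistics and figures to
results/behavior/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from sleepswitch import behavior, report
from sleepswitch.pipeline import per_fly_arousal_table
from sleepswitch.stats import correlate_sleep_vs_responsiveness
from sleepswitch.synth import CohortConfig, simulate_cohort

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "behavior"


def analyze(name: str, cfg: CohortConfig):
    traces, sched, gt = simulate_cohort(cfg)
    tab = per_fly_arousal_table(traces, sched)
    rd = correlate_sleep_vs_responsiveness(tab.day_sleep_min_hr, tab.day_peak_mm_s, "day")
    rn = correlate_sleep_vs_responsiveness(tab.night_sleep_min_hr, tab.night_peak_mm_s, "night")
    calls = behavior.call_responders(traces, sched)
    imm = [c for c in calls if c.immobile_at_stim]
    bins = behavior.intensity_by_inactivity_bin(imm)
    return tab, {"day": rd, "night": rn}, bins, float(behavior.sleep_intensity(imm))


def main() -> None:
    with open(ROOT / "cohorts" / "cohort_configs.json") as fh:
        configs = json.load(fh)

    tables, statistics, plots = {}, {}, {}
    for name in ("wildtype", "activated"):
        cfg = CohortConfig.from_dict(configs[name])
        tab, corrs, bins, intensity = analyze(name, cfg)
        tables[f"{name}_per_fly"] = tab
        tables[f"{name}_intensity_by_bin"] = bins
        for w, c in corrs.items():
            statistics[f"{name}_{w}_correlation"] = c
        print(f"{name}: n={len(tab)}  day R={corrs['day'].R:+.3f} (p={corrs['day'].p:.3g})  "
              f"night R={corrs['night'].R:+.3f} (p={corrs['night'].p:.3g})  "
              f"sleep intensity={intensity:.2f}")

        def scatter(ax, tab=tab, name=name):
            ax.scatter(tab.night_peak_mm_s, tab.night_sleep_min_hr, s=8, c="0.3",
                       label="night")
            ax.scatter(tab.day_peak_mm_s, tab.day_sleep_min_hr, s=8, c="goldenrod",
                       alpha=0.6, label="day")
            ax.set_xlabel("peak response speed (mm/s)")
            ax.set_ylabel("sleep duration (min/hr)")
            ax.set_title(name)
            ax.legend(frameon=False)

        plots[f"{name}_correlation.png"] = scatter

        def intensity_plot(ax, bins=bins, name=name):
            sel = bins[bins.bin != "30+"]
            ax.plot(sel.bin_lo_min + 2.5, sel.fraction_responding, "o-")
            ax.set_xlabel("prior immobility (min)")
            ax.set_ylabel("fraction responding")
            ax.set_ylim(0, 1)
            ax.set_title(f"{name}: sleep intensity by inactivity bin")

        plots[f"{name}_intensity_by_bin.png"] = intensity_plot

    out = report.build_report(OUT, tables, statistics, plots)
    print(f"wrote behavioral tables, statistics and figures to {out}")


if __name__ == "__main__":
    main()
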