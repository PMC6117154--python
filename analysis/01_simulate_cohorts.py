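#!/usr/bin/env python
"""Simulate the behavioral cohorts used throughout the analysis.

Writes a small demonstration cohort to tidy CSV (tracking, stimuli, light
schedule, ground truth) under results/cohorts/, and records the full-scale
cohort configurations (wildtype-like n=225 and activated-like n=51, three
recording days each) so the downstream scripts can regenerate them in
memory without shipping gigabytes of tracking data.
"""

import dataclasses
import json
from pathlib import Path

from sleepswitch import io
from sleepswitch.synth import (CohortConfig, activated_like_config,
                               simulate_cohort, wildtype_like_config)

OUT = Path(__file__).resolve().parents[1] / "results" / "cohorts"
SEED = 2026


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    demo_cfg = CohortConfig(n_flies=12, days=1, seed=SEED)
    traces, sched, gt = simulate_cohort(demo_cfg)
    io.write_tracking_csv(OUT / "demo_tracking.csv", traces)
    io.write_stimulus_csv(OUT / "demo_stimuli.csv", sched)
    io.write_light_csv(OUT / "demo_light.csv", sched.light_windows)
    gt.flies.to_csv(OUT / "demo_ground_truth_flies.csv", index=False)
    gt.stimuli.to_csv(OUT / "demo_ground_truth_stimuli.csv", index=False)

    configs = {
        "demo": dataclasses.asdict(demo_cfg),
        "wildtype": dataclasses.asdict(wildtype_like_config(seed=SEED)),
        "activated": dataclasses.asdict(activated_like_config(seed=SEED + 1)),
    }
    with open(OUT / "cohort_configs.json", "w") as fh:
        json.dump(configs, fh, indent=2)

    print(f"wrote demonstration cohort ({demo_cfg.n_flies} flies, "
          f"{len(sched.events)} stimuli) and cohort configs to {OUT}")
    print(f"planted: wildtype day R = {configs['wildtype']['planted_R_day']}, "
          f"night R = {configs['wildtype']['planted_R_night']}; "
          f"activated day R = {configs['activated']['planted_R_day']}, "
          f"night R = {configs['activated']['planted_R_night']}")


if __name__ == "__main__":
    main()
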