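"""Report assembly: tidy metric tables, a JSON of every statistic, and the
standard figures, written deterministically to one directory."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DependencyError
from .stats import CorrelationResult, GroupComparison


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def build_report(
    out_dir,
    tables: dict[str, pd.DataFrame],
    statistics: dict[str, CorrelationResult | GroupComparison] | None = None,
    plots: dict[str, "callable"] | None = None,
    required: tuple[str, ...] = (),
) -> Path:
    """Write a report bundle and return its directory.

    ``tables`` maps name -> tidy DataFrame (written as ``<name>.csv``);
    ``statistics`` maps name -> CorrelationResult / GroupComparison
    (collected into ``statistics.json``); ``plots`` maps filename -> a
    callable taking a matplotlib Axes.  Missing ``required`` tables raise a
    dependency error naming the stage.  Output is deterministic for
    identical inputs (sorted keys, no timestamps).
    """
    for name in required:
        if name not in tables:
            raise DependencyError(f"missing upstream stage output: {name!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in sorted(tables):
        tables[name].to_csv(out / f"{name}.csv", index=False)
    stats = statistics or {}
    payload = {name: _jsonable(stats[name]) for name in sorted(stats)}
    with open(out / "statistics.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for fname in sorted(plots):
            fig, ax = plt.subplots(figsize=(6, 4))
            plots[fname](ax)
            fig.tight_layout()
            fig.savefig(out / fname, dpi=120)
            plt.close(fig)
    return out
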