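"""End-to-end runs: simulate or load movies, compute R(t), the measure
battery, group comparisons, and write a reproducible run directory.

A run is fully determined by its :class:`RunConfig` (serializable JSON) and
the inputs it points at: re-running the same config writes byte-identical
report JSON.  Per-cell failures are quarantined with reasons; the run fails
only if every cell fails.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import before_after, compare_groups
from .embedding import bk_embed, recurrence_plot, recurrence_rate, rp_to_image
from .mask import masks_from_stack, read_stack, roundness_series
from .measures import MEASURE_ORDER, measure_battery
from .series import RSeries
from .synthetic import SyntheticParams, simulate_roundness
from .wavelet import morlet_cwt, scalogram_to_image, transition_profile

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run.

    ``groups`` is a list of dicts, each either
    ``{"state": "...", "n_cells": k, "overrides": {...}}`` (simulated) or
    ``{"label": "...", "stacks": [path, ...]}`` (mask movies on disk) or
    ``{"label": "...", "rseries": [csv, ...]}`` (precomputed R series).
    """

    groups: list = field(default_factory=list)
    dt: float = 2.0
    seed: int = 0
    out_dir: str = "run"
    tail: str = "observed"
    make_figures: bool = False
    wolf: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _group_series(group: dict, cfg: RunConfig, gi: int):
    """Yield (cell_id, RSeries-or-exception) for one config group."""
    out = []
    if "state" in group:
        n_cells = int(group.get("n_cells", 1))
        over = dict(group.get("overrides", {}))
        factory = getattr(SyntheticParams, group["state"])
        for ci in range(n_cells):
            seed = (cfg.seed * 10_000 + gi * 1_000 + ci) % (2 ** 31)
            cell_id = f"{group['state']}-{ci}"
            try:
                params = factory(seed=seed, **over)
                series, _info = simulate_roundness(params)
                series.cell_id = cell_id
                out.append((cell_id, series))
            except Exception as exc:
                out.append((cell_id, exc))
    elif "stacks" in group:
        for ci, path in enumerate(group["stacks"]):
            cell_id = f"{group.get('label', 'group')}-{ci}"
            try:
                masks = masks_from_stack(read_stack(path), dt=cfg.dt)
                out.append((cell_id, roundness_series(
                    masks, dt=cfg.dt, cell_id=cell_id,
                    state_label=group.get("label", "unknown")
                    if group.get("label") in
                    ("idling", "treadmilling", "translocating", "transition")
                    else "unknown")))
            except Exception as exc:
                out.append((cell_id, exc))
    elif "rseries" in group:
        for ci, path in enumerate(group["rseries"]):
            cell_id = f"{group.get('label', 'group')}-{ci}"
            try:
                out.append((cell_id, RSeries.from_csv(path, cell_id=cell_id)))
            except Exception as exc:
                out.append((cell_id, exc))
    else:
        raise ValueError("group needs one of 'state', 'stacks', 'rseries'")
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run and write its outputs under ``config.out_dir``.

    Writes per-cell R(t) CSVs, a measures table, a group comparison table
    (first two groups), and a JSON report with config echo, versions and
    quarantined failures.  Returns the report dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {
        "config": asdict(config),
        "versions": {"pmnshape": __version__, "numpy": np.__version__},
        "cells": [],
        "quarantined": {},
    }
    group_sets = []
    group_names = []
    all_series = {}
    for gi, group in enumerate(config.groups):
        name = group.get("state") or group.get("label") or f"group{gi}"
        group_names.append(name)
        sets = []
        for cell_id, item in _group_series(group, config, gi):
            if isinstance(item, Exception):
                logger.warning("quarantined %s: %s", cell_id, item)
                report["quarantined"][cell_id] = str(item)
                continue
            item.to_csv(out / f"r_{cell_id}.csv")
            ms = measure_battery(item, **config.wolf)
            ms.cell_id = cell_id
            sets.append(ms)
            all_series[cell_id] = item
            report["cells"].append(ms.to_dict())
        group_sets.append(sets)
    if not any(group_sets):
        raise RuntimeError("all cells failed; nothing to report")
    pd.DataFrame([c for c in report["cells"]]).to_csv(
        out / "measures.csv", index=False)
    if len(group_sets) >= 2 and len(group_sets[0]) >= 2 and len(group_sets[1]) >= 2:
        cmp = compare_groups(group_sets[0], group_sets[1], tail=config.tail)
        cmp.to_frame().to_csv(out / "comparison.csv", index=False)
        report["comparison"] = {
            "groups": group_names[:2],
            "note": "no multiple-testing correction across measures",
            "rows": [vars(r) for r in cmp.rows],
        }
    # before/after on any transition cells, split at the known switch index
    for gi, group in enumerate(config.groups):
        if group.get("state") == "transition":
            ts = int(group.get("overrides", {}).get("t_switch", 283))
            for ms, (cell_id, series) in zip(
                    group_sets[gi],
                    [(c, s) for c, s in all_series.items()
                     if c.startswith("transition")]):
                ba = before_after(series, ts)
                prof = transition_profile(morlet_cwt(series))
                report.setdefault("before_after", {})[cell_id] = {
                    "deltas": ba.deltas,
                    "direction_match": ba.direction_match,
                    "change_point": prof.change_point,
                    "change_point_error": prof.change_point - ts,
                }
    if config.make_figures:
        _figures(all_series, out)
    text = json.dumps(report, indent=2, sort_keys=True)
    (out / "report.json").write_text(text)
    return report


def _figures(all_series: dict, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    for cell_id, series in list(all_series.items())[:4]:
        fig, ax = plt.subplots(figsize=(8, 3))
        ax.plot(series.times / 60.0, series.values, lw=0.7)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("R(t)")
        ax.set_title(cell_id)
        fig.savefig(out / f"r_{cell_id}.png", dpi=120)
        plt.close(fig)
        rp = recurrence_plot(series, mode="quantile", q=10.0)
        rp_to_image(rp, out / f"rp_{cell_id}.png")
        sc = morlet_cwt(series)
        scalogram_to_image(sc, out / f"cwt_{cell_id}.png",
                           series=series.values)
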