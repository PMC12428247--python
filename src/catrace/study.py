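"""Parameter-recovery study over the bundled condition presets.

The published group statistics derive from imaging data that was never
deposited, so the reproducible claim this package makes is closure of the
whole pipeline: cohorts generated from presets that encode each printed
condition statistic must, after background subtraction, normalization and
window-max extraction, return those statistics within Monte-Carlo
tolerance. Each entry of :data:`RECOVERY_TARGETS` names one such quantity;
:func:`run_recovery` regenerates its cohort from scratch, runs the full
extraction pipeline, and measures it.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .extraction import process_cohort
from .groupstats import mann_whitney_u
from .kinetics import extract_cell_metrics, replicate_responder_percent
from .presets import load_presets
from .protocol import AnalysisConfig, StimulusProtocol
from .simulate import generate_cohort

#: Each target: condition, measured statistic, seed offset (added to
#: base_seed * 1000), and cells per replicate. Cohorts are always
#: 2 lines x 3 replicates.
RECOVERY_TARGETS: dict[str, dict] = {
    "t1": dict(stage="iPSC", stimulus="ATP", group="ASD", metric="max_rmr_fold", k=1, n_cells=50),
    "t2": dict(stage="iPSC", stimulus="ATP", group="control", metric="max_rmr_fold", k=2, n_cells=50),
    "t3": dict(stage="iPSC", stimulus="ATP", group="ASD", metric="time_to_max_rmr", k=1, n_cells=50),
    "t4": dict(stage="iPSC", stimulus="ATP", group="control", metric="time_to_max_rmr", k=2, n_cells=50),
    "t5": dict(stage="Diff1wk", stimulus="KCl", group="ASD", metric="max_rmr_fold", k=3, n_cells=50),
    "t6": dict(stage="Diff1wk", stimulus="ATP", group="ASD", metric="responder_percent", k=4, n_cells=100),
    "t7": dict(stage="Diff4wk", stimulus="KCl", group="ASD", metric="max_rmr_fold", k=5, n_cells=50),
    "t8": dict(stage="Diff4wk", stimulus="ATP", group="ASD", metric="max_rmr_fold", k=6, n_cells=50),
    "t9": dict(stage="Diff4wk", stimulus="DHPG", group="ASD", metric="max_rmr_fold", k=7, n_cells=50),
}


def derive_seed(base_seed: int, k: int) -> int:
    """Per-target seed derived from one base seed; stays below 2**31."""
    return (base_seed * 1000 + k) % (2**31)


def cohort_metrics(
    stage: str,
    stimulus: str,
    group: str,
    seed: int,
    n_cells_per_replicate: int | None = None,
    protocol: StimulusProtocol | None = None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Generate one preset cohort and run the full extraction pipeline."""
    protocol = protocol or StimulusProtocol(stimulus_name=stimulus)
    config = config or AnalysisConfig()
    preset = load_presets()[(stage, stimulus, group)]
    if n_cells_per_replicate is not None:
        preset = replace(preset, n_cells_per_replicate=n_cells_per_replicate)
    traces = generate_cohort(preset, protocol, seed, threshold=config.doubling_threshold)
    normalized = process_cohort(traces, protocol, config)
    return extract_cell_metrics(normalized, protocol, config)


def run_recovery(base_seed: int = 1) -> dict[str, dict]:
    """Recompute every recovery target from scratch.

    Returns ``{target_id: {"value": measured, "n": cells used}}``; the
    Mann-Whitney entry ("t10") compares the two pluripotent-stage cohorts
    at cell level and reports its two-tailed p.
    """
    cohorts: dict[tuple, pd.DataFrame] = {}
    results: dict[str, dict] = {}
    for tid, target in RECOVERY_TARGETS.items():
        key = (target["stage"], target["stimulus"], target["group"], target["k"], target["n_cells"])
        if key not in cohorts:
            cohorts[key] = cohort_metrics(
                target["stage"],
                target["stimulus"],
                target["group"],
                derive_seed(base_seed, target["k"]),
                n_cells_per_replicate=target["n_cells"],
            )
        metrics = cohorts[key]
        if target["metric"] == "responder_percent":
            value = float(replicate_responder_percent(metrics).mean())
        else:
            value = float(metrics[target["metric"]].mean())
        results[tid] = {"value": value, "n": int(len(metrics))}
    asd = cohorts[("iPSC", "ATP", "ASD", 1, 50)]
    ctl = cohorts[("iPSC", "ATP", "control", 2, 50)]
    _, p = mann_whitney_u(
        asd["max_rmr_fold"].to_numpy(), ctl["max_rmr_fold"].to_numpy()
    )
    results["t10"] = {"value": float(p), "n": int(len(asd) + len(ctl))}
    return results
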