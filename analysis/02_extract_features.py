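#!/usr/bin/env python
"""Extract per-cell kinetics from the simulated cohorts.

For every cohort written by 01_simulate_cohorts.py: subtract the stored
background, normalize to the mean of the first three pre-stimulus frames,
and take window maxima / times-to-max plus the responder flag. Per-cell
metrics go to scratch/ (one row per cell); the condition-level summary
table (mean +/- SEM per metric) and a mean-trace figure go to results/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from catrace.extraction import process_cohort
from catrace.io import read_traces
from catrace.kinetics import extract_cell_metrics, summarize_cells
from catrace.protocol import AnalysisConfig, StimulusProtocol

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    manifest = pd.read_csv(ROOT / "results" / "cohort_manifest.csv")
    config = AnalysisConfig()
    all_metrics = []
    mean_traces = {}
    for row in manifest.itertuples():
        protocol = StimulusProtocol(stimulus_name=row.stimulus)
        traces = read_traces(ROOT / row.path, protocol)
        normalized = process_cohort(traces, protocol, config)
        metrics = extract_cell_metrics(normalized, protocol, config)
        all_metrics.append(metrics)
        mean_traces[(row.stage, row.stimulus, row.group)] = np.mean(
            [nt.fold for nt in normalized], axis=0
        )
        print(
            f"{row.stage:8s} {row.stimulus:5s} {row.group:8s}  "
            f"max RMR {metrics.max_rmr_fold.mean():5.2f}  "
            f"ttp {metrics.time_to_max_rmr.mean():6.2f} s  "
            f"doubling {metrics.responder.mean() * 100:5.1f} %"
        )
    metrics = pd.concat(all_metrics, ignore_index=True)
    metrics.to_csv(ROOT / "scratch" / "cell_metrics.csv", index=False)

    summary = summarize_cells(metrics, config)
    out = ROOT / "results" / "group_summaries.csv"
    summary.to_csv(out, index=False, float_format="%.6g")
    print(f"\nwrote {len(summary)} summary rows to {out}")

    _plot_mean_traces(mean_traces)


def _plot_mean_traces(mean_traces: dict) -> None:
    conditions = sorted({(s, st) for (s, st, _) in mean_traces})
    fig, axes = plt.subplots(2, 3, figsize=(13, 6), sharey=True)
    t = np.arange(500)
    for ax, (stage, stim) in zip(axes.ravel(), conditions):
        for group, color in (("ASD", "crimson"), ("control", "steelblue")):
            ax.plot(t, mean_traces[(stage, stim, group)], color=color, lw=1.2, label=group)
        for x in (20, 200, 400):
            ax.axvline(x, color="0.8", lw=0.8, zorder=0)
        ax.set_title(f"{stage} / {stim}")
        ax.set_xlabel("time (s)")
    axes[0, 0].set_ylabel("fold over baseline")
    axes[0, 0].legend(frameon=False)
    fig.tight_layout()
    out = ROOT / "results" / "figures" / "mean_traces.png"
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=150)
    print(f"mean-trace figure at {out}")


if __name__ == "__main__":
    main()
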