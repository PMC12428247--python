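#!/usr/bin/env python
"""ASD vs control comparisons per condition.

Pools the two lines of each diagnosis group and runs the two-tailed
Mann-Whitney U test at cell level for the four kinetic metrics and at
replicate level for the doubling percentage, per (stage, stimulus). Writes
the tidy report (summary + test rows, JSON sidecar) to results/ and prints
each significant difference with its direction.
"""

from pathlib import Path

import pandas as pd

from catrace.groupstats import compare_conditions
from catrace.io import write_report
from catrace.protocol import AnalysisConfig

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    metrics = pd.read_csv(ROOT / "scratch" / "cell_metrics.csv")
    config = AnalysisConfig()
    results = compare_conditions(metrics, config)
    out = ROOT / "results" / "comparisons.csv"
    write_report(results, out, config=config.to_dict())
    print(f"wrote {len(results)} comparisons to {out}\n")
    for res in results:
        a, b = res.summaries
        direction = ">" if a.mean > b.mean else "<"
        flag = (
            "****" if res.p_two_tailed <= 1e-4
            else "*" if res.p_two_tailed <= 0.05
            else "    "
        )
        print(
            f"{res.stage:8s} {res.stimulus:5s} {res.metric:18s} "
            f"{a.group} {a.mean:7.2f} {direction} {b.group} {b.mean:7.2f}  "
            f"U={res.U:9.1f}  p={res.p_two_tailed:9.3g} {flag}"
        )


if __name__ == "__main__":
    main()
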