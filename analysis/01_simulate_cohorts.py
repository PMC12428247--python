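#!/usr/bin/env python
"""Generate one synthetic cohort per studied condition.

Every (stage, stimulus, group) condition in the bundled presets becomes a
cohort of 2 lines x 3 replicates x 50 cells on the standard 500 s protocol
(stimulus at 20 s, ionomycin at 200 s, EGTA at 400 s). Per-frame traces are
bulky and reproducible, so they go to scratch/traces/; a small manifest of
what was generated lands in results/.
"""

from pathlib import Path

import pandas as pd

from catrace.io import write_traces
from catrace.presets import load_presets
from catrace.protocol import StimulusProtocol
from catrace.simulate import generate_cohort

ROOT = Path(__file__).resolve().parents[1]
TRACE_DIR = ROOT / "scratch" / "traces"
BASE_SEED = 20_000


def main() -> None:
    presets = load_presets()
    rows = []
    for idx, ((stage, stimulus, group), preset) in enumerate(sorted(presets.items())):
        protocol = StimulusProtocol(stimulus_name=stimulus)
        seed = BASE_SEED + idx
        cohort = generate_cohort(preset, protocol, seed)
        path = TRACE_DIR / f"{stage}_{stimulus}_{group}.csv"
        write_traces(cohort, path)
        rows.append(
            {
                "stage": stage, "stimulus": stimulus, "group": group,
                "n_cells": len(cohort), "seed": seed, "path": str(path.relative_to(ROOT)),
            }
        )
        print(f"{stage:8s} {stimulus:5s} {group:8s} -> {len(cohort)} cells (seed {seed})")
    manifest = pd.DataFrame(rows)
    out = ROOT / "results" / "cohort_manifest.csv"
    out.parent.mkdir(exist_ok=True)
    manifest.to_csv(out, index=False)
    print(f"\n{len(rows)} cohorts written under {TRACE_DIR}; manifest at {out}")


if __name__ == "__main__":
    main()
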