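# catrace

Stimulus-response calcium-imaging analysis for iPSC-derived cortical
cultures: synthetic Fluo-4-like cohort generation, ΔF/F0 extraction,
per-cell kinetics and responder classification, nonparametric
ASD-vs-control comparison, and a hypergeometric stage-selection screen
over differential-expression tables.

## The problem

Calcium-imaging studies of ASD and control iPSC lines record 500 s
timelapses (~1 s frames) in which a receptor stimulus (ATP, KCl, or DHPG)
is delivered at second 20, the ionophore ionomycin at second 200, and the
chelator EGTA at second 400. Per cell, the analysis computes

- fold = F/F0 after background subtraction, with F0 the mean of the first
  three pre-stimulus frames;
- the maximum receptor-mediated response (RMR), max fold on [20, 200) s,
  and the time from stimulus to that maximum;
- the same pair for the ionomycin window [200, 400) s;
- a responder flag: max RMR fold ≥ 2 ("doubled its response").

Cells from the two lines of each diagnosis are pooled and groups are
compared with the two-tailed Mann–Whitney U test (U = min(U₁,U₂),
midranks; exact for small tie-free samples, tie-corrected normal
approximation with continuity correction otherwise).

The underlying recordings were never deposited — only condition-level
statistics (means ± SEM, doubling percentages) are available. `catrace`
therefore ships a synthetic-cohort generator whose presets encode each
published condition, and demonstrates *parameter recovery*: generated
cohorts, pushed through the full pipeline, return the encoded statistics
within Monte-Carlo tolerance and reproduce the published group
differences. Cohort means mix responders and non-responders, so the
generator solves the responder-component mean in closed form
(µ_r = (µ − (1−f)·µ_nr)/f) so the mixture mean equals the published mean
exactly. See `docs/methods.md` for the model.

A companion screen module implements the transcriptomic stage-selection
logic: tally significant DEGs per differentiation stage (iPSC, NI, NSP,
Diff), intersect with a calcium-annotation gene set, compute phyper-style
upper-tail enrichment with Benjamini–Hochberg correction, and rank stages
by annotated-DEG burden.

## Worked example

```python
from catrace import (
    StimulusProtocol, load_presets, generate_cohort,
    process_cohort, extract_cell_metrics, compare_conditions,
)
import pandas as pd

protocol = StimulusProtocol()          # stimulus 20 s, ionomycin 200 s, EGTA 400 s
presets = load_presets()               # 12 published (stage, stimulus, group) conditions

parts = []
for group, seed in (("ASD", 1001), ("control", 1002)):
    cohort = generate_cohort(presets[("iPSC", "ATP", group)], protocol, seed)
    normalized = process_cohort(cohort, protocol)          # subtract + ΔF/F0
    parts.append(extract_cell_metrics(normalized, protocol))
metrics = pd.concat(parts, ignore_index=True)

for res in compare_conditions(metrics):
    a, b = res.summaries
    print(f"{res.metric:18s} ASD {a.mean:6.2f}  control {b.mean:6.2f}  p={res.p_two_tailed:.3g}")
```

prints

```
max_rmr_fold       ASD   4.20  control   3.71  p=7.06e-21
max_iono_fold      ASD   3.55  control   3.88  p=4.93e-10
time_to_max_rmr    ASD  78.96  control  49.68  p=3.83e-46
time_to_max_iono   ASD  48.56  control  49.15  p=0.7
responder_percent  ASD 100.00  control 100.00  p=1
```

(preceded by a logged warning that the responder percentages are identical
in every replicate, so that test degenerates to p = 1).

Each cohort is 2 lines × 3 replicates × 50 cells. The ASD preset encodes
the published pluripotent-stage ATP response (mean max 4.23 fold, 82.59 s
to peak) and the control preset 3.71 fold / 49.87 s; after generation with
1% noise and full re-extraction the pooled means land within sampling
error of those values, ASD exceeds control in amplitude, and the
cell-level Mann–Whitney p is far below the published 10⁻⁴ bound. The
ionomycin amplitude comes out directionally lower in ASD, as encoded, and
every pluripotent cell doubles its response, matching the "homogeneous
response" description (the presets set the responder fraction to 1 at this
stage, and the RMR time-to-max difference — 79 vs 50 s — is the published
slower ASD rise).

## Analysis drivers

The `analysis/` scripts rerun the whole study on synthetic cohorts:

```bash
python analysis/01_simulate_cohorts.py   # 12 cohorts -> scratch/traces/
python analysis/02_extract_features.py   # metrics, summaries, mean-trace figure
python analysis/03_compare_groups.py     # Mann-Whitney report -> results/comparisons.csv
python analysis/04_stage_screen.py       # DEG tallies + enrichment -> results/stage_screen.csv
```

The comparison table reproduces every published direction (e.g. higher
ATP response in ASD at the pluripotent stage; lower ATP but higher
KCl/DHPG responses in ASD neurons) and the screen selects the iPSC and
Diff stages, the two with 39 calcium-annotated significant genes each.

There is also a thin CLI (`catrace simulate|extract|compare|screen`) over
the same library functions.

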