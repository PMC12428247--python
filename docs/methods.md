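# Methods

## Problem setting

Stimulus-response calcium imaging of iPSC-derived cultures compares ASD and
control cell lines at three points along cortical differentiation (iPSC,
1-week and 4-week differentiated neurons). Fluo-4-loaded cells are recorded
for 500 s at ~1 s frames; a receptor stimulus (100 µM ATP, 25 mM KCl, or
200 µM DHPG) is delivered at second 20, 4 µM ionomycin at second 200, and
EGTA at second 400. Analysis proceeds per cell: background subtraction,
normalization of intensity to the mean of the first three pre-stimulus
frames (dF/F0 as a fold ratio), then the maximum fold and time-to-maximum
within the receptor-mediated-response (RMR) window and the ionomycin
window, plus a responder flag (maximum RMR fold >= 2, "doubled its
response"). Lines are pooled into one ASD and one control group per
condition and compared with the two-tailed Mann-Whitney U test.

The original imaging data are not deposited; only condition-level
statistics are published. The package therefore pairs the analysis
pipeline with a synthetic-cohort generator whose presets encode each
published condition statistic, and the headline claim is *closure*:
generated cohorts, pushed through the full extraction pipeline, return the
encoded statistics within Monte-Carlo tolerance, and the ASD-vs-control
comparisons reproduce the published directions and significance bounds.

## Timing model

`StimulusProtocol` fixes an exact grid: frame k at time k·Δt with
Δt = 1 s, 500 frames spanning [0, 500) s. The source describes
"approximately 1 s" intervals; an exact grid is assumed for determinism and
is configurable. Windows are half-open so every frame belongs to exactly
one window and an event's frame opens its own window: baseline = first
3 frames, RMR = [20, 200) s, ionomycin = [200, 400) s, EGTA tail =
[400, 500) s. "First three images before delivering the stimulus" is read
as frames {0, 1, 2} (the `start` anchor); the alternative reading — the
three frames immediately preceding the stimulus — is available as
`baseline_anchor="prestim"` and is identical for flat baselines.

## Synthetic trace model

No waveform equation is published, so the generator uses a parametric
pulse whose two parameters are exactly the published quantities (peak
amplitude and time-to-peak):

- Rise: a generalized alpha function g(τ) = (τ/τp)^m · exp(m(1 − τ/τp)),
  which equals 1 exactly at τ = τp for any exponent m. The default
  m = 3 was chosen because the plain alpha pulse (m = 1) has curvature
  1/τp² at its top: for slow responses (τp ≈ 80 s) the top is flat on the
  scale of the 1% additive noise, and the argmax-based time-to-max
  acquires a systematic early bias of several seconds. m = 3 keeps the
  peak identifiable while remaining a smooth, physiological-looking
  transient; noise-free recovery is exact either way.
- After the peak the RMR relaxes exponentially (τ = 30 s) toward a partial
  plateau 1 + 0.35·(A − 1), reflecting incomplete store clearance before
  ionomycin.
- The ionomycin window blends the clearing receptor residual
  (exponential clearance, τ = 20 s) with a second alpha pulse as a convex
  combination whose maximum equals the drawn ionomycin fold exactly.
  Because continuity forbids a window maximum below the level the trace
  enters with, each cell's drawn ionomycin amplitude is clamped from
  below at that residual (affects roughly 1–2% of cells in the worst
  preset; the stored value is the clamped one, so generate→extract
  closure holds for every cell). Apart from this feasibility clamp, the
  ionomycin response is drawn independently of the RMR amplitude, since
  the published conditions show the two diverging.
- After EGTA the fold decays exponentially toward 1 (τ = 30 s). No metric
  is computed there; the tail is generated for realism only.
- Raw counts: background (50) + F0 (1000) · fold · exp(−bleach·t) +
  Gaussian noise (SD 10 counts = 1% of F0), clipped at 0. Bleaching
  defaults to 0 because the original analysis applies no bleach
  correction; it exists for robustness experiments.

Drawn times-to-peak are snapped to the frame grid inside the generator.
Off-grid peaks would undershoot the continuous maximum by up to ~5·10⁻⁴
fold on a discrete grid; snapping makes the noise-free pipeline exactly
invertible (amplitude to float precision, peak time to one frame), which
is what the closure tests assert.

## Population model and calibration

Published cohort means average *all* imaged cells — a mean of 1.58 printed
beside a 13.6% doubling rate is only consistent if non-responders are
included. Each cohort is therefore a two-component mixture:

- non-responders: Normal(1.3, 0.15) truncated to [1, 2) fold — realistic
  sub-doubling responses that can never cross the threshold;
- responders: Normal(µ_r, 0.6) truncated below at 1, with µ_r solved in
  closed form so the mixture mean equals the published cohort mean
  exactly: µ_r = (µ − (1 − f)·1.3)/f for responder fraction f. A preset
  whose published mean and fraction are mutually inconsistent at this
  non-responder level (µ_r < 2) is rejected as infeasible.

Published "± x" values are SEMs at unstated n, so they cannot fix
cell-level spread. Per-cell SDs default to 0.6 fold for amplitudes and
0.3·µ for times-to-peak; recovery targets are means, not spreads, and the
SEMs are carried in the presets only as metadata. Times-to-peak are
truncated-normal within their window. Conditions where a quantity was not
published use fixed plausible defaults on the scale of neighbouring
conditions (ionomycin time-to-max 50 s at the pluripotent stage; 1-week
KCl ionomycin amplitude 2.80 fold): these are stated in the preset file
and were chosen once, not fitted.

Cohort structure mirrors the experiment: 2 cell lines per group × 3
independent replicates × 50 cells (cell count per coverslip is not
published; 50 is a typical field of view and gives n = 300 cells/group,
comfortable for CLT-scale tolerances while keeping every run under a
minute).

## Extraction and statistics

- Background: the stored scalar/column estimate takes precedence; scalar
  and rolling-percentile (drifting offset) modes exist. Negative values
  after subtraction are clipped to 0 before F0 is computed, since
  fluorescence cannot be negative. A background at or above every
  intensity is a degenerate trace, not a silent zero.
- Normalization: fold = corrected / F0 with F0 the baseline mean; the
  baseline-window mean of fold is 1 exactly by construction, normalization
  is scale invariant, and no smoothing or detrending is applied (either
  would bias time-to-max).
- Kinetics: window maximum and first-occurrence argmax time. "Rate of
  rise" is reported as time-to-maximum in seconds, matching how the
  results are printed; a 10–90% rise slope (fold/s) exists as an optional
  secondary metric.
- Summaries: amplitude/time metrics are pooled over cells with cell-level
  SEM; the doubling percentage is summarized at replicate level (mean of
  replicate percentages, SEM across replicates), the unit its published
  SEMs most plausibly refer to. Both units are implemented because the
  source does not state which was used; the choice is configuration, not
  assertion.
- Mann-Whitney: U = min(U₁, U₂) with midranks; exact permutation p when
  n₁ + n₂ ≤ 20 and tie-free, otherwise the normal approximation with
  tie-corrected variance and continuity correction. Cell-level testing is
  the default: published p ≤ 10⁻⁴ values are unattainable at n = 3
  replicates with this test, so cells are the only consistent sampling
  unit; replicate-level testing is available by configuration and the
  unit is recorded in every report row. No multiple-testing correction is
  applied by default (matching the source analysis); Benjamini-Hochberg
  is available behind a flag.
- Stage screen: significant genes per stage at q ≤ 0.05 split by log2FC
  sign; upper-tail hypergeometric over-representation of a user-supplied
  calcium gene set, computed via the log-space survival function for
  stability at extreme p; BH across stages; stages ranked by annotated-DEG
  count with ties broken by smaller p, then name. The universe defaults
  to all genes in the table (the study detected 18,119). The bundled
  calcium gene list is a demo fixture, not a curated GO set.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis assumes:
per-cell amplitude heterogeneity, responder mixtures, timing jitter,
photobleaching drift (off by default), background offset, additive noise,
and the replicate/line nesting. It does not model spontaneous transients
or oscillations, mechanistic calcium handling (no ODEs, no store
dynamics), spatial structure within cells, motion, or focus drift. Passing
recovery tests therefore demonstrates that the pipeline measures what it
claims to measure on data with this structure — an internal-consistency
and correctness statement, not an independent validation of the biological
findings.

## Numerical choices and degenerate inputs

- Ties in window maxima: first occurrence wins, so a flat window reports
  time 0.
- Responder threshold boundary (exactly 2.0) counts as a responder.
- Identical samples in the Mann-Whitney test return U = n₁n₂/2, p = 1
  with a warning rather than dividing by a zero variance.
- p-values are clipped to (0, 1]; enrichment p uses log-space survival.
- A single replicate leaves replicate-level SEMs undefined (NaN + warning)
  rather than silently zero.
- CSV floats are parsed with round-trip precision, so write→read preserves
  values bit for bit.

## Problem sizes used in the shipped runs

Recovery runs use 2 × 3 × 50 cells per cohort (100/replicate for the
1-week ATP doubling target, where the percentage is the statistic), the
Monte-Carlo type-I-error check uses 10⁴ null simulations at n = 20/20, and
the enrichment oracle comparisons enumerate exact combinatorics up to
N = 30. These sizes give tolerance-dominated, not runtime-dominated,
checks; all were chosen as the smallest sizes at which the Monte-Carlo
error is clearly inside the stated tolerances.

## Known limitations

- The waveform is phenomenological; parameter recovery says nothing about
  mechanistic interpretability of its time constants.
- The feasibility clamp ties the extreme lower tail of the ionomycin
  amplitude distribution to the RMR plateau.
- Exact Mann-Whitney with ties (as some commercial packages implement) is
  not replicated bit for bit; midranks + corrected normal approximation
  are used instead.
- The published enrichment numbers (39 calcium-binding DEGs, Q = 0.00011)
  are not recoverable without the original annotation and universe; the
  screen reproduces the logic and the stage ranking, not those exact
  p-values.
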