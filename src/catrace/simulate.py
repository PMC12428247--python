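"""Synthetic Fluo-4-like cohort generator.

Each condition (group x differentiation stage x stimulus) is described by a
:class:`CohortPreset` whose location parameters are the published condition
statistics: mean maximum receptor-mediated fold response, mean time to that
maximum, responder (doubling) fraction, and the corresponding ionomycin
quantities. A cell's noise-free fold profile is built from alpha-function
pulses with independent, interpretable peak amplitude and time-to-peak:

* flat baseline at fold 1 before the stimulus;
* receptor pulse: a generalized alpha rise
  ``g(tau) = (tau/tau_p)^m * exp(m * (1 - tau/tau_p))`` scaled so the fold
  peaks at A exactly at tau_p (m = rise_power, default 3, keeps the peak
  time identifiable against noise), then relaxation toward a partial
  plateau ``1 + plateau_frac * (A - 1)``;
* a second alpha pulse in the ionomycin window whose maximum equals the
  drawn ionomycin fold (the decaying receptor residual is blended in as a
  convex combination, so the window max is the drawn amplitude by
  construction);
* exponential decay toward baseline after EGTA.

Raw counts are ``background + F0 * fold * exp(-bleach_rate * t)`` plus
additive Gaussian noise, clipped at zero. Because observed cohort means mix
responders with sub-doubling cells, :func:`calibrate_mixture` solves the
responder-component mean so the mixture mean equals the target exactly.

Drawn times-to-peak are snapped to the acquisition grid, so the noise-free
generate -> extract round trip recovers every drawn amplitude and peak time
exactly (to float precision).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InfeasiblePresetError, LayoutError, ValidationError
from .io import Trace
from .protocol import GROUPS, SCREEN_STAGES, STAGES, STIMULI, StimulusProtocol


@dataclass
class KineticShape:
    """Per-cell kinetic parameterization of one trace.

    Amplitudes are dimensionless folds over baseline; times are seconds
    after the event that opens the window.
    """

    peak_fold: float
    time_to_peak: float
    iono_peak_fold: float = 1.0
    iono_time_to_peak: float = 50.0
    rise_power: float = 3.0
    post_peak_plateau_frac: float = 0.35
    rmr_decay_tau: float = 30.0
    iono_plateau_frac: float = 0.6
    iono_decay_tau: float = 40.0
    receptor_clear_tau: float = 20.0
    egta_decay_tau: float = 30.0

    def __post_init__(self) -> None:
        if self.peak_fold < 1:
            raise ValidationError("peak_fold must be >= 1")
        if self.time_to_peak <= 0 or self.iono_time_to_peak <= 0:
            raise ValidationError("times to peak must be positive")
        for name in ("post_peak_plateau_frac", "iono_plateau_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")


@dataclass
class CohortPreset:
    """Generative parameters of one (group, stage, stimulus) condition.

    Location parameters (``mu_*``, ``responder_frac``) encode the condition's
    published statistics; dispersion parameters are cell-level spreads the
    source does not constrain (its printed spreads are SEMs at unstated n)
    and default to sd_peak_cell = 0.6 fold and sd_ttp = 0.3 * mu_ttp.
    ``reported_sem`` carries the published SEMs as metadata for tolerance
    bookkeeping; it plays no role in generation.
    """

    group: str
    stage: str
    stimulus: str
    mu_peak: float
    mu_ttp: float
    responder_frac: float
    mu_iono_peak: float
    mu_iono_ttp: float
    sd_peak_cell: float = 0.6
    sd_ttp: float | None = None
    nonresponder_mu: float = 1.3
    nonresponder_sd: float = 0.15
    sd_iono_cell: float = 0.6
    sd_iono_ttp: float | None = None
    f0: float = 1000.0
    noise_sd: float = 10.0
    bleach_rate: float = 0.0
    background_level: float = 50.0
    n_cells_per_replicate: int = 50
    n_replicates: int = 3
    n_lines: int = 2
    reported_sem: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}")
        if self.stage not in STAGES:
            raise ValidationError(f"stage must be one of {STAGES}")
        if self.stimulus not in STIMULI:
            raise ValidationError(f"stimulus must be one of {STIMULI}")
        if self.mu_peak < 1:
            raise ValidationError("mu_peak must be >= 1")
        if not 0 <= self.responder_frac <= 1:
            raise ValidationError("responder_frac must lie in [0, 1]")
        if self.mu_ttp <= 0:
            raise ValidationError("mu_ttp must be positive")
        for name in ("n_cells_per_replicate", "n_replicates", "n_lines"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.sd_ttp is None:
            self.sd_ttp = 0.3 * self.mu_ttp
        if self.sd_iono_ttp is None:
            self.sd_iono_ttp = 0.3 * self.mu_iono_ttp

    @property
    def n_cells_total(self) -> int:
        return self.n_lines * self.n_replicates * self.n_cells_per_replicate


def calibrate_mixture(preset: CohortPreset, threshold: float = 2.0) -> tuple[float, float]:
    """Solve the responder-component mean from the target mixture mean.

    With responder fraction f, non-responder mean m, and target cohort mean
    mu, the responder mean is ``(mu - (1 - f) * m) / f``, which makes the
    mixture mean equal mu exactly. Raises :class:`InfeasiblePresetError`
    when the implied responder mean falls below the doubling threshold
    (the stated mean and fraction are inconsistent at this non-responder
    level).
    """
    f = preset.responder_frac
    if f <= 0:
        raise InfeasiblePresetError("responder_frac must be positive to calibrate")
    if preset.nonresponder_mu >= threshold:
        raise InfeasiblePresetError("nonresponder_mu must lie below the threshold")
    responder_mu = (preset.mu_peak - (1.0 - f) * preset.nonresponder_mu) / f
    if responder_mu < threshold:
        raise InfeasiblePresetError(
            f"calibrated responder mean {responder_mu:.3f} below threshold {threshold}: "
            "cohort mean and responder fraction are inconsistent"
        )
    return responder_mu, preset.nonresponder_mu


# ---------------------------------------------------------------------------
# Waveform
# ---------------------------------------------------------------------------

def _alpha_rise(tau: np.ndarray | float, tau_p: float, power: float = 3.0) -> np.ndarray:
    """Generalized alpha rising branch, ``(tau/tau_p)^m * exp(m (1 - tau/tau_p))``.

    Peaks at exactly 1 when tau = tau_p for any exponent m; m > 1 sharpens
    the curvature at the peak (``|g''(tau_p)| = m / tau_p**2``) so the peak
    time stays identifiable against additive noise even for slow responses.
    """
    x = np.asarray(tau, dtype=float) / tau_p
    return x**power * np.exp(power * (1.0 - x))


def _pulse(tau, tau_p, plateau_frac, decay_tau, power: float = 3.0):
    """Unit pulse: alpha rise to 1 at tau_p, then relaxation toward plateau_frac."""
    tau = np.asarray(tau, dtype=float)
    rising = tau <= tau_p
    out = np.empty_like(tau)
    out[rising] = _alpha_rise(tau[rising], tau_p, power)
    out[~rising] = plateau_frac + (1.0 - plateau_frac) * np.exp(
        -(tau[~rising] - tau_p) / decay_tau
    )
    return out


def rmr_residual_at_ionomycin(shape: KineticShape, protocol: StimulusProtocol) -> float:
    """Fold level the receptor response has relaxed to when ionomycin is added."""
    h_end = _pulse(
        np.array([protocol.rmr_duration]),
        shape.time_to_peak,
        shape.post_peak_plateau_frac,
        shape.rmr_decay_tau,
        shape.rise_power,
    )[0]
    return 1.0 + (shape.peak_fold - 1.0) * float(h_end)


def fold_profile(shape: KineticShape, protocol: StimulusProtocol) -> np.ndarray:
    """Noise-free fold-over-baseline profile of one cell on the protocol grid."""
    if shape.time_to_peak >= protocol.rmr_duration:
        raise ValidationError("receptor time_to_peak places the peak beyond its window")
    if shape.iono_time_to_peak >= protocol.ionomycin_duration:
        raise ValidationError("ionomycin time_to_peak places the peak beyond its window")
    t = protocol.times
    fold = np.ones_like(t)

    in_rmr = protocol.rmr_mask(t)
    tau1 = t[in_rmr] - protocol.t_stimulus
    fold[in_rmr] = 1.0 + (shape.peak_fold - 1.0) * _pulse(
        tau1, shape.time_to_peak, shape.post_peak_plateau_frac, shape.rmr_decay_tau,
        shape.rise_power,
    )

    # Ionomycin window: convex blend of the clearing receptor residual and the
    # ionophore pulse; the blend's maximum is the ionomycin fold provided the
    # residual never exceeds it (enforced at draw time by generate_cohort).
    residual = rmr_residual_at_ionomycin(shape, protocol)
    a_iono = max(shape.iono_peak_fold, residual)
    in_iono = protocol.ionomycin_mask(t)
    tau2 = t[in_iono] - protocol.t_ionomycin
    g2 = _pulse(
        tau2, shape.iono_time_to_peak, shape.iono_plateau_frac, shape.iono_decay_tau,
        shape.rise_power,
    )
    clearing = 1.0 + (residual - 1.0) * np.exp(-tau2 / shape.receptor_clear_tau)
    fold[in_iono] = (1.0 - g2) * clearing + g2 * a_iono

    in_egta = protocol.egta_mask(t)
    tau2_end = protocol.ionomycin_duration
    g2_end = _pulse(
        np.array([tau2_end]), shape.iono_time_to_peak, shape.iono_plateau_frac,
        shape.iono_decay_tau, shape.rise_power,
    )[0]
    clearing_end = 1.0 + (residual - 1.0) * np.exp(-tau2_end / shape.receptor_clear_tau)
    level_at_egta = (1.0 - g2_end) * clearing_end + g2_end * a_iono
    tau3 = t[in_egta] - protocol.t_egta
    fold[in_egta] = 1.0 + (level_at_egta - 1.0) * np.exp(-tau3 / shape.egta_decay_tau)
    return fold


def generate_trace(
    shape: KineticShape,
    preset: CohortPreset,
    protocol: StimulusProtocol,
    rng: np.random.Generator,
    *,
    cell_id: str = "cell0",
    line_id: str = "line0",
    replicate_id: str = "r1",
) -> Trace:
    """Render one cell: fold profile -> counts with bleach, offset and noise."""
    fold = fold_profile(shape, protocol)
    t = protocol.times
    signal = preset.f0 * fold * np.exp(-preset.bleach_rate * t)
    raw = preset.background_level + signal
    if preset.noise_sd > 0:
        raw = raw + rng.normal(0.0, preset.noise_sd, size=raw.shape)
    raw = np.clip(raw, 0.0, None)
    return Trace(
        cell_id=cell_id,
        line_id=line_id,
        group=preset.group,
        stage=preset.stage,
        replicate_id=replicate_id,
        stimulus=preset.stimulus,
        times=t,
        raw=raw,
        background=preset.background_level,
    )


def _trunc_normal(
    rng: np.random.Generator, mu: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    if sd <= 0:
        return np.full(size, np.clip(mu, lo, hi))
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def _snap(values: np.ndarray, protocol: StimulusProtocol, upper: float) -> np.ndarray:
    """Snap drawn times to the frame grid, keeping the peak inside its window."""
    dt = protocol.frame_interval
    snapped = np.round(values / dt) * dt
    return np.clip(snapped, dt, upper - dt)


def generate_cohort(
    preset: CohortPreset,
    protocol: StimulusProtocol,
    seed: int,
    threshold: float = 2.0,
) -> list[Trace]:
    """Generate n_lines x n_replicates x n_cells_per_replicate traces.

    Peak folds come from the calibrated responder/non-responder mixture
    (responders: Normal(responder_mu, sd_peak_cell) truncated below 1;
    non-responders: Normal(nonresponder_mu, nonresponder_sd) truncated to
    [1, threshold)). Times-to-peak are Normal draws truncated to their
    window and snapped to the grid. Ionomycin amplitudes are drawn
    independently, then clamped from below at the receptor residual at
    ionomycin onset so the window maximum always equals the stored value.
    """
    if preset.responder_frac > 0:
        responder_mu, nonresponder_mu = calibrate_mixture(preset, threshold)
    else:
        responder_mu, nonresponder_mu = None, preset.nonresponder_mu
    rng = np.random.default_rng(seed)
    prefix = "ASD" if preset.group == "ASD" else "CTL"
    traces: list[Trace] = []
    for li in range(preset.n_lines):
        line_id = f"{prefix}{li + 1}"
        for ri in range(preset.n_replicates):
            replicate_id = f"r{ri + 1}"
            n = preset.n_cells_per_replicate
            is_resp = rng.random(n) < preset.responder_frac
            peaks = np.empty(n)
            n_resp = int(is_resp.sum())
            if n_resp:
                peaks[is_resp] = _trunc_normal(
                    rng, responder_mu, preset.sd_peak_cell, 1.0, np.inf, n_resp
                )
            if n - n_resp:
                peaks[~is_resp] = _trunc_normal(
                    rng, nonresponder_mu, preset.nonresponder_sd, 1.0, threshold, n - n_resp
                )
            ttps = _snap(
                _trunc_normal(
                    rng, preset.mu_ttp, preset.sd_ttp, protocol.frame_interval,
                    protocol.rmr_duration - protocol.frame_interval, n,
                ),
                protocol,
                protocol.rmr_duration,
            )
            iono_peaks = _trunc_normal(
                rng, preset.mu_iono_peak, preset.sd_iono_cell, 1.0, np.inf, n
            )
            iono_ttps = _snap(
                _trunc_normal(
                    rng, preset.mu_iono_ttp, preset.sd_iono_ttp, protocol.frame_interval,
                    protocol.ionomycin_duration - protocol.frame_interval, n,
                ),
                protocol,
                protocol.ionomycin_duration,
            )
            for ci in range(n):
                shape = KineticShape(
                    peak_fold=float(peaks[ci]),
                    time_to_peak=float(ttps[ci]),
                    iono_peak_fold=float(iono_peaks[ci]),
                    iono_time_to_peak=float(iono_ttps[ci]),
                )
                # feasibility clamp: window max must equal the stored amplitude
                residual = rmr_residual_at_ionomycin(shape, protocol)
                if shape.iono_peak_fold < residual:
                    shape.iono_peak_fold = residual
                traces.append(
                    generate_trace(
                        shape,
                        preset,
                        protocol,
                        rng,
                        cell_id=f"{preset.stage}_{preset.stimulus}_{line_id}_{replicate_id}_c{ci:03d}",
                        line_id=line_id,
                        replicate_id=replicate_id,
                    )
                )
    return traces


# ---------------------------------------------------------------------------
# Toy image stacks (fixtures for the ROI-extraction path)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StackLayout:
    """Grid placement of cells as uniform discs in a synthetic timelapse."""

    n_cols: int = 4
    radius: int = 4
    spacing: int = 16
    margin: int = 10

    def __post_init__(self) -> None:
        if self.spacing < 2 * self.radius + 2:
            raise LayoutError("spacing too small: discs would touch or overlap")


def generate_image_stack(
    cohort: Sequence[Trace], layout: StackLayout = StackLayout()
) -> tuple[np.ndarray, np.ndarray]:
    """Render traces as a uint16 timelapse stack plus an ROI label mask.

    Every cell is a disc whose pixels all equal the trace's raw value at
    that frame (rounded to integer counts), so ROI means reproduce the
    source traces to within quantization. Pixels outside all discs equal
    the first trace's scalar background.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValidationError("cannot render an empty cohort")
    n_frames = cohort[0].raw.size
    n_rows = -(-len(cohort) // layout.n_cols)
    height = 2 * layout.margin + (n_rows - 1) * layout.spacing + 1
    width = 2 * layout.margin + (layout.n_cols - 1) * layout.spacing + 1
    bg = cohort[0].background
    bg_value = int(round(float(bg))) if bg is not None else 0
    stack = np.full((n_frames, height, width), bg_value, dtype=np.uint16)
    masks = np.zeros((height, width), dtype=np.int32)
    yy, xx = np.mgrid[0:height, 0:width]
    for idx, tr in enumerate(cohort):
        cy = layout.margin + (idx // layout.n_cols) * layout.spacing
        cx = layout.margin + (idx % layout.n_cols) * layout.spacing
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= layout.radius**2
        masks[disc] = idx + 1
        values = np.clip(np.round(tr.raw), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        stack[:, disc] = values[:, None]
    return stack, masks


def save_image_stack(stack: np.ndarray, masks: np.ndarray, stack_path, mask_path) -> None:
    import tifffile

    tifffile.imwrite(stack_path, stack)
    tifffile.imwrite(mask_path, masks)


# ---------------------------------------------------------------------------
# Synthetic DEG tables for the stage screen
# ---------------------------------------------------------------------------

#: Calcium-handling genes used in the bundled demo annotation set: ryanodine
#: receptors, voltage-gated channel subunits, CaM kinases, pumps and the
#: group I metabotropic glutamate receptor — a fixture, not a curated GO set.
DEMO_CALCIUM_GENES = [
    "RYR1", "RYR3", "CACNA1S", "CAMK4", "GRM5", "ATP2B3", "GRIN1",
    "CAMK2B", "ATP2A1", "SLN", "CASQ2", "CACNA1H", "ITPR1", "CALM1",
]


def make_deg_table(
    stage_totals: dict[str, int],
    annotated_sig: dict[str, int],
    universe_size: int = 18119,
    annotation_size: int = 700,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Build a synthetic DEG table with known per-stage composition.

    Returns (table, annotation gene set, universe). Each stage contributes
    ``stage_totals[stage]`` significant genes (q <= 0.05), of which
    ``annotated_sig[stage]`` fall inside the annotation set, plus an equal
    number of non-significant rows; signs of log2FC lean upregulated.
    """
    rng = np.random.default_rng(seed)
    universe = [f"GENE{i:05d}" for i in range(universe_size - len(DEMO_CALCIUM_GENES))]
    universe = DEMO_CALCIUM_GENES + universe
    annotation = universe[:annotation_size]
    non_annotated = universe[annotation_size:]
    rows = []
    for stage in SCREEN_STAGES:
        total = stage_totals.get(stage, 0)
        k = annotated_sig.get(stage, 0)
        if k > total:
            raise ValidationError(f"{stage}: annotated significant genes exceed total")
        picked = rng.choice(non_annotated, size=2 * total - k, replace=False)
        sig_genes = list(rng.choice(annotation, size=k, replace=False)) + list(
            picked[: total - k]
        )
        nonsig_genes = picked[total - k :]
        for gene in sig_genes:
            lfc = rng.normal(1.0, 0.8) if rng.random() < 0.65 else rng.normal(-1.0, 0.8)
            rows.append(
                {
                    "gene": gene,
                    "stage": stage,
                    "log2fc": lfc if lfc != 0 else 0.1,
                    "qvalue": float(rng.uniform(1e-6, 0.05)),
                }
            )
        for gene in nonsig_genes:
            rows.append(
                {
                    "gene": gene,
                    "stage": stage,
                    "log2fc": float(rng.normal(0.0, 0.5)),
                    "qvalue": float(rng.uniform(0.051, 1.0)),
                }
            )
    return pd.DataFrame(rows), annotation, universe
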