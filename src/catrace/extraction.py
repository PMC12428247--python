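"""Background subtraction, baseline normalization, and ROI trace extraction.

The normalization follows the standard dF/F0 recipe for these recordings:
subtract background, then divide by F0, the mean of the first
``n_baseline_frames`` background-subtracted frames acquired before the
stimulus. No smoothing or detrending is applied before feature extraction —
smoothing would bias the time-to-maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import DegenerateTraceError, ValidationError
from .io import Trace
from .protocol import AnalysisConfig, StimulusProtocol

logger = logging.getLogger(__name__)


@dataclass
class NormalizedTrace:
    """Per-cell fold-over-baseline series; f0 is the denominator used."""

    cell_id: str
    line_id: str
    group: str
    stage: str
    replicate_id: str
    stimulus: str
    times: np.ndarray
    fold: np.ndarray
    f0: float

    @property
    def replicate_key(self) -> str:
        return f"{self.line_id}/{self.replicate_id}"


def subtract_background(
    trace: Trace,
    method: str = "auto",
    value: float | None = None,
    percentile: float = 10.0,
    window: int = 51,
) -> Trace:
    """Return a copy of the trace with background removed and clipped at 0.

    Methods: "column" uses the background stored with the trace (scalar or
    per-frame); "scalar" subtracts ``value``; "rolling-percentile" subtracts
    a running low-percentile estimate (for drifting offsets); "auto" picks
    "column" when a background accompanies the trace, else "scalar". A
    stored background takes precedence over an explicit scalar, with a
    warning, since it came with the recording.
    """
    if method not in ("auto", "column", "scalar", "rolling-percentile"):
        raise ValidationError(f"unknown background method: {method}")
    if method == "scalar" and trace.background is not None:
        logger.warning(
            "%s: background column present; it takes precedence over scalar=%s",
            trace.cell_id,
            value,
        )
        method = "column"
    if method == "auto":
        method = "column" if trace.background is not None else "scalar"

    if method == "column":
        if trace.background is None:
            raise ValidationError(f"{trace.cell_id}: no stored background to subtract")
        bg = np.broadcast_to(np.asarray(trace.background, dtype=float), trace.raw.shape)
    elif method == "scalar":
        if value is None:
            raise ValidationError("scalar background subtraction requires a value")
        bg = np.full_like(trace.raw, float(value))
    else:  # rolling-percentile
        bg = ndimage.percentile_filter(trace.raw, percentile, size=window, mode="nearest")

    if np.all(bg >= trace.raw):
        raise DegenerateTraceError(
            f"{trace.cell_id}: background exceeds every intensity value"
        )
    corrected = np.clip(trace.raw - bg, 0.0, None)
    return Trace(
        cell_id=trace.cell_id,
        line_id=trace.line_id,
        group=trace.group,
        stage=trace.stage,
        replicate_id=trace.replicate_id,
        stimulus=trace.stimulus,
        times=trace.times,
        raw=corrected,
        background=None,
    )


def normalize(
    trace: Trace,
    protocol: StimulusProtocol,
    anchor: str = "start",
) -> NormalizedTrace:
    """Divide a background-subtracted trace by its baseline mean F0.

    ``anchor="start"`` takes the first n_baseline_frames of the recording
    (the default reading of "first images before the stimulus");
    ``anchor="prestim"`` takes the n frames immediately preceding the
    stimulus. The two agree for flat baselines.
    """
    n = protocol.n_baseline_frames
    pre = trace.times < protocol.t_stimulus
    if pre.sum() < n:
        raise ValidationError(
            f"{trace.cell_id}: fewer than {n} pre-stimulus frames"
        )
    if anchor == "start":
        baseline = trace.raw[:n]
    elif anchor == "prestim":
        baseline = trace.raw[pre][-n:]
    else:
        raise ValidationError("anchor must be 'start' or 'prestim'")
    f0 = float(np.mean(baseline))
    if f0 <= 0:
        raise DegenerateTraceError(f"{trace.cell_id}: non-positive baseline F0")
    return NormalizedTrace(
        cell_id=trace.cell_id,
        line_id=trace.line_id,
        group=trace.group,
        stage=trace.stage,
        replicate_id=trace.replicate_id,
        stimulus=trace.stimulus,
        times=trace.times,
        fold=trace.raw / f0,
        f0=f0,
    )


def process_cohort(
    traces: Sequence[Trace],
    protocol: StimulusProtocol,
    config: AnalysisConfig | None = None,
    background_value: float | None = None,
) -> list[NormalizedTrace]:
    """Background-subtract and normalize every trace of a cohort."""
    config = config or AnalysisConfig()
    out = []
    for tr in traces:
        method = "auto" if tr.background is not None or background_value is None else "scalar"
        sub = subtract_background(tr, method=method, value=background_value)
        out.append(normalize(sub, protocol, anchor=config.baseline_anchor))
    return out


# ---------------------------------------------------------------------------
# Image-stack path
# ---------------------------------------------------------------------------

def estimate_background(stack: np.ndarray, masks: np.ndarray) -> float:
    """Scalar background: median intensity over non-ROI pixels, all frames."""
    outside = masks == 0
    if not outside.any():
        raise ValidationError("mask covers the whole frame; no background pixels")
    return float(np.median(stack[:, outside]))


def extract_roi_traces(
    stack: np.ndarray,
    masks: np.ndarray,
    protocol: StimulusProtocol,
    *,
    group: str = "control",
    stage: str = "iPSC",
    line_id: str = "roi",
    replicate_id: str = "r1",
) -> list[Trace]:
    """Mean ROI intensity per frame for every label in the mask.

    Empty labels are skipped with a warning; a stack/mask shape mismatch is
    a validation error.
    """
    if stack.ndim != 3:
        raise ValidationError("stack must be a (frames, y, x) array")
    if stack.shape[1:] != masks.shape:
        raise ValidationError("stack and masks have different spatial dimensions")
    labels = np.unique(masks)
    labels = labels[labels >= 1]
    if labels.size == 0:
        logger.warning("mask contains no ROIs; returning zero traces")
        return []
    counts = ndimage.sum_labels(np.ones_like(masks), labels=masks, index=labels)
    keep = counts > 0
    if not keep.all():
        logger.warning("skipping %d empty ROI labels", int((~keep).sum()))
        labels = labels[keep]
    means = np.stack(
        [ndimage.mean(frame, labels=masks, index=labels) for frame in stack]
    )
    traces = []
    for j, label in enumerate(labels):
        traces.append(
            Trace(
                cell_id=f"roi{int(label):03d}",
                line_id=line_id,
                group=group,
                stage=stage,
                replicate_id=replicate_id,
                stimulus=protocol.stimulus_name,
                times=protocol.times[: stack.shape[0]],
                raw=means[:, j],
                background=None,
            )
        )
    return traces
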