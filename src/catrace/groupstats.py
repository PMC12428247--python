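"""Group pooling and two-tailed Mann-Whitney comparisons.

Cells from the two lines of each diagnosis are pooled into single ASD and
control samples per condition, and each metric is compared with a
two-tailed Mann-Whitney U test. The reported U is min(U1, U2) with
midranks for ties. Exact p-values come from the permutation null when
n1 + n2 <= 20 and the data are tie-free; otherwise the normal approximation
with tie-corrected variance and continuity correction is used. The default
comparison unit is the cell — the published significance levels (p <= 1e-4)
are only attainable at cell-level n; replicate-level testing is available
by configuration. Responder fractions are always compared at replicate
level, since a cell's responder flag is binary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .kinetics import ALL_METRICS, FRACTION_METRIC, replicate_responder_percent
from .protocol import AnalysisConfig

logger = logging.getLogger(__name__)


@dataclass
class GroupSummary:
    group: str
    mean: float
    sem: float
    n: int
    sem_unit: str


@dataclass
class ComparisonResult:
    stage: str
    stimulus: str
    metric: str
    summaries: tuple[GroupSummary, GroupSummary]
    U: float
    p_two_tailed: float
    n_per_group: tuple[int, int]
    test_unit: str
    p_adjusted: float | None = None


def mann_whitney_u(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test; returns (min(U1, U2), p).

    mode: "exact" (permutation null; requires tie-free data), "asymptotic"
    (normal approximation, tie-corrected variance, continuity correction),
    or "auto" (exact when n1 + n2 <= 20 and tie-free). Identical samples
    yield U = n1*n2/2, p = 1 with a warning. p is clipped to (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        logger.warning("all observations identical; U at its midpoint, p = 1")
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    if mode == "exact" and has_ties:
        logger.warning("ties present; falling back to the normal approximation")
        mode = "asymptotic"
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    u1 = float(res.statistic)
    u = min(u1, x.size * y.size - u1)
    p = float(min(max(res.pvalue, np.finfo(float).tiny), 1.0))
    return u, p


def pool_groups(
    metrics: pd.DataFrame, metric: str, unit: str = "cell"
) -> dict[str, np.ndarray]:
    """Per-group observation vectors for one metric at the given unit.

    unit="cell" pools every cell; unit="replicate" reduces each replicate
    (line x run) to its mean first. The responder metric is always
    replicate-level percentages.
    """
    out: dict[str, np.ndarray] = {}
    for group, sub in metrics.groupby("group", sort=False):
        if metric == FRACTION_METRIC:
            values = replicate_responder_percent(sub).to_numpy()
        elif unit == "replicate":
            values = (
                sub.groupby(
                    sub["line_id"].astype(str) + "/" + sub["replicate_id"].astype(str)
                )[metric]
                .mean()
                .to_numpy()
            )
        else:
            values = sub[metric].to_numpy(dtype=float)
        if values.size == 0:
            raise ValidationError(f"group {group}: no observations for {metric}")
        out[str(group)] = values
    return out


def _sem(values: np.ndarray) -> float:
    if values.size < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / np.sqrt(values.size))


def compare_conditions(
    metrics: pd.DataFrame,
    config: AnalysisConfig | None = None,
    adjust: str = "none",
) -> list[ComparisonResult]:
    """One ComparisonResult per (stage, stimulus) x metric.

    Metrics: the two window maxima, the two times-to-maximum (at
    ``config.test_unit``), and the replicate-level responder percentage.
    ``adjust="bh"`` additionally reports Benjamini-Hochberg adjusted
    p-values across all comparisons (off by default; the standard analysis
    applies none).
    """
    config = config or AnalysisConfig()
    if adjust not in ("none", "bh"):
        raise ValidationError("adjust must be 'none' or 'bh'")
    results: list[ComparisonResult] = []
    for (stage, stimulus), sub in metrics.groupby(["stage", "stimulus"], sort=False):
        groups = sorted(sub["group"].unique())
        if len(groups) != 2:
            raise ValidationError(
                f"{stage}/{stimulus}: need exactly two groups, found {groups}"
            )
        for metric in ALL_METRICS:
            unit = "replicate" if metric == FRACTION_METRIC else config.test_unit
            samples = pool_groups(sub, metric, unit=unit)
            a, b = (samples[g] for g in groups)
            u, p = mann_whitney_u(a, b)
            summaries = tuple(
                GroupSummary(
                    group=g,
                    mean=float(samples[g].mean()),
                    sem=_sem(samples[g]),
                    n=int(samples[g].size),
                    sem_unit=unit,
                )
                for g in groups
            )
            results.append(
                ComparisonResult(
                    stage=str(stage),
                    stimulus=str(stimulus),
                    metric=metric,
                    summaries=summaries,  # type: ignore[arg-type]
                    U=u,
                    p_two_tailed=p,
                    n_per_group=(int(a.size), int(b.size)),
                    test_unit=unit,
                )
            )
    if adjust == "bh" and results:
        adjusted = multipletests([r.p_two_tailed for r in results], method="fdr_bh")[1]
        for r, q in zip(results, adjusted):
            r.p_adjusted = float(q)
    return results
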