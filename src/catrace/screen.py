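"""Stage-selection screen over differential-expression tables.

Given per-stage DEG tables (gene, stage, log2FC, q-value) from a four-stage
differentiation course (iPSC, NI, NSP, Diff), the screen tallies significant
genes per stage, intersects them with a user-supplied calcium-annotation
gene set, computes upper-tail hypergeometric over-representation p-values
(phyper-style, in log space), applies Benjamini-Hochberg correction across
stages, and ranks stages by their annotated-DEG counts to pick where
functional follow-up should concentrate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    stage: str
    k: int  # annotated significant genes
    K: int  # annotation-set size within the universe
    n: int  # significant genes within the universe
    N: int  # universe size
    p_hyper: float
    q_bh: float | None = None


def validate_deg_table(df: pd.DataFrame) -> pd.DataFrame:
    required = {"gene", "stage", "log2fc", "qvalue"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"DEG table missing columns {sorted(missing)}")
    q = df["qvalue"].to_numpy(dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValidationError("qvalue outside [0, 1]")
    return df


def count_stage_degs(df: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Per-stage totals of significant genes, split by log2FC sign.

    A significant gene with log2FC exactly 0 counts toward the total but
    neither direction (warned).
    """
    validate_deg_table(df)
    sig = df[df["qvalue"] <= q_threshold]
    n_zero = int((sig["log2fc"] == 0).sum())
    if n_zero:
        logger.warning("%d significant genes with log2fc == 0 counted as neither direction", n_zero)
    rows = []
    for stage in df["stage"].unique():
        s = sig[sig["stage"] == stage]
        rows.append(
            {
                "stage": stage,
                "total": int(len(s)),
                "up": int((s["log2fc"] > 0).sum()),
                "down": int((s["log2fc"] < 0).sum()),
            }
        )
    return pd.DataFrame(rows)


def hypergeometric_enrichment(
    deg_genes: Iterable[str],
    annotation: Iterable[str],
    universe: Iterable[str],
    stage: str = "",
) -> EnrichmentResult:
    """Upper-tail over-representation p = P[X >= k], X ~ Hypergeom(N, K, n).

    Genes outside the universe are dropped with a warning; the survival
    function is evaluated in log space for stability at extreme p.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty gene universe")
    deg = set(deg_genes)
    outside = deg - universe
    if outside:
        logger.warning("%d DEGs outside the universe dropped", len(outside))
        deg &= universe
    if not deg:
        raise ValidationError("no significant genes within the universe")
    ann = set(annotation) & universe
    N, K, n = len(universe), len(ann), len(deg)
    k = len(deg & ann)
    p = float(np.exp(stats.hypergeom.logsf(k - 1, N, K, n)))
    p = min(max(p, 0.0), 1.0)
    return EnrichmentResult(stage=stage, k=k, K=K, n=n, N=N, p_hyper=p)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, monotone and capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_stages(results: Sequence[EnrichmentResult], top_k: int) -> list[str]:
    """Stages ranked by annotated-DEG count; ties broken by smaller p, then name."""
    if top_k > len(results):
        logger.warning("top_k exceeds the number of stages; returning all")
        top_k = len(results)
    ranked = sorted(results, key=lambda r: (-r.k, r.p_hyper, r.stage))
    return [r.stage for r in ranked[:top_k]]


def screen_stages(
    deg_table: pd.DataFrame,
    annotation: Iterable[str],
    universe: Iterable[str] | None = None,
    q_threshold: float = 0.05,
    top_k: int = 2,
) -> tuple[pd.DataFrame, list[str]]:
    """Full screen: tallies, per-stage enrichment with BH, ranked selection.

    The universe defaults to every gene appearing in the expression table
    (significant or not).
    """
    validate_deg_table(deg_table)
    universe = set(universe) if universe is not None else set(deg_table["gene"])
    annotation = set(annotation)
    counts = count_stage_degs(deg_table, q_threshold)
    sig = deg_table[deg_table["qvalue"] <= q_threshold]
    results = []
    for stage in counts["stage"]:
        genes = set(sig.loc[sig["stage"] == stage, "gene"])
        if not genes:
            logger.warning("%s: no significant genes; stage excluded from enrichment", stage)
            continue
        results.append(
            hypergeometric_enrichment(genes, annotation, universe, stage=str(stage))
        )
    if not results:
        raise ValidationError("no stage has significant genes at this threshold")
    qs = bh_adjust([r.p_hyper for r in results])
    for r, q in zip(results, qs):
        r.q_bh = float(q)
    table = pd.DataFrame([r.__dict__ for r in results]).merge(counts, on="stage")
    ranked = select_stages(results, top_k)
    return table, ranked
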