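"""Depth-saturation result surfaces.

Three summaries characterize how much a library's depth matters:

* detection — how many of the annotated genes receive at least one read
  at each depth (transcriptome coverage, a rarefaction curve);
* distribution percentiles — the 5/25/50/75/95 percentiles of log2
  expression at each depth, showing how the expression distribution
  shifts as depth drops;
* reliability — Pearson correlation of log2(RPKM) between each depth
  and the full-depth reference, overall and stratified by the reference
  expression quartile (Q1 = bottom 25% .. Q4 = top 25%). Genes with zero
  expression in either profile are excluded from these correlations;
  quartile membership is fixed by the reference profile.

Replicate agreement at one depth is measured as all pairwise Pearson
correlations of raw (untransformed) RPKM — zeros kept, since the
zero-exclusion rule applies only to cross-depth comparisons.

Correlations at two strata can be compared with Fisher's r-to-z test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import ExpressionProfile

PERCENTILES = (5, 25, 50, 75, 95)


# ---------------------------------------------------------------------------
# detection

def detection_percent(n_detected: float, n_annotated: int) -> float:
    """Percentage of the annotated universe detected."""
    if n_detected > n_annotated:
        raise ValueError(
            f"n_detected ({n_detected}) exceeds n_annotated ({n_annotated})"
        )
    return 100.0 * n_detected / n_annotated


def detection_report(
    profiles: Sequence[ExpressionProfile], n_annotated: int
) -> pd.DataFrame:
    """Detected-gene counts and percentages per (sample, depth).

    A gene is detected iff its RPKM is positive (>= 1 assigned read).
    Replicates at the same depth are summarized by the mean detected
    count, reported with its min/max range.
    """
    rows = []
    per_cell: dict[tuple, list[int]] = {}
    for p in profiles:
        n_det = int((p.rpkm > 0).sum())
        if n_det > n_annotated:
            raise ValueError(
                f"profile {p.label} detects {n_det} genes, more than the "
                f"annotated universe of {n_annotated}"
            )
        per_cell.setdefault((p.sample, p.depth), []).append(n_det)
    for (sample, depth), dets in per_cell.items():
        mean_det = float(np.mean(dets))
        rows.append(
            {
                "sample": sample,
                "depth": depth,
                "n_detected": mean_det,
                "n_detected_min": min(dets),
                "n_detected_max": max(dets),
                "n_replicates": len(dets),
                "n_annotated": n_annotated,
                "percent_detected": detection_percent(mean_det, n_annotated),
            }
        )
    return pd.DataFrame(rows)


def detection_report_from_counts(
    counts: Sequence[tuple[str, int | float | str, int]], n_annotated: int
) -> pd.DataFrame:
    """Detection report from published (sample, depth, n_detected) rows."""
    rows = []
    for sample, depth, n_det in counts:
        rows.append(
            {
                "sample": sample,
                "depth": depth,
                "n_detected": n_det,
                "n_annotated": n_annotated,
                "percent_detected": detection_percent(n_det, n_annotated),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# quartiles

def assign_quartiles(reference: ExpressionProfile) -> pd.Series:
    """Expression quartile (1..4) of every expressed reference gene.

    Genes are ranked by RPKM ascending (ties broken by gene id) and the
    ranks are split into four contiguous blocks as equal as integer
    division allows; block 4 holds the top 25%.
    """
    expressed = reference.rpkm[reference.rpkm > 0]
    n = len(expressed)
    if n < 4:
        raise ValueError(f"need at least 4 expressed genes, got {n}")
    order = expressed.reset_index()
    order.columns = ["gene_id", "rpkm"]
    order = order.sort_values(["rpkm", "gene_id"], kind="mergesort")
    base, extra = divmod(n, 4)
    sizes = [base + (1 if q < extra else 0) for q in range(4)]
    labels = np.repeat(np.arange(1, 5), sizes)
    return pd.Series(labels, index=pd.Index(order["gene_id"], name="gene_id"), name="quartile")


# ---------------------------------------------------------------------------
# correlations

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(stats.pearsonr(x, y).statistic)


def depth_correlation(
    low: ExpressionProfile,
    reference: ExpressionProfile,
    quartiles: pd.Series | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlation of log2(RPKM) between a lower depth and the reference.

    Computed over genes expressed in BOTH profiles, overall and within
    each reference-defined quartile. Strata with fewer than 3 common
    expressed genes get r = NaN (their n is still reported).
    """
    if not low.rpkm.index.equals(reference.rpkm.index):
        raise ValueError("profiles cover different gene sets")
    if quartiles is None:
        quartiles = assign_quartiles(reference)
    common = low.rpkm.index[(low.rpkm > 0) & (reference.rpkm > 0)]
    lx = np.log2(low.rpkm[common].to_numpy())
    ly = np.log2(reference.rpkm[common].to_numpy())

    def corr(x: np.ndarray, y: np.ndarray) -> float:
        if len(x) < 3:
            return float("nan")
        if method == "spearman":
            return float(stats.spearmanr(x, y).statistic)
        return _pearson(x, y)

    rows = [
        {
            "sample": low.sample,
            "depth": low.depth,
            "stratum": "overall",
            "r": corr(lx, ly),
            "n_genes": len(common),
        }
    ]
    qmap = quartiles.reindex(common)
    for q in (1, 2, 3, 4):
        mask = (qmap == q).to_numpy()
        rows.append(
            {
                "sample": low.sample,
                "depth": low.depth,
                "stratum": f"Q{q}",
                "r": corr(lx[mask], ly[mask]),
                "n_genes": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def replicate_correlations(
    replicates: Sequence[ExpressionProfile],
) -> pd.DataFrame:
    """All pairwise Pearson correlations of per-gene RPKM between replicates.

    Raw RPKM, zeros kept (a gene undetected in one replicate contributes
    a zero there). Returns one row per unordered pair.
    """
    if len(replicates) < 2:
        return pd.DataFrame(columns=["rep_a", "rep_b", "r"])
    universe = replicates[0].rpkm.index
    for p in replicates[1:]:
        if not p.rpkm.index.equals(universe):
            raise ValueError("replicates cover different gene sets")
    rows = []
    for a, b in combinations(range(len(replicates)), 2):
        r = _pearson(
            replicates[a].rpkm.to_numpy(), replicates[b].rpkm.to_numpy()
        )
        rows.append(
            {
                "rep_a": replicates[a].replicate if replicates[a].replicate is not None else a,
                "rep_b": replicates[b].replicate if replicates[b].replicate is not None else b,
                "r": r,
            }
        )
    return pd.DataFrame(rows)


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher r-to-z test for the difference of two independent correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); two-sided
    normal p-value.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both sample sizes must exceed 3")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| must be < 1 (atanh is undefined at 1)")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * stats.norm.sf(abs(z))
    return z, min(float(p), 1.0)


# ---------------------------------------------------------------------------
# percentiles

def percentile_summary(
    profile: ExpressionProfile, counts: pd.Series | None = None
) -> pd.DataFrame:
    """Percentiles {5,25,50,75,95} of log2 expression over expressed genes.

    Linear interpolation between order statistics. By default the log2
    RPKM scale is summarized; pass a per-gene ``counts`` series to
    summarize log2 raw read counts instead.
    """
    if counts is not None:
        c = counts.to_numpy(dtype=float)
        vals = np.log2(c[c > 0])
    else:
        vals = profile.log2_rpkm.dropna().to_numpy()
    if len(vals) == 0:
        raise ValueError("profile has no expressed genes")
    pcts = np.percentile(vals, PERCENTILES, method="linear")
    row = {"sample": profile.sample, "depth": profile.depth, "replicate": profile.replicate}
    row.update({f"p{p}": v for p, v in zip(PERCENTILES, pcts)})
    return pd.DataFrame([row])
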