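"""Screening thresholds, criterion intersection, and SNP-to-gene linkage.

Each windowed index gets a genome-wide Tukey upper fence (Q3 + 1.5*IQR with
type-7 quantiles); a SNP is screened when it exceeds all three fences. A SNP
is linked to a gene when it overlaps, or lies within 5 kbp of, one of the
gene's exons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GeneAnnotation

__all__ = [
    "ScreeningThresholds",
    "upper_fence_threshold",
    "compute_thresholds",
    "screen_loci",
    "link_snps_to_genes",
]

INDEX_COLUMNS = ("u_bar", "gst_bar", "ddprime_bar")


@dataclass
class ScreeningThresholds:
    """Per-index quartiles and upper fences, computed genome-wide."""

    q1: dict[str, float]
    q3: dict[str, float]
    fence: dict[str, float]

    def iqr(self, index: str) -> float:
        return self.q3[index] - self.q1[index]


def upper_fence_threshold(
    values: np.ndarray, multiplier: float = 1.5
) -> float:
    """Tukey upper fence Q3 + multiplier*(Q3 - Q1), type-7 quantiles."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 4:
        raise ValueError("need at least 4 finite values to place a fence")
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation
    return float(q3 + multiplier * (q3 - q1))


def compute_thresholds(
    stats: pd.DataFrame, multiplier: float = 1.5
) -> ScreeningThresholds:
    q1, q3, fence = {}, {}, {}
    for col in INDEX_COLUMNS:
        vals = stats[col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 4:
            raise ValueError(f"fewer than 4 finite values for {col}")
        a, b = np.quantile(vals, [0.25, 0.75])
        q1[col], q3[col] = float(a), float(b)
        fence[col] = float(b + multiplier * (b - a))
    return ScreeningThresholds(q1, q3, fence)


def screen_loci(
    stats: pd.DataFrame,
    thresholds: ScreeningThresholds,
    *,
    strict: bool = True,
) -> pd.DataFrame:
    """Flag loci against the three fences and intersect the criteria.

    Returns a copy of ``stats`` with boolean columns pass_u, pass_gst,
    pass_ddprime and ``screened`` (the three-way AND). The fence comparison
    is strict ">" by default.
    """
    out = stats.copy()
    flags = []
    for col, flag in zip(
        INDEX_COLUMNS, ("pass_u", "pass_gst", "pass_ddprime")
    ):
        v = out[col].to_numpy(dtype=float)
        f = thresholds.fence[col]
        out[flag] = v > f if strict else v >= f
        flags.append(flag)
    out["screened"] = out[flags[0]] & out[flags[1]] & out[flags[2]]
    return out


def venn_counts(screened: pd.DataFrame) -> dict[str, int]:
    """Counts of the 7 non-empty regions of the three criterion sets."""
    a = screened["pass_u"].to_numpy()
    b = screened["pass_gst"].to_numpy()
    c = screened["pass_ddprime"].to_numpy()
    return {
        "u_only": int(np.sum(a & ~b & ~c)),
        "gst_only": int(np.sum(~a & b & ~c)),
        "ddprime_only": int(np.sum(~a & ~b & c)),
        "u_gst": int(np.sum(a & b & ~c)),
        "u_ddprime": int(np.sum(a & ~b & c)),
        "gst_ddprime": int(np.sum(~a & b & c)),
        "all_three": int(np.sum(a & b & c)),
    }


def link_snps_to_genes(
    scaffolds: np.ndarray,
    positions: np.ndarray,
    annot: GeneAnnotation,
    max_dist: int = 5000,
) -> list[set[str]]:
    """Per SNP, the set of genes with an exon overlapping or within max_dist bp.

    SNP positions are 1-based; exons are 0-based half-open, so a SNP at
    1-based position p occupies the 0-based point p-1 and overlaps exon
    [start, end) when start <= p-1 < end. The gap to a non-overlapping exon
    is measured between the point and the interval boundary; a gap of
    exactly ``max_dist`` still links ("within 5 kbp" read inclusively).
    """
    positions = np.asarray(positions, dtype=np.int64)
    out: list[set[str]] = [set() for _ in range(len(positions))]
    exons = annot.exons
    for scf, sub in exons.groupby("scaffold", sort=False):
        snp_idx = np.flatnonzero(scaffolds == scf)
        if snp_idx.size == 0:
            continue
        pts = positions[snp_idx] - 1  # 0-based point coordinate
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        genes = sub["gene_id"].to_numpy(dtype=object)
        # distance 0 when start <= pt < end; else gap to nearest boundary
        for s, e, g in zip(starts, ends, genes):
            gap = np.maximum(s - pts, 0) + np.maximum(pts - (e - 1), 0)
            hit = gap <= max_dist
            for i in snp_idx[hit]:
                out[i].add(g)
    return out
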