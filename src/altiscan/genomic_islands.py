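"""Hitchhiking-region ("genomic island") detection on the windowed-U curve.

Consecutive SNPs on one scaffold are joined by straight lines (unless more
than ``gap`` bp apart); every maximal stretch where the curve is strictly
positive is an island. Island boundaries fall at linearly interpolated
x-intercepts, at gap breaks (the last observed SNP position — no
extrapolation into unobserved sequence), or at scaffold ends. The area
between the curve and the x-axis, by the trapezoid rule on the piecewise
linear curve, ranks islands; islands with fewer than two screened SNPs are
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popgen_stats import DemeFrequencies, ALTITUDE_GROUPS

__all__ = [
    "GenomicIsland",
    "segment_islands",
    "rank_islands",
    "island_candidate_genes",
    "sliding_profile",
]


@dataclass
class GenomicIsland:
    scaffold: str
    start: float
    end: float
    area: float
    member_idx: list[int]  # indices into the stats frame, U-bar > 0 members
    n_screened: int = 0
    screened_idx: list[int] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    rank: int | None = None


def _segment_runs(scaffolds: np.ndarray, positions: np.ndarray, gap: int):
    """Yield (start, stop) index ranges of gap-connected same-scaffold runs."""
    n = len(positions)
    start = 0
    for i in range(1, n + 1):
        if (
            i == n
            or scaffolds[i] != scaffolds[start]
            or positions[i] - positions[i - 1] > gap
        ):
            yield start, i
            start = i


def segment_islands(
    scaffolds: np.ndarray,
    positions: np.ndarray,
    u_bar: np.ndarray,
    gap: int = 4000,
) -> list[GenomicIsland]:
    """Segment the piecewise-linear U-bar curve into positive islands.

    A SNP with U-bar exactly 0 is a boundary point, not a member. A single
    isolated positive SNP (gaps on both sides) yields a degenerate island of
    zero width and zero area; it can never hold two screened SNPs and is
    discarded during ranking.
    """
    positions = np.asarray(positions, dtype=np.int64)
    u_bar = np.asarray(u_bar, dtype=float)
    if not np.all(np.isfinite(u_bar)):
        raise ValueError("U-bar values must be finite")
    islands: list[GenomicIsland] = []
    for lo, hi in _segment_runs(scaffolds, positions, gap):
        pos = positions[lo:hi].astype(float)
        if np.any(np.diff(pos) <= 0):
            raise ValueError(
                f"positions unsorted on scaffold {scaffolds[lo]!r}"
            )
        val = u_bar[lo:hi]
        scf = scaffolds[lo]
        m = hi - lo
        i = 0
        while i < m:
            if val[i] <= 0:
                i += 1
                continue
            # island start: interpolated crossing from val[i-1] <= 0, or the
            # run boundary (gap break / scaffold end) at pos[i]
            if i > 0 and val[i - 1] < 0:
                x0 = pos[i - 1] + (pos[i] - pos[i - 1]) * (
                    -val[i - 1] / (val[i] - val[i - 1])
                )
            elif i > 0:  # val[i-1] == 0: boundary exactly at that SNP
                x0 = pos[i - 1]
            else:
                x0 = pos[i]
            members = []
            area = 0.0
            prev_x, prev_y = x0, (0.0 if i > 0 or val[i] <= 0 else None)
            if prev_y is None:
                prev_y = val[i]  # run starts inside positive territory
            while i < m and val[i] > 0:
                area += (pos[i] - prev_x) * (prev_y + val[i]) / 2.0
                members.append(lo + i)
                prev_x, prev_y = pos[i], val[i]
                i += 1
            if i < m:
                if val[i] < 0:
                    x1 = prev_x + (pos[i] - prev_x) * (
                        prev_y / (prev_y - val[i])
                    )
                    area += (x1 - prev_x) * prev_y / 2.0
                else:  # exact zero SNP terminates the island
                    x1 = pos[i]
                    area += (x1 - prev_x) * prev_y / 2.0
            else:
                x1 = prev_x  # run end: stop at the last observed SNP
            islands.append(
                GenomicIsland(
                    scaffold=str(scf),
                    start=float(x0),
                    end=float(x1),
                    area=float(area),
                    member_idx=members,
                )
            )
    return islands


def rank_islands(
    islands: list[GenomicIsland],
    screened: np.ndarray,
    min_screened: int = 2,
) -> list[GenomicIsland]:
    """Drop islands with < min_screened screened member SNPs; rank by area.

    ``screened`` is the per-SNP boolean from the screening stage, indexed
    like the stats frame the islands were segmented from. Ties in area break
    by (scaffold, start) ascending; ranks are 1-based.
    """
    screened = np.asarray(screened, dtype=bool)
    kept = []
    for isl in islands:
        s_idx = [i for i in isl.member_idx if screened[i]]
        isl.n_screened = len(s_idx)
        isl.screened_idx = s_idx
        if isl.n_screened >= min_screened:
            kept.append(isl)
    kept.sort(key=lambda g: (-g.area, g.scaffold, g.start))
    for r, isl in enumerate(kept, start=1):
        isl.rank = r
    return kept


def island_candidate_genes(
    islands: list[GenomicIsland],
    snp_genes: list[set[str]],
    top_n: int = 20,
) -> tuple[list[GenomicIsland], pd.DataFrame]:
    """Attach candidate genes (union over screened member SNPs) and report.

    Returns the islands (genes filled in, sorted order preserved) and a
    top-N table with one row per island: rank, scaffold, start, end, area,
    n_screened, genes (comma-joined, deduplicated, sorted).
    """
    for isl in islands:
        genes: set[str] = set()
        for i in isl.screened_idx:
            genes |= snp_genes[i]
        isl.genes = sorted(genes)
    rows = [
        {
            "rank": isl.rank,
            "scaffold": isl.scaffold,
            "start": isl.start,
            "end": isl.end,
            "area": isl.area,
            "n_screened": isl.n_screened,
            "genes": ",".join(isl.genes),
        }
        for isl in islands[:top_n]
    ]
    return islands, pd.DataFrame(
        rows,
        columns=[
            "rank",
            "scaffold",
            "start",
            "end",
            "area",
            "n_screened",
            "genes",
        ],
    )


def sliding_profile(
    freqs: DemeFrequencies,
    focal_allele: np.ndarray,
    scaffolds: np.ndarray,
    positions: np.ndarray,
    scaffold: str,
    start: int,
    end: int,
    window: int = 4000,
    step: int = 1000,
) -> pd.DataFrame:
    """Sliding-window |F_deme - F_L| tracks across a region.

    Windows of ``window`` bp advance by ``step`` bp across [start, end]; at
    each window center the mean absolute focal-allele frequency difference
    from the lowest deme is reported for M1, M2, and H. Empty windows yield
    NaN.
    """
    if end <= start:
        raise ValueError("zero-width region")
    idx = np.flatnonzero(
        (scaffolds == scaffold) & (positions >= start) & (positions <= end)
    )
    pos = positions[idx].astype(np.int64)
    rows_idx = np.arange(len(focal_allele))
    f = {
        g: freqs.group(g)[rows_idx, focal_allele][idx]
        for g in ALTITUDE_GROUPS
    }
    diffs = {g: np.abs(f[g] - f["L"]) for g in ("M1", "M2", "H")}
    half = window / 2.0
    centers = np.arange(start + half, end - half + step, step, dtype=float)
    if centers.size == 0:
        centers = np.array([(start + end) / 2.0])
    out = []
    for c in centers:
        inside = (pos >= c - half) & (pos <= c + half)
        row = {"scaffold": scaffold, "center": c, "n_snps": int(inside.sum())}
        for g in ("M1", "M2", "H"):
            row[f"diff_{g}"] = (
                float(np.mean(diffs[g][inside])) if inside.any() else np.nan
            )
        out.append(row)
    return pd.DataFrame(out)
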