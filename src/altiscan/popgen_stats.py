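"""Per-locus and windowed statistics for the altitudinal cline scan.

The screen rests on three per-SNP indices, each averaged over a 4-kbp window
(2 kbp each side of the focal SNP):

* ``U`` — rewards a large lowest-vs-highest frequency difference whose
  intermediate deme frequencies change monotonically along the transect;
  range [-1, 1].
* Hedrick's standardized G'ST between the lowest and highest demes.
* ``dD'`` — increase of the derived-allele frequency (minor allele of the
  pooled low-altitude reference demes) in the highest deme, weighted by the
  probability 1 - D_R that the allele really is derived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .io_formats import GenotypeTable, TransectDesign

__all__ = [
    "DemeFrequencies",
    "pop_allele_frequencies",
    "select_focal_allele",
    "u_index",
    "gst_prime_pair",
    "derived_allele_freq",
    "delta_d_prime",
    "window_mean",
    "compute_locus_stats",
    "diversity_summary",
    "multilocus_gst_matrix",
]

MAX_ALLELES = 4

#: Row order of the altitude groups in DemeFrequencies.freqs.
ALTITUDE_GROUPS = ("L", "M1", "M2", "H")
POOLED_REFERENCE = "REF"


@dataclass
class DemeFrequencies:
    """Allele-frequency vectors per group per locus.

    ``freqs`` has shape (n_groups, n_loci, MAX_ALLELES) with NaN beyond a
    locus's allele count; ``counts`` holds called chromosomes per group and
    locus. Groups are the four altitude demes L, M1, M2, H followed by the
    pooled reference group and then any extra demes in ``group_labels``.
    """

    group_labels: list[str]
    freqs: np.ndarray
    counts: np.ndarray
    n_alleles: np.ndarray

    def group(self, label: str) -> np.ndarray:
        return self.freqs[self.group_labels.index(label)]


def _group_freqs(
    calls: np.ndarray, sample_idx: list[int], n_alleles: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Allele counts over called chromosomes for a set of samples."""
    sub = calls[sample_idx]  # (n, loci, 2)
    n_loci = sub.shape[1]
    counts = np.zeros((n_loci, MAX_ALLELES), dtype=np.int64)
    for a in range(MAX_ALLELES):
        counts[:, a] = np.sum(sub == a, axis=(0, 2))
    total = counts.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts / total[:, None]
    for j in range(n_loci):
        freqs[j, n_alleles[j]:] = np.nan
    return freqs, total


def pop_allele_frequencies(
    table: GenotypeTable, design: TransectDesign
) -> DemeFrequencies:
    """Per-deme allele frequencies, with reference demes pooled by counts.

    Reference pooling sums allele counts over all reference demes before
    dividing (sample-size weighted), mirroring pooling the individuals.
    """
    nal = table.n_alleles()
    sample_pos = {s: i for i, s in enumerate(table.samples)}
    labels: list[str] = list(ALTITUDE_GROUPS)
    groups: list[list[int]] = []
    for deme in design.altitude_demes():
        members = design.samples_in(deme)
        if not members:
            raise ValueError(f"altitude deme {deme!r} has no samples")
        groups.append([sample_pos[s] for s in members])
    ref_samples: list[int] = []
    for deme in design.reference_demes():
        ref_samples.extend(sample_pos[s] for s in design.samples_in(deme))
    if ref_samples:
        labels.append(POOLED_REFERENCE)
        groups.append(ref_samples)
    freqs = np.full((len(groups), table.n_loci, MAX_ALLELES), np.nan)
    counts = np.zeros((len(groups), table.n_loci), dtype=np.int64)
    for gi, idx in enumerate(groups):
        f, tot = _group_freqs(table.calls, idx, nal)
        zero = np.flatnonzero(tot == 0)
        if zero.size:
            j = zero[0]
            raise ValueError(
                f"group {labels[gi]!r} has zero called chromosomes at locus "
                f"{table.scaffolds[j]}:{table.positions[j]}"
            )
        freqs[gi] = f
        counts[gi] = tot.astype(np.int64)
    return DemeFrequencies(labels, freqs, counts, nal)


def select_focal_allele(freqs: DemeFrequencies) -> np.ndarray:
    """Per locus, the allele with the largest |F_L - F_H|; ties -> lowest index."""
    fl = freqs.group("L")
    fh = freqs.group("H")
    diff = np.abs(fl - fh)
    diff = np.where(np.isnan(diff), -np.inf, diff)
    return np.argmax(diff, axis=1)  # argmax returns the first maximal index


def u_index(f_l, f_m1, f_m2, f_h, *, halved: bool = False):
    """Unidirectionality index of a four-deme frequency series.

    U = |F_L-F_H| + (|F_L-F_H| - |F_L-F_M1| - |F_M1-F_M2| - |F_M2-F_H|) / 2

    Equals 1 for a monotone series spanning the full [0, 1] range, 0 for a
    flat series, and -1 for the maximal zigzag (0,1,0,0). ``halved=True``
    selects the alternative reading dividing the whole expression by 2
    (range [-0.5, 0.5]).
    """
    f_l, f_m1, f_m2, f_h = map(np.asarray, (f_l, f_m1, f_m2, f_h))
    for arr in (f_l, f_m1, f_m2, f_h):
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
    d = np.abs(f_l - f_h)
    steps = np.abs(f_l - f_m1) + np.abs(f_m1 - f_m2) + np.abs(f_m2 - f_h)
    if halved:
        return (d + d - steps) / 2.0
    return d + (d - steps) / 2.0


def gst_prime_pair(p: np.ndarray, q: np.ndarray) -> float | np.ndarray:
    """Hedrick's standardized G'ST between two demes (k = 2).

    H_S = mean of within-deme expected heterozygosities, H_T from the
    unweighted mean frequency vector; G_ST = (H_T - H_S)/H_T is rescaled by
    its maximum attainable value given H_S. Returns 0 where H_T = 0.
    Accepts single vectors or (n_loci, n_alleles) arrays (NaN-padded).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    hs = 1.0 - 0.5 * (np.nansum(p**2, axis=-1) + np.nansum(q**2, axis=-1))
    ht = 1.0 - np.nansum(((p + q) / 2.0) ** 2, axis=-1)
    k = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        gst = (ht - hs) / ht
        gprime = gst * (k - 1.0 + hs) / ((k - 1.0) * (1.0 - hs))
    gprime = np.where(ht <= 0, 0.0, gprime)
    # fixed difference: hs == 1 impossible; hs -> denominator 0 only if both
    # demes are maximally heterozygous and identical, where gst == 0 anyway
    gprime = np.where(np.isnan(gprime), 0.0, gprime)
    if gprime.ndim == 0:
        return float(gprime)
    return gprime


def derived_allele_freq(freqs: DemeFrequencies) -> tuple[np.ndarray, np.ndarray]:
    """Derived-allele frequencies (D_H, D_R) per locus.

    The derived allele is the minor allele of the pooled reference group
    (ties break to the lowest allele index), so D_R is in [0, 0.5]. For tri-
    and tetra-allelic loci the derived frequency is 1 minus the major-allele
    frequency, computed separately in the reference pool and the highest
    deme.
    """
    ref = freqs.group(POOLED_REFERENCE)
    high = freqs.group("H")
    n_loci = ref.shape[0]
    d_r = np.empty(n_loci)
    d_h = np.empty(n_loci)
    biallelic = freqs.n_alleles == 2
    # biallelic: the reference-minor allele, tracked in both groups
    ref2 = ref[:, :2]
    minor = np.where(ref2[:, 1] < ref2[:, 0], 1, 0)  # tie (=) -> index 0
    rows = np.arange(n_loci)
    d_r[biallelic] = ref2[rows, minor][biallelic]
    d_h[biallelic] = high[:, :2][rows, minor][biallelic]
    # multiallelic: 1 - major frequency within each group separately
    multi = ~biallelic
    if np.any(multi):
        d_r[multi] = 1.0 - np.nanmax(ref[multi], axis=1)
        d_h[multi] = 1.0 - np.nanmax(high[multi], axis=1)
    return d_h, d_r


def delta_d_prime(d_h, d_r, *, strict: bool = True):
    """dD' = |D_H - D_R| * (1 - D_R), the reference-weighted DAF increment.

    With ``strict`` (default) D_R must lie in [0, 0.5], the range of the
    biallelic minor-allele rule. The multiallelic rule (1 minus the major
    frequency) can legitimately exceed 0.5 when no allele is in the
    majority; pass ``strict=False`` there, where the formula remains in
    [0, 1] for any D_R in [0, 1].
    """
    d_h = np.asarray(d_h, dtype=float)
    d_r = np.asarray(d_r, dtype=float)
    if np.any((d_h < 0) | (d_h > 1)):
        raise ValueError("D_H must lie in [0, 1]")
    hi = 0.5 if strict else 1.0
    if np.any((d_r < 0) | (d_r > hi + 1e-12)):
        raise ValueError(f"D_R must lie in [0, {hi}]")
    out = np.abs(d_h - d_r) * (1.0 - d_r)
    return float(out) if out.ndim == 0 else out


def window_mean(
    scaffolds: np.ndarray,
    positions: np.ndarray,
    values: np.ndarray,
    half_width: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of ``values`` over all SNPs within ``half_width`` bp of each SNP.

    Windows are inclusive (|delta pos| <= half_width, focal SNP included)
    and never cross scaffold boundaries. Returns (means, window SNP counts).
    Input must be sorted by (scaffold, position).
    """
    positions = np.asarray(positions, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    n = len(positions)
    out = np.empty(n)
    counts = np.empty(n, dtype=np.int64)
    start = 0
    while start < n:
        scf = scaffolds[start]
        stop = start
        while stop < n and scaffolds[stop] == scf:
            stop += 1
        pos = positions[start:stop]
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions unsorted on scaffold {scf!r}")
        vals = values[start:stop]
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        lo = np.searchsorted(pos, pos - half_width, side="left")
        hi = np.searchsorted(pos, pos + half_width, side="right")
        out[start:stop] = (csum[hi] - csum[lo]) / (hi - lo)
        counts[start:stop] = hi - lo
        start = stop
    return out, counts


def compute_locus_stats(
    table: GenotypeTable,
    design: TransectDesign,
    half_width: int = 2000,
    *,
    halved_u: bool = False,
) -> pd.DataFrame:
    """All per-locus indices and their windowed means, as one DataFrame.

    Columns: scaffold, position, focal_allele, u, gst, ddprime, u_bar,
    gst_bar, ddprime_bar, n_window.
    """
    freqs = pop_allele_frequencies(table, design)
    focal = select_focal_allele(freqs)
    rows = np.arange(table.n_loci)
    f = {g: freqs.group(g)[rows, focal] for g in ALTITUDE_GROUPS}
    u = u_index(f["L"], f["M1"], f["M2"], f["H"], halved=halved_u)
    gst = gst_prime_pair(freqs.group("L"), freqs.group("H"))
    d_h, d_r = derived_allele_freq(freqs)
    ddp = delta_d_prime(d_h, d_r, strict=False)
    u_bar, n_win = window_mean(table.scaffolds, table.positions, u, half_width)
    gst_bar, _ = window_mean(table.scaffolds, table.positions, gst, half_width)
    ddp_bar, _ = window_mean(table.scaffolds, table.positions, ddp, half_width)
    return pd.DataFrame(
        {
            "scaffold": table.scaffolds,
            "position": table.positions,
            "focal_allele": focal,
            "u": u,
            "gst": gst,
            "ddprime": ddp,
            "u_bar": u_bar,
            "gst_bar": gst_bar,
            "ddprime_bar": ddp_bar,
            "n_window": n_win,
        }
    )


def _per_deme_locus_he(
    table: GenotypeTable, design: TransectDesign
) -> dict[str, np.ndarray]:
    nal = table.n_alleles()
    sample_pos = {s: i for i, s in enumerate(table.samples)}
    out = {}
    for deme in sorted(design.role_of):
        idx = [sample_pos[s] for s in design.samples_in(deme)]
        if len(idx) < 2:
            raise ValueError(f"deme {deme!r} has fewer than 2 samples")
        f, _ = _group_freqs(table.calls, idx, nal)
        out[deme] = 1.0 - np.nansum(f**2, axis=1)
    return out


def diversity_summary(
    table: GenotypeTable, design: TransectDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-deme diversity (P, He, Ho) and pairwise Wilcoxon tests on He.

    P is the fraction of loci polymorphic within the deme, He the mean
    expected heterozygosity, Ho the mean fraction of heterozygous
    individuals. The second table holds two-sided Wilcoxon signed-rank
    p-values on per-locus He between the four altitude demes of the
    transect, Bonferroni-corrected over the 6 pairs.
    """
    he_by_deme = _per_deme_locus_he(table, design)
    sample_pos = {s: i for i, s in enumerate(table.samples)}
    rows = []
    for deme in sorted(design.role_of):
        idx = [sample_pos[s] for s in design.samples_in(deme)]
        calls = table.calls[idx]
        called = np.all(calls >= 0, axis=2)
        het = (calls[:, :, 0] != calls[:, :, 1]) & called
        with np.errstate(invalid="ignore"):
            ho = np.sum(het, axis=0) / np.sum(called, axis=0)
        he = he_by_deme[deme]
        rows.append(
            {
                "deme": deme,
                "role": design.role_of[deme],
                "altitude_m": design.altitude_of[deme],
                "n_samples": len(idx),
                "P": float(np.mean(he > 0)),
                "He": float(np.mean(he)),
                "Ho": float(np.nanmean(ho)),
            }
        )
    summary = pd.DataFrame(rows)

    alt_demes = design.altitude_demes()
    pairs = [
        (alt_demes[i], alt_demes[j])
        for i in range(len(alt_demes))
        for j in range(i + 1, len(alt_demes))
    ]
    test_rows = []
    for a, b in pairs:
        diff = he_by_deme[a] - he_by_deme[b]
        if np.allclose(diff, 0):
            p = 1.0
        else:
            p = float(wilcoxon(he_by_deme[a], he_by_deme[b]).pvalue)
        test_rows.append(
            {
                "deme_a": a,
                "deme_b": b,
                "p_value": p,
                "p_bonferroni": min(1.0, p * len(pairs)),
            }
        )
    return summary, pd.DataFrame(test_rows)


def multilocus_gst_matrix(
    table: GenotypeTable, design: TransectDesign
) -> pd.DataFrame:
    """Pairwise multilocus Hedrick's G'ST between all demes.

    H_S and H_T are averaged across loci before forming G_ST and applying
    the k = 2 standardization (the standard multilocus construction).
    """
    nal = table.n_alleles()
    sample_pos = {s: i for i, s in enumerate(table.samples)}
    demes = sorted(design.role_of)
    freqs = {
        d: _group_freqs(
            table.calls, [sample_pos[s] for s in design.samples_in(d)], nal
        )[0]
        for d in demes
    }
    mat = pd.DataFrame(0.0, index=demes, columns=demes)
    for i, a in enumerate(demes):
        for b in demes[i + 1:]:
            p, q = freqs[a], freqs[b]
            hs = 1.0 - 0.5 * (
                np.nansum(p**2, axis=1) + np.nansum(q**2, axis=1)
            )
            ht = 1.0 - np.nansum(((p + q) / 2.0) ** 2, axis=1)
            hs_bar = float(np.mean(hs))
            ht_bar = float(np.mean(ht))
            if ht_bar <= 0:
                g = 0.0
            else:
                gst = (ht_bar - hs_bar) / ht_bar
                g = gst * (1.0 + hs_bar) / (1.0 - hs_bar)
            mat.loc[a, b] = mat.loc[b, a] = g
    return mat
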