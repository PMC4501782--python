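"""Synthetic altitudinal-transect datasets with known truth.

The generator emulates the sampling design the scan assumes: four
altitude-ordered demes (5 diploids each) on a linear stepping-stone, plus
four pooled low-altitude reference demes (4 diploids each). Neutral loci
drift around a shared ancestral frequency via a Balding-Nichols chain;
selected loci carry a monotone frequency cline across the altitude demes;
neutral loci near a selected locus are pulled toward the cline with weight
w = exp(-d / lambda), emulating hitchhiking with distance decay. Gene and
GO annotations are tiled deterministically, with a configurable set of GO
terms enriched among genes near selected loci, so every downstream stage
has a truth table to recover.

Everything is driven by one numpy Generator: identical seeds give identical
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ALTITUDE_ROLES,
    REFERENCE_ROLE,
    GeneAnnotation,
    GenotypeTable,
    TransectDesign,
    write_exon_bed,
    write_genotype_vcf,
    write_go_map,
    write_population_map,
)

__all__ = ["SelectedLocus", "SimulationConfig", "simulate_scan_dataset",
           "write_fixture_bundle"]

NUCS = np.array(["A", "C", "G", "T"])

#: Altitudes (m) of the four transect demes and the four reference demes.
DEFAULT_ALTITUDES = (380.0, 600.0, 1000.0, 1250.0)
DEFAULT_REF_ALTITUDES = (220.0, 230.0, 370.0, 520.0)


@dataclass
class SelectedLocus:
    """A locus under altitude-dependent selection with a frequency cline."""

    scaffold: int  # scaffold index
    position: int  # 1-based bp
    f_low: float = 0.0  # selected-allele frequency in the lowest deme
    f_high: float = 1.0  # ... in the highest deme


@dataclass
class SimulationConfig:
    n_scaffolds: int = 4
    scaffold_length: int = 250_000
    mean_spacing: float = 484.0  # mean inter-SNP distance, bp
    n_per_altitude_deme: int = 5
    n_per_reference_deme: int = 4
    n_reference_demes: int = 4
    f_model: float = 0.05  # Balding-Nichols divergence of neutral drift
    rho: float = 0.8  # stepping-stone neighbor correlation, [0, 1)
    selected: list[SelectedLocus] = field(default_factory=list)
    lambda_bp: float = 2000.0  # hitchhiking decay length
    multiallelic_fraction: float = 0.016  # share of neutral loci with 3 alleles
    depth_mean: float = 20.0
    depth_dispersion: float = 10.0
    go_terms: int = 10
    enriched_terms: int = 2  # terms over-represented near selected loci
    enriched_radius: int = 10_000  # bp around a selected locus
    base_term_prob: float = 0.10
    enriched_term_prob: float = 0.90
    gene_spacing: int = 5_000  # one gene tile per this many bp
    seed: int = 0

    def validate(self) -> None:
        if self.mean_spacing <= 0 or self.lambda_bp <= 0:
            raise ValueError("spacing and lambda must be positive")
        if not 0 < self.f_model < 1:
            raise ValueError("f_model must lie in (0, 1)")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        for p in (
            self.multiallelic_fraction,
            self.base_term_prob,
            self.enriched_term_prob,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_per_altitude_deme < 1:
            raise ValueError("altitude demes need at least one sample")
        for sel in self.selected:
            if not 0 <= sel.scaffold < self.n_scaffolds:
                raise ValueError(f"selected scaffold {sel.scaffold} out of range")
            if not 1 <= sel.position <= self.scaffold_length:
                raise ValueError(
                    f"selected position {sel.position} outside scaffold "
                    f"(length {self.scaffold_length})"
                )
            if not (0 <= sel.f_low <= 1 and 0 <= sel.f_high <= 1):
                raise ValueError("cline endpoints must lie in [0, 1]")


def _balding_nichols(
    rng: np.random.Generator, p: np.ndarray, f: float
) -> np.ndarray:
    """Draw frequencies around mean p with divergence f (Beta parametrized)."""
    p = np.clip(p, 0.0, 1.0)
    interior = (p > 0) & (p < 1)
    out = p.copy()
    if np.any(interior):
        scale = (1.0 - f) / f
        a = p[interior] * scale
        b = (1.0 - p[interior]) * scale
        out[interior] = rng.beta(a, b)
    return out


def _positions(rng: np.random.Generator, cfg: SimulationConfig) -> list[np.ndarray]:
    """Exponentially spaced 1-based positions per scaffold, selected sites added."""
    per_scaffold = []
    for s in range(cfg.n_scaffolds):
        gaps = rng.exponential(cfg.mean_spacing, size=int(
            2 * cfg.scaffold_length / cfg.mean_spacing + 10
        ))
        pos = 1 + np.cumsum(np.maximum(1, np.round(gaps))).astype(np.int64)
        pos = pos[pos <= cfg.scaffold_length]
        sel_here = [x.position for x in cfg.selected if x.scaffold == s]
        if sel_here:
            pos = np.unique(np.concatenate([pos, np.array(sel_here, dtype=np.int64)]))
        per_scaffold.append(pos)
    return per_scaffold


def simulate_scan_dataset(
    cfg: SimulationConfig,
) -> tuple[GenotypeTable, TransectDesign, GeneAnnotation, pd.DataFrame]:
    """Generate one transect dataset plus its truth table.

    Returns (genotypes, design, annotation, truth). The truth table has one
    row per locus: scaffold, position, is_selected, hitchhike weight w, and
    the expected selected-allele frequency in each altitude deme and the
    pooled reference group.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    pos_per_scf = _positions(rng, cfg)
    scaffold_names = [f"scaffold_{s + 1}" for s in range(cfg.n_scaffolds)]
    scaffolds = np.concatenate(
        [
            np.full(len(p), scaffold_names[s], dtype=object)
            for s, p in enumerate(pos_per_scf)
        ]
    )
    positions = np.concatenate(pos_per_scf)
    n_loci = len(positions)

    # --- expected frequencies -------------------------------------------
    p0 = rng.uniform(0.05, 0.95, size=n_loci)
    n_alt = len(ALTITUDE_ROLES)
    neutral = np.empty((n_alt, n_loci))
    neutral[0] = _balding_nichols(rng, p0, cfg.f_model)
    f_step = cfg.f_model * (1.0 - cfg.rho)
    for j in range(1, n_alt):
        neutral[j] = _balding_nichols(rng, neutral[j - 1], f_step)
    ref_neutral = np.stack(
        [
            _balding_nichols(rng, p0, cfg.f_model)
            for _ in range(cfg.n_reference_demes)
        ]
    )

    # hitchhiking weight toward the nearest selected locus (same scaffold)
    w = np.zeros(n_loci)
    cline = np.zeros((n_alt, n_loci))
    ref_target = np.zeros(n_loci)
    is_selected = np.zeros(n_loci, dtype=bool)
    for s, scf in enumerate(scaffold_names):
        sel_here = [x for x in cfg.selected if x.scaffold == s]
        if not sel_here:
            continue
        idx = np.flatnonzero(scaffolds == scf)
        pos = positions[idx].astype(float)
        sel_pos = np.array([x.position for x in sel_here], dtype=float)
        dist = np.abs(pos[:, None] - sel_pos[None, :])
        nearest = np.argmin(dist, axis=1)
        d = dist[np.arange(len(idx)), nearest]
        w[idx] = np.exp(-d / cfg.lambda_bp)
        steps = np.linspace(0.0, 1.0, n_alt)
        for i_local, i_global in enumerate(idx):
            sel = sel_here[nearest[i_local]]
            cline[:, i_global] = sel.f_low + steps * (sel.f_high - sel.f_low)
            ref_target[i_global] = sel.f_low
        for sel in sel_here:
            is_selected[idx[pos == sel.position]] = True

    alt_freq = (1.0 - w) * neutral + w * cline  # selected allele, per deme
    ref_freq = (1.0 - w) * ref_neutral + w * ref_target

    # --- allele composition ---------------------------------------------
    # allele 0 = REF (background), allele 1 = the simulated/selected allele;
    # a multiallelic neutral locus splits the background share with allele 2
    tri = (rng.random(n_loci) < cfg.multiallelic_fraction) & ~is_selected
    tri_split = rng.uniform(0.05, 0.30, size=n_loci)

    def allele_vectors(freq_sel: np.ndarray) -> np.ndarray:
        """(n_loci, 4) frequency vectors from selected-allele frequencies."""
        out = np.zeros((n_loci, 4))
        bg = 1.0 - freq_sel
        out[:, 1] = freq_sel
        out[:, 0] = np.where(tri, bg * (1.0 - tri_split), bg)
        out[:, 2] = np.where(tri, bg * tri_split, 0.0)
        return out

    # --- samples and genotypes ------------------------------------------
    deme_labels = ["L", "M1", "M2", "H"] + [
        f"R{i + 1}" for i in range(cfg.n_reference_demes)
    ]
    deme_freqs = [allele_vectors(alt_freq[j]) for j in range(n_alt)] + [
        allele_vectors(ref_freq[j]) for j in range(cfg.n_reference_demes)
    ]
    deme_sizes = [cfg.n_per_altitude_deme] * n_alt + [
        cfg.n_per_reference_deme
    ] * cfg.n_reference_demes

    samples: list[str] = []
    deme_of: dict[str, str] = {}
    calls_parts = []
    for label, fv, size in zip(deme_labels, deme_freqs, deme_sizes):
        cdf = np.cumsum(fv, axis=1)
        cdf[:, -1] = 1.0
        u = rng.random((size, n_loci, 2))
        idx = (u[..., None] >= cdf[None, :, None, :]).sum(axis=-1)
        calls_parts.append(idx.astype(np.int8))
        for i in range(size):
            sid = f"{label}_{i + 1}"
            samples.append(sid)
            deme_of[sid] = label
    calls = np.concatenate(calls_parts, axis=0)
    n_samples = len(samples)

    p_nb = cfg.depth_dispersion / (cfg.depth_dispersion + cfg.depth_mean)
    depths = rng.negative_binomial(
        cfg.depth_dispersion, p_nb, size=(n_samples, n_loci)
    ).astype(np.int32)

    # nucleotide labels per locus
    alleles: list[tuple[str, ...]] = []
    for j in range(n_loci):
        k = 3 if tri[j] else 2
        letters = rng.choice(4, size=k, replace=False)
        alleles.append(tuple(NUCS[letters]))

    table = GenotypeTable(
        samples=samples,
        scaffolds=scaffolds,
        positions=positions,
        alleles=alleles,
        calls=calls,
        depths=depths,
    )
    table.validate()

    role_of = dict(zip(deme_labels[:n_alt], ALTITUDE_ROLES))
    altitude_of = dict(zip(deme_labels[:n_alt], DEFAULT_ALTITUDES))
    for i in range(cfg.n_reference_demes):
        role_of[f"R{i + 1}"] = REFERENCE_ROLE
        altitude_of[f"R{i + 1}"] = DEFAULT_REF_ALTITUDES[
            i % len(DEFAULT_REF_ALTITUDES)
        ]
    design = TransectDesign(deme_of, role_of, altitude_of)
    design.validate()

    annot = _tile_annotation(rng, cfg, scaffold_names)

    truth = pd.DataFrame(
        {
            "scaffold": scaffolds,
            "position": positions,
            "is_selected": is_selected,
            "w": w,
            "f_L": alt_freq[0],
            "f_M1": alt_freq[1],
            "f_M2": alt_freq[2],
            "f_H": alt_freq[3],
            "f_REF": ref_freq.mean(axis=0),
        }
    )
    return table, design, annot, truth


def _tile_annotation(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    scaffold_names: list[str],
) -> GeneAnnotation:
    """Tile genes with two exons each; enrich chosen GO terms near selection."""
    terms = [f"GO:{i + 1:07d}" for i in range(cfg.go_terms)]
    names = {t: f"synthetic process {i + 1}" for i, t in enumerate(terms)}
    enriched = set(terms[: cfg.enriched_terms])
    sel_by_scf: dict[str, list[int]] = {s: [] for s in scaffold_names}
    for sel in cfg.selected:
        sel_by_scf[scaffold_names[sel.scaffold]].append(sel.position)
    records = []
    gene_go: dict[str, set[str]] = {}
    for scf in scaffold_names:
        n_genes = cfg.scaffold_length // cfg.gene_spacing
        for g in range(n_genes):
            start = g * cfg.gene_spacing + 1000
            gene_id = f"{scf}_g{g + 1:04d}"
            records.append((scf, start, start + 800, gene_id))
            records.append((scf, start + 1200, start + 2000, gene_id))
            near_sel = any(
                abs((start + 1000) - sp) <= cfg.enriched_radius
                for sp in sel_by_scf[scf]
            )
            tags = set()
            for t in terms:
                p = (
                    cfg.enriched_term_prob
                    if (t in enriched and near_sel)
                    else cfg.base_term_prob
                )
                if rng.random() < p:
                    tags.add(t)
            if tags:
                gene_go[gene_id] = tags
    annot = GeneAnnotation(
        exons=pd.DataFrame(
            records, columns=["scaffold", "start", "end", "gene_id"]
        ),
        gene_go=gene_go,
        go_names=names,
    )
    annot.validate()
    return annot


def write_fixture_bundle(
    dataset: tuple[GenotypeTable, TransectDesign, GeneAnnotation, pd.DataFrame],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write genotypes.vcf, popmap.tsv, exons.bed, go_map.tsv, truth.tsv."""
    table, design, annot, truth = dataset
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "popmap": out / "popmap.tsv",
        "bed": out / "exons.bed",
        "go": out / "go_map.tsv",
        "truth": out / "truth.tsv",
    }
    write_genotype_vcf(table, paths["vcf"])
    write_population_map(design, paths["popmap"])
    write_exon_bed(annot, paths["bed"])
    write_go_map(annot, paths["go"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
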