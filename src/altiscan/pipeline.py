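"""End-to-end orchestration: stats -> screen -> islands -> enrichment.

``run_scan`` executes one transect from input files (or an in-memory
dataset) and writes every result table as TSV with a provenance header
(config hash, seed, package version) in leading ``#`` comment lines.
Identical config and inputs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrichment import go_enrichment
from .genomic_islands import island_candidate_genes, rank_islands, segment_islands
from .io_formats import (
    GeneAnnotation,
    GenotypeTable,
    TransectDesign,
    read_exon_bed,
    read_genotype_vcf,
    read_go_map,
    read_population_map,
)
from .popgen_stats import compute_locus_stats, diversity_summary, multilocus_gst_matrix
from .resampling import ResamplingSpec, shared_gene_pvalue
from .screening import compute_thresholds, link_snps_to_genes, screen_loci, venn_counts

log = logging.getLogger("altiscan")

__all__ = ["PipelineConfig", "ScanResult", "run_scan", "compare_transects"]


@dataclass
class PipelineConfig:
    vcf: str | None = None
    popmap: str | None = None
    exon_bed: str | None = None
    go_map: str | None = None
    out_dir: str = "scan_out"
    window_half_width: int = 2000
    island_gap: int = 4000
    min_screened: int = 2
    gene_link_dist: int = 5000
    fence_multiplier: float = 1.5
    top_n: int = 20
    go_terms: list[str] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        for name in ("window_half_width", "island_gap", "gene_link_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fence_multiplier < 0:
            raise ValueError("fence_multiplier must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        # out_dir does not affect results, so it is not part of the identity
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ScanResult:
    stats: pd.DataFrame  # per-locus indices + screening flags
    thresholds: dict
    venn: dict
    islands: list
    island_table: pd.DataFrame
    candidate_genes: list[str]
    enrichment_snp: pd.DataFrame
    enrichment_gene: pd.DataFrame
    diversity: pd.DataFrame
    diversity_tests: pd.DataFrame
    gst_matrix: pd.DataFrame


def _write_with_header(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# altiscan {__version__}\n")
        fh.write(f"# config_hash: {cfg.digest()}\n")
        fh.write(f"# seed: {cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_scan(
    cfg: PipelineConfig,
    dataset: tuple[GenotypeTable, TransectDesign, GeneAnnotation] | None = None,
    write: bool = True,
) -> ScanResult:
    """Run the full scan for one transect.

    ``dataset`` may supply (table, design, annotation) directly; otherwise
    the paths in ``cfg`` are read. Set ``write=False`` to skip writing the
    result tables.
    """
    cfg.validate()
    if dataset is not None:
        table, design, annot = dataset
    else:
        if not (cfg.vcf and cfg.popmap and cfg.exon_bed and cfg.go_map):
            raise ValueError("config must name vcf, popmap, exon_bed, go_map")
        log.info("reading inputs")
        table = read_genotype_vcf(cfg.vcf)
        design = read_population_map(cfg.popmap)
        annot = read_exon_bed(cfg.exon_bed)
        go = read_go_map(cfg.go_map)
        annot.gene_go = go.gene_go
        annot.go_names = go.go_names
    orphans = sorted(set(design.deme_of) - set(table.samples))
    if orphans:
        raise ValueError(f"samples in population map but not in VCF: {orphans}")

    log.info("computing per-locus statistics (%d loci)", table.n_loci)
    stats = compute_locus_stats(table, design, cfg.window_half_width)
    thresholds = compute_thresholds(stats, cfg.fence_multiplier)
    stats = screen_loci(stats, thresholds)
    venn = venn_counts(stats)
    log.info("screened %d / %d SNPs", int(stats["screened"].sum()), len(stats))

    snp_genes = link_snps_to_genes(
        table.scaffolds, table.positions, annot, cfg.gene_link_dist
    )
    islands = segment_islands(
        table.scaffolds,
        table.positions,
        stats["u_bar"].to_numpy(),
        cfg.island_gap,
    )
    ranked = rank_islands(
        islands, stats["screened"].to_numpy(), cfg.min_screened
    )
    ranked, island_table = island_candidate_genes(ranked, snp_genes, cfg.top_n)
    candidates = sorted({g for isl in ranked[: cfg.top_n] for g in isl.genes})
    log.info("%d ranked islands, %d candidate genes", len(ranked), len(candidates))

    terms = cfg.go_terms or sorted(annot.go_names)
    screened_arr = stats["screened"].to_numpy()
    enr_snp = go_enrichment(screened_arr, snp_genes, annot, terms, "snp_based")
    enr_gene = go_enrichment(screened_arr, snp_genes, annot, terms, "gene_based")

    diversity, div_tests = diversity_summary(table, design)
    gst_mat = multilocus_gst_matrix(table, design)

    result = ScanResult(
        stats=stats,
        thresholds={
            "q1": thresholds.q1,
            "q3": thresholds.q3,
            "fence": thresholds.fence,
        },
        venn=venn,
        islands=ranked,
        island_table=island_table,
        candidate_genes=candidates,
        enrichment_snp=enr_snp,
        enrichment_gene=enr_gene,
        diversity=diversity,
        diversity_tests=div_tests,
        gst_matrix=gst_mat,
    )
    if write:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_with_header(stats, out / "locus_stats.tsv", cfg)
        _write_with_header(island_table, out / "islands_top.tsv", cfg)
        _write_with_header(enr_snp, out / "enrichment_snp.tsv", cfg)
        _write_with_header(enr_gene, out / "enrichment_gene.tsv", cfg)
        _write_with_header(diversity, out / "diversity.tsv", cfg)
        _write_with_header(div_tests, out / "diversity_tests.tsv", cfg)
        _write_with_header(
            gst_mat.reset_index(names="deme"), out / "gst_matrix.tsv", cfg
        )
        pd.DataFrame([venn]).pipe(
            _write_with_header, out / "venn_counts.tsv", cfg
        )
        log.info("wrote result tables to %s", out)
    return result


def compare_transects(
    result_a: ScanResult,
    result_b: ScanResult,
    universe: int,
    trials: int = 1_000_000,
    seed: int = 0,
) -> dict:
    """Shared candidate genes between two transects plus an empirical p-value."""
    genes_a = set(result_a.candidate_genes)
    genes_b = set(result_b.candidate_genes)
    shared = sorted(genes_a & genes_b)
    spec = ResamplingSpec(
        universe=universe,
        n1=len(genes_a),
        n2=len(genes_b),
        k=max(len(shared), 0),
        trials=trials,
        seed=seed,
    )
    if spec.k == 0:
        p_hat = p_exact = 1.0
    else:
        res = shared_gene_pvalue(spec)
        p_hat, p_exact = res.p_hat, res.p_exact
    return {
        "shared_genes": shared,
        "n_shared": len(shared),
        "n_list_a": len(genes_a),
        "n_list_b": len(genes_b),
        "universe": universe,
        "p_hat": p_hat,
        "p_exact": p_exact,
    }
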