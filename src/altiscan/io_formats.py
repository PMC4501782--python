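"""Readers, writers, and validated containers for scan inputs and outputs.

Coordinate conventions: SNP positions are 1-based (VCF); exon intervals are
0-based half-open (BED). Conversion happens once, at the SNP-to-gene linkage
boundary, never inside the containers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "GenotypeTable",
    "TransectDesign",
    "GeneAnnotation",
    "ALTITUDE_ROLES",
    "REFERENCE_ROLE",
    "read_genotype_vcf",
    "write_genotype_vcf",
    "read_population_map",
    "write_population_map",
    "read_exon_bed",
    "write_exon_bed",
    "read_go_map",
    "write_go_map",
    "write_table",
]

#: Altitude roles in transect order, lowest first.
ALTITUDE_ROLES = ("lowest", "lower_middle", "higher_middle", "highest")
REFERENCE_ROLE = "reference"

MISSING = -1  # sentinel allele index for a missing call


class ValidationError(ValueError):
    """Raised when an input file or container violates its invariants."""


@dataclass
class GenotypeTable:
    """Per-sample diploid allele calls at SNP loci with scaffold coordinates.

    Attributes
    ----------
    samples : list of sample identifiers.
    scaffolds : object array, scaffold id per locus.
    positions : int64 array, 1-based position per locus.
    alleles : list of allele tuples (REF first), length 2-4 per locus.
    calls : int8 array of shape (n_samples, n_loci, 2); allele indices,
        ``MISSING`` (-1) for uncalled. The pair is unordered.
    depths : optional int32 array of shape (n_samples, n_loci).
    """

    samples: list[str]
    scaffolds: np.ndarray
    positions: np.ndarray
    alleles: list[tuple[str, ...]]
    calls: np.ndarray
    depths: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.positions)

    def n_alleles(self) -> np.ndarray:
        return np.array([len(a) for a in self.alleles], dtype=np.int64)

    def validate(self) -> None:
        if self.calls.shape != (self.n_samples, self.n_loci, 2):
            raise ValidationError(
                f"calls shape {self.calls.shape} != "
                f"({self.n_samples}, {self.n_loci}, 2)"
            )
        if self.depths is not None and self.depths.shape != (
            self.n_samples,
            self.n_loci,
        ):
            raise ValidationError("depths shape mismatch")
        for j, a in enumerate(self.alleles):
            if not 2 <= len(a) <= 4:
                raise ValidationError(
                    f"locus {j} ({self.scaffolds[j]}:{self.positions[j]}) has "
                    f"{len(a)} alleles; expected 2-4"
                )
        # positions strictly increasing within each scaffold
        for j in range(1, self.n_loci):
            if self.scaffolds[j] == self.scaffolds[j - 1] and (
                self.positions[j] <= self.positions[j - 1]
            ):
                raise ValidationError(
                    f"positions not strictly increasing on {self.scaffolds[j]} "
                    f"at index {j}"
                )
        nal = self.n_alleles()
        called = self.calls >= 0
        if np.any(self.calls[called.nonzero()[0], called.nonzero()[1], called.nonzero()[2]] >= nal[called.nonzero()[1]]):
            raise ValidationError("call allele index exceeds locus allele count")

    def subset_loci(self, mask: np.ndarray) -> "GenotypeTable":
        """Return a new table restricted to loci where ``mask`` is True."""
        idx = np.flatnonzero(mask)
        return GenotypeTable(
            samples=list(self.samples),
            scaffolds=self.scaffolds[idx],
            positions=self.positions[idx],
            alleles=[self.alleles[i] for i in idx],
            calls=self.calls[:, idx, :],
            depths=None if self.depths is None else self.depths[:, idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        same = (
            self.samples == other.samples
            and np.array_equal(self.scaffolds, other.scaffolds)
            and np.array_equal(self.positions, other.positions)
            and self.alleles == other.alleles
            and np.array_equal(
                np.sort(self.calls, axis=2), np.sort(other.calls, axis=2)
            )
        )
        if not same:
            return False
        if (self.depths is None) != (other.depths is None):
            return False
        return self.depths is None or np.array_equal(self.depths, other.depths)


@dataclass
class TransectDesign:
    """Assignment of samples to altitude-ordered demes and reference demes."""

    deme_of: dict[str, str]  # sample_id -> deme label
    role_of: dict[str, str]  # deme label -> role
    altitude_of: dict[str, float]  # deme label -> meters

    def samples_in(self, deme: str) -> list[str]:
        return [s for s, d in self.deme_of.items() if d == deme]

    def altitude_demes(self) -> list[str]:
        """The four altitude demes ordered lowest to highest."""
        by_role = {r: d for d, r in self.role_of.items()}
        return [by_role[r] for r in ALTITUDE_ROLES]

    def reference_demes(self) -> list[str]:
        return [d for d, r in self.role_of.items() if r == REFERENCE_ROLE]

    def validate(self) -> None:
        for d in self.deme_of.values():
            if d not in self.role_of:
                raise ValidationError(f"deme {d!r} has no role assignment")
        counts = {r: 0 for r in ALTITUDE_ROLES}
        for d, r in self.role_of.items():
            if r in counts:
                counts[r] += 1
            elif r != REFERENCE_ROLE:
                raise ValidationError(f"unknown role {r!r} for deme {d!r}")
            if d not in self.altitude_of:
                raise ValidationError(f"deme {d!r} has no altitude")
        missing = [r for r, c in counts.items() if c == 0]
        if missing:
            raise ValidationError(f"absent altitude roles: {missing}")
        dup = [r for r, c in counts.items() if c > 1]
        if dup:
            raise ValidationError(f"duplicated altitude roles: {dup}")
        alts = [self.altitude_of[d] for d in self.altitude_demes()]
        if not all(a < b for a, b in zip(alts, alts[1:])):
            raise ValidationError(
                f"altitudes not strictly increasing over roles: {alts}"
            )


@dataclass
class GeneAnnotation:
    """Exon intervals (0-based half-open) plus gene -> GO-term mapping."""

    exons: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["scaffold", "start", "end", "gene_id"]
        )
    )
    gene_go: dict[str, set[str]] = field(default_factory=dict)
    go_names: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        bad = self.exons[self.exons["start"] >= self.exons["end"]]
        if len(bad):
            row = bad.iloc[0]
            raise ValidationError(
                f"exon with start >= end: {row['scaffold']} "
                f"{row['start']} {row['end']} {row['gene_id']}"
            )
        for g, terms in self.gene_go.items():
            for t in terms:
                if t not in self.go_names:
                    raise ValidationError(
                        f"GO id {t!r} of gene {g!r} missing from name table"
                    )

    def genes(self) -> list[str]:
        return sorted(set(self.exons["gene_id"]))


# ---------------------------------------------------------------------------
# VCF


def read_genotype_vcf(path: str | Path) -> GenotypeTable:
    """Read a VCF v4.x into a :class:`GenotypeTable`.

    REF+ALT allele order is preserved; multiallelic records are kept as
    single loci (never split). Loci are sorted by (scaffold, position).
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    scaffolds: list[str] = []
    positions: list[int] = []
    alleles: list[tuple[str, ...]] = []
    calls: list[np.ndarray] = []
    depths: list[np.ndarray] = []
    has_depth = True
    for var in vcf:
        alls = (var.REF, *var.ALT)
        if len(alls) > 4:
            raise ValidationError(
                f"locus {var.CHROM}:{var.POS} has {len(alls)} alleles (max 4): "
                f"{alls}"
            )
        scaffolds.append(var.CHROM)
        positions.append(var.POS)
        alleles.append(tuple(alls))
        gt = np.asarray(var.genotypes, dtype=np.int64)[:, :2]
        calls.append(gt.astype(np.int8))
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is None:
            has_depth = False
        else:
            depths.append(dp[:, 0].astype(np.int32))
    vcf.close()
    n_loci = len(positions)
    order = sorted(range(n_loci), key=lambda i: (scaffolds[i], positions[i]))
    table = GenotypeTable(
        samples=samples,
        scaffolds=np.array([scaffolds[i] for i in order], dtype=object),
        positions=np.array([positions[i] for i in order], dtype=np.int64),
        alleles=[alleles[i] for i in order],
        calls=(
            np.stack([calls[i] for i in order], axis=1)
            if n_loci
            else np.empty((len(samples), 0, 2), dtype=np.int8)
        ),
        depths=(
            np.stack([depths[i] for i in order], axis=1)
            if has_depth and depths
            else None
        ),
    )
    table.validate()
    return table


def write_genotype_vcf(table: GenotypeTable, path: str | Path) -> None:
    """Write a :class:`GenotypeTable` as minimal VCF v4.2 (GT, optional DP)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if table.depths is not None:
            fh.write(
                '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
            )
        for scf in sorted(set(table.scaffolds.tolist())):
            fh.write(f"##contig=<ID={scf}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        fmt = "GT:DP" if table.depths is not None else "GT"
        buf = io.StringIO()
        for j in range(table.n_loci):
            alls = table.alleles[j]
            fields = [
                str(table.scaffolds[j]),
                str(table.positions[j]),
                ".",
                alls[0],
                ",".join(alls[1:]),
                ".",
                "PASS",
                ".",
                fmt,
            ]
            for i in range(table.n_samples):
                a, b = table.calls[i, j]
                gt = "./." if a < 0 or b < 0 else f"{a}/{b}"
                if table.depths is not None:
                    gt += f":{table.depths[i, j]}"
                fields.append(gt)
            buf.write("\t".join(fields) + "\n")
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Population map


def read_population_map(path: str | Path) -> TransectDesign:
    """Read a TSV with columns sample_id, deme, role, altitude_m."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "deme": str})
    required = {"sample_id", "deme", "role", "altitude_m"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"population map missing columns: {sorted(required - set(df.columns))}"
        )
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids: {dups}")
    deme_of = dict(zip(df["sample_id"], df["deme"]))
    role_of: dict[str, str] = {}
    altitude_of: dict[str, float] = {}
    for _, row in df.iterrows():
        d = row["deme"]
        if d in role_of and role_of[d] != row["role"]:
            raise ValidationError(f"deme {d!r} has conflicting roles")
        role_of[d] = row["role"]
        altitude_of[d] = float(row["altitude_m"])
    design = TransectDesign(deme_of, role_of, altitude_of)
    design.validate()
    return design


def write_population_map(design: TransectDesign, path: str | Path) -> None:
    rows = [
        {
            "sample_id": s,
            "deme": d,
            "role": design.role_of[d],
            "altitude_m": design.altitude_of[d],
        }
        for s, d in design.deme_of.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Exon BED and GO map


def read_exon_bed(path: str | Path) -> GeneAnnotation:
    """Read a BED4 of exons (0-based half-open, gene_id in the name column)."""
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(f"line {ln}: expected >=4 BED columns")
            scaffold, start, end, gene_id = parts[:4]
            start_i, end_i = int(start), int(end)
            if start_i >= end_i:
                raise ValidationError(
                    f"line {ln}: start {start_i} >= end {end_i}"
                )
            records.append((scaffold, start_i, end_i, gene_id))
    annot = GeneAnnotation(
        exons=pd.DataFrame(
            records, columns=["scaffold", "start", "end", "gene_id"]
        )
    )
    annot.validate()
    return annot


def write_exon_bed(annot: GeneAnnotation, path: str | Path) -> None:
    annot.exons.to_csv(path, sep="\t", index=False, header=False)


def read_go_map(path: str | Path) -> GeneAnnotation:
    """Read a TSV with columns gene_id, go_id, go_name into gene->GO maps."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "go_id", "go_name"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"GO map missing columns: {sorted(required - set(df.columns))}"
        )
    if len(df) == 0:
        raise ValidationError("GO map is empty")
    gene_go: dict[str, set[str]] = {}
    go_names: dict[str, str] = {}
    for _, row in df.iterrows():
        gene_go.setdefault(row["gene_id"], set()).add(row["go_id"])
        go_names[row["go_id"]] = row["go_name"]
    return GeneAnnotation(gene_go=gene_go, go_names=go_names)


def write_go_map(annot: GeneAnnotation, path: str | Path) -> None:
    rows = [
        {"gene_id": g, "go_id": t, "go_name": annot.go_names.get(t, t)}
        for g in sorted(annot.gene_go)
        for t in sorted(annot.gene_go[g])
    ]
    pd.DataFrame(rows, columns=["gene_id", "go_id", "go_name"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Result tables


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with floats at 6 significant digits."""
    rows.to_csv(path, sep="\t", index=False, float_format="%.6g")
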