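"""Post-call SNP cleaning for depth-annotated genotype tables.

Three rules, applied in a fixed order so every dropped locus carries exactly
one (first-failing) reason:

1. ``min_depth`` — every individual must have at least ``min_reads_per_individual``
   reads at the locus.
2. ``max_total`` — summed depth over individuals must not exceed
   ``max_total_read_count`` (excess coverage flags collapsed paralogs).
3. ``allele_fraction`` — the locus-wide frequency of the second-most-frequent
   allele among called chromosomes must exceed
   ``min_antagonistic_allele_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeTable

__all__ = ["FilterConfig", "filter_loci"]


@dataclass
class FilterConfig:
    min_reads_per_individual: int = 5
    min_antagonistic_allele_fraction: float = 0.20
    max_total_read_count: int = 10_000

    def __post_init__(self) -> None:
        if self.min_reads_per_individual < 0 or self.max_total_read_count < 0:
            raise ValueError("depth thresholds must be non-negative")
        if not 0.0 <= self.min_antagonistic_allele_fraction <= 1.0:
            raise ValueError("allele fraction threshold must be in [0, 1]")


def filter_loci(
    table: GenotypeTable, cfg: FilterConfig | None = None
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Apply the cleaning rules; return the retained table and a reason table.

    The reason table has one row per dropped locus with columns scaffold,
    position, reason in {min_depth, max_total, allele_fraction}.
    """
    if cfg is None:
        cfg = FilterConfig()
    if table.depths is None and (
        cfg.min_reads_per_individual > 0 or cfg.max_total_read_count < np.inf
    ):
        raise ValueError(
            "genotype table has no read depths; disable depth filters or "
            "provide DP"
        )
    depths = table.depths
    n_loci = table.n_loci
    reason = np.full(n_loci, "", dtype=object)

    fail_min = np.any(depths < cfg.min_reads_per_individual, axis=0)
    reason[fail_min] = "min_depth"

    fail_total = depths.sum(axis=0) > cfg.max_total_read_count
    reason[(reason == "") & fail_total] = "max_total"

    # second-most-frequent allele frequency over called chromosomes
    counts = np.zeros((n_loci, 4), dtype=np.int64)
    for a in range(4):
        counts[:, a] = np.sum(table.calls == a, axis=(0, 2))
    total = counts.sum(axis=1).astype(float)
    second = np.sort(counts, axis=1)[:, -2]
    with np.errstate(invalid="ignore", divide="ignore"):
        second_freq = np.where(total > 0, second / total, 0.0)
    # strict ">" per the rule; a zero threshold disables the rule entirely so
    # the null config is the identity filter
    if cfg.min_antagonistic_allele_fraction == 0:
        fail_frac = np.zeros(n_loci, dtype=bool)
    else:
        fail_frac = ~(second_freq > cfg.min_antagonistic_allele_fraction)
    reason[(reason == "") & fail_frac] = "allele_fraction"

    keep = reason == ""
    dropped = pd.DataFrame(
        {
            "scaffold": table.scaffolds[~keep],
            "position": table.positions[~keep],
            "reason": reason[~keep],
        }
    )
    return table.subset_loci(keep), dropped
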