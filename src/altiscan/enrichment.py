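"""GO-term enrichment of the screened set, SNP-based and gene-based.

Both modes build one 2x2 table per GO term — screened vs not-screened
against term vs no-term — and test enrichment with a one-tailed Fisher
exact test (upper hypergeometric tail). Units are gene-linked SNPs in
``snp_based`` mode (a SNP carries a term if any linked gene does) and
SNP-tagged genes in ``gene_based`` mode (a gene is screened if at least one
screened SNP links to it). q-values are Benjamini-Hochberg across the
requested terms; significance at q < 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneAnnotation

__all__ = ["fisher_one_tailed_2x2", "fdr_qvalues", "go_enrichment"]


def fisher_one_tailed_2x2(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail Fisher exact p for the 2x2 table [[a, b], [c, d]].

    P(X >= a) for X hypergeometric with population a+b+c+d, a+b draws, and
    a+c successes — the enrichment direction.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    return float(hypergeom.sf(a - 1, n, a + c, a + b))


def fdr_qvalues(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pvals.size == 0:
        return pvals.copy()
    return multipletests(pvals, method="fdr_bh")[1]


def go_enrichment(
    screened: np.ndarray,
    snp_genes: list[set[str]],
    annot: GeneAnnotation,
    terms: list[str],
    mode: str = "snp_based",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Enrichment table for the requested GO terms.

    Parameters
    ----------
    screened : per-SNP boolean, all three criteria fulfilled.
    snp_genes : per-SNP set of linked genes (within 5 kbp of an exon); SNPs
        with an empty set are excluded from both foreground and background.
    annot : supplies gene -> GO mapping and term names.
    terms : GO ids to test; absent terms yield zero counts and p = 1.
    mode : "snp_based" or "gene_based".
    """
    screened = np.asarray(screened, dtype=bool)
    if mode == "snp_based":
        linked = np.array([len(g) > 0 for g in snp_genes])
        unit_terms = [
            frozenset().union(*(annot.gene_go.get(g, set()) for g in gs))
            if gs
            else frozenset()
            for gs in snp_genes
        ]
        unit_screened = screened & linked
        unit_mask = linked
        unit_term_sets = [t for t, keep in zip(unit_terms, unit_mask) if keep]
        unit_flag = unit_screened[unit_mask]
    elif mode == "gene_based":
        gene_screened: dict[str, bool] = {}
        for i, gs in enumerate(snp_genes):
            for g in gs:
                gene_screened[g] = gene_screened.get(g, False) or bool(
                    screened[i]
                )
        genes = sorted(gene_screened)
        unit_term_sets = [frozenset(annot.gene_go.get(g, set())) for g in genes]
        unit_flag = np.array([gene_screened[g] for g in genes], dtype=bool)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    n_scr = int(unit_flag.sum())
    n_bg = len(unit_flag) - n_scr
    rows = []
    for term in terms:
        has = np.array([term in ts for ts in unit_term_sets], dtype=bool)
        a = int(np.sum(has & unit_flag))  # screened with term
        b = n_scr - a  # screened without term
        c = int(np.sum(has & ~unit_flag))  # unscreened with term
        d = n_bg - c
        p = fisher_one_tailed_2x2(a, b, c, d)
        scr_frac = a / n_scr if n_scr else 0.0
        bg_frac = (a + c) / len(unit_flag) if len(unit_flag) else 0.0
        fold = scr_frac / bg_frac if bg_frac > 0 else np.nan
        rows.append(
            {
                "go_id": term,
                "go_name": annot.go_names.get(term, term),
                "mode": mode,
                "n_screened_term": a,
                "n_screened_noterm": b,
                "n_unscreened_term": c,
                "n_unscreened_noterm": d,
                "fold_enrichment": fold,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = fdr_qvalues(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < alpha
    return out
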