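"""Binding-expression integration: DE filtering, peak-to-gene assignment,
direct-target calling, and feed-forward-loop enumeration.

A *direct target* of a factor is a gene that is differentially expressed in
the factor-knockout comparison and carries at least one factor-specific peak
within the assignment window of its TSS.  A *feed-forward loop* is a triple
(factor, regulator, target) in which the factor binds both the regulator and
the target and the regulator->target edge exists in the supplied network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genomic_io import ExpressionRecord
from .peaks import Peak


def filter_de(records: list[ExpressionRecord], fc_min: float = 1.5,
              fdr_max: float = 0.15) -> set[str]:
    """Differentially expressed genes at |linear FC| >= fc_min and
    FDR <= fdr_max (both boundaries inclusive).

    ``log2fc`` is on the log2 scale, so the linear threshold translates to
    |log2fc| >= log2(fc_min).  When FDR values are absent, Benjamini-
    Hochberg adjustment is computed from the p-values first.
    """
    if not records:
        return set()
    fdrs = [r.fdr for r in records]
    if any(f is None for f in fdrs):
        pvals = [r.pvalue for r in records]
        if any(p is None for p in pvals):
            raise ValueError("records lack both fdr and pvalue")
        fdrs = multipletests(pvals, method="fdr_bh")[1]
    lfc_min = math.log2(fc_min)
    return {
        r.gene_id
        for r, f in zip(records, fdrs)
        if abs(r.log2fc) >= lfc_min and f <= fdr_max
    }


def assign_peaks_to_genes(peaks: list[Peak], tss_table: pd.DataFrame,
                          window: int = 100_000
                          ) -> dict[str, list[tuple[int, float]]]:
    """Map gene -> [(peak_index, signed distance)] for every gene whose TSS
    lies within ``window`` bp of a peak midpoint (multi-assignment)."""
    out: dict[str, list[tuple[int, float]]] = {}
    by_chrom = {c: g for c, g in tss_table.groupby("chrom")}
    for i, p in enumerate(peaks):
        iv = p.interval
        sub = by_chrom.get(iv.chrom)
        if sub is None:
            continue
        mid = iv.midpoint
        raw = mid - sub.tss.to_numpy()
        within = np.abs(raw) <= window
        signed = np.where(sub.strand.to_numpy() == "-", -raw, raw)
        for gene, d in zip(sub.gene_id.to_numpy()[within], signed[within]):
            out.setdefault(str(gene), []).append((i, float(d)))
    return out


@dataclass
class DirectTargetReport:
    factor_label: str
    n_bound_genes: int
    n_de_genes: int
    n_direct: int
    fraction_of_de: float
    genes: dict[str, list[tuple[int, float]]] = field(default_factory=dict)


def direct_targets(bound_gene_map: dict[str, list[tuple[int, float]]],
                   de_genes: set[str], factor_label: str
                   ) -> DirectTargetReport:
    """Intersect bound genes with DE genes; an empty DE set yields a zero
    report rather than an error."""
    direct = sorted(set(bound_gene_map) & de_genes)
    frac = len(direct) / len(de_genes) if de_genes else 0.0
    return DirectTargetReport(
        factor_label=factor_label,
        n_bound_genes=len(bound_gene_map),
        n_de_genes=len(de_genes),
        n_direct=len(direct),
        fraction_of_de=frac,
        genes={g: bound_gene_map[g] for g in direct},
    )


def read_edges(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"regulator", "target"} <= set(df.columns):
        raise ValueError("edge table needs regulator and target columns")
    if (df.regulator == df.target).any():
        raise ValueError("self-edges (regulator == target) are not allowed")
    return df


def find_feed_forward_loops(factor_label: str, bound_genes: set[str],
                            edges: pd.DataFrame
                            ) -> list[tuple[str, str, str]]:
    """All (factor, regulator, target) triples in which the factor binds both
    endpoints of an existing regulator->target edge; deterministically
    sorted."""
    triples = {
        (factor_label, str(r), str(t))
        for r, t in zip(edges.regulator, edges.target)
        if r != t and str(r) in bound_genes and str(t) in bound_genes
    }
    return sorted(triples)
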