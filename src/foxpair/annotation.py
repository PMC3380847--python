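"""Positional annotation of binding sites: distance to the nearest TSS and
overlap with histone-mark domains.

Distances are signed in gene orientation: peak midpoint minus TSS, with the
sign flipped for minus-strand genes, so negative always means upstream of
the gene.  Equidistant TSS ties break toward the smaller signed distance
(i.e. upstream), a fixed documented rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import GenomicInterval
from .peaks import Peak

log = logging.getLogger(__name__)


def _midpoint(peak: Peak | GenomicInterval) -> tuple[str, int]:
    iv = peak.interval if isinstance(peak, Peak) else peak
    return iv.chrom, iv.midpoint


def nearest_tss(peak: Peak | GenomicInterval,
                tss_table: pd.DataFrame) -> tuple[str | None, float]:
    """Nearest TSS by absolute signed distance; returns (gene_id, distance).

    Peaks on chromosomes without any TSS get (None, inf) and are excluded
    from histograms by the caller.
    """
    chrom, mid = _midpoint(peak)
    sub = tss_table[tss_table.chrom == chrom]
    if len(sub) == 0:
        log.debug("no TSS on %s", chrom)
        return None, math.inf
    raw = mid - sub.tss.to_numpy()
    signed = np.where(sub.strand.to_numpy() == "-", -raw, raw)
    best = np.min(np.abs(signed))
    # ties toward the smaller signed value (upstream)
    candidates = np.flatnonzero(np.abs(signed) == best)
    pick = candidates[np.argmin(signed[candidates])]
    return str(sub.gene_id.iloc[pick]), float(signed[pick])


def tss_distances(peaks: list[Peak], tss_table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for i, p in enumerate(peaks):
        gene, d = nearest_tss(p, tss_table)
        rows.append({"peak_index": i, "gene_id": gene, "distance": d})
    return pd.DataFrame(rows)


@dataclass
class TssHistogram:
    bins: pd.DataFrame  # bin_start, bin_end, count (signed distances)
    n_left_flank: int  # beyond -half_window
    n_right_flank: int  # beyond +half_window
    n_finite: int  # peaks with a finite assignment
    frac_within_10kb: float


def tss_histogram(peaks: list[Peak], tss_table: pd.DataFrame,
                  half_window: int = 100_000, bin_size: int = 5_000
                  ) -> TssHistogram:
    """Histogram of signed nearest-TSS distances over [-half_window,
    +half_window]; out-of-window peaks are tallied in flank counters."""
    if half_window % bin_size:
        raise ValueError("bin_size must divide half_window")
    dists = [nearest_tss(p, tss_table)[1] for p in peaks]
    finite = np.array([d for d in dists if math.isfinite(d)])
    edges = np.arange(-half_window, half_window + bin_size, bin_size)
    in_window = finite[(finite >= -half_window) & (finite < half_window)]
    counts, _ = np.histogram(in_window, bins=edges)
    bins = pd.DataFrame({
        "bin_start": edges[:-1], "bin_end": edges[1:], "count": counts,
    })
    n_left = int((finite < -half_window).sum())
    n_right = int((finite >= half_window).sum())
    frac10 = float((np.abs(finite) <= 10_000).mean()) if len(finite) else 0.0
    return TssHistogram(bins=bins, n_left_flank=n_left, n_right_flank=n_right,
                        n_finite=len(finite), frac_within_10kb=frac10)


def domain_overlap_fraction(peaks: list[Peak],
                            domains: list[GenomicInterval]
                            ) -> tuple[int, float]:
    """How many peaks overlap (>=1 bp) any domain, and the fraction."""
    if not peaks:
        raise ValueError("empty peak set")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append((d.start, d.end))
    idx = {}
    for chrom, pairs in by_chrom.items():
        arr = np.array(pairs)
        idx[chrom] = (np.sort(arr[:, 0]), np.sort(arr[:, 1]))
    n = 0
    for p in peaks:
        iv = p.interval
        if iv.chrom not in idx:
            continue
        ss, es = idx[iv.chrom]
        overlapping = (np.searchsorted(ss, iv.end, side="left")
                       - np.searchsorted(es, iv.start, side="right"))
        if overlapping > 0:
            n += 1
    return n, n / len(peaks)
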