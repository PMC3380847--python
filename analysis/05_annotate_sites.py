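#!/usr/bin/env python
"""Positional and chromatin-context annotation of each occupancy class.

Computes signed nearest-TSS distance histograms (fraction within 10 kb) and
the fraction of each class overlapping histone-style domains — the planted
configuration covers 92% of shared, 29% of A-only and 68% of B-only sites.
Outputs in results/annotation/.
"""

from pathlib import Path

import pandas as pd

from foxpair.annotation import domain_overlap_fraction, tss_histogram
from foxpair.genomic_io import GenomicInterval, read_intervals, read_tss_table
from foxpair.peaks import Peak

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    tss = read_tss_table(ROOT / "data" / "tss.tsv")
    domains = read_intervals(ROOT / "data" / "domains.bed")
    outdir = ROOT / "annotation"
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name in ("common", "a_only", "b_only"):
        ivs = read_intervals(ROOT / "occupancy" / f"sites_{name}.bed")
        peaks = [Peak(iv, 1, 0, 1.0) for iv in ivs]
        hist = tss_histogram(peaks, tss)
        hist.bins.to_csv(outdir / f"tss_histogram_{name}.tsv",
                         sep="\t", index=False)
        n_dom, frac_dom = domain_overlap_fraction(peaks, domains)
        rows.append({"class": name, "n_sites": len(peaks),
                     "frac_within_10kb": round(hist.frac_within_10kb, 4),
                     "domain_overlap": round(frac_dom, 4)})
        print(f"{name:8s} domain overlap {frac_dom:.3f}  "
              f"within 10 kb of TSS {hist.frac_within_10kb:.3f}")
    pd.DataFrame(rows).to_csv(outdir / "summary.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
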