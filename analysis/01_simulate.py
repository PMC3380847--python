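#!/usr/bin/env python
"""Generate the reference synthetic two-factor ChIP-seq experiment.

Writes the genome, TSS annotation, three tag libraries (factor A, factor B,
input), histone-style domains, two knockout expression tables, the
regulator->target edge list, and the planted-site truth roster under
results/data/.  Everything downstream reads only these files.
"""

from pathlib import Path

from foxpair.config import SyntheticConfig
from foxpair.synthetic import generate_dataset

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    cfg = SyntheticConfig()  # the reference benchmark: 1 Mb, 100/50/50 sites
    ds = generate_dataset(cfg, OUT)
    print(f"genome: {cfg.n_chrom} chromosomes, {cfg.genome_length:,} bp")
    print(f"planted sites: {cfg.n_shared} shared, {cfg.n_a_only} A-only, "
          f"{cfg.n_b_only} B-only")
    print(f"tag libraries: A={ds.tags_a.total:,}  B={ds.tags_b.total:,}  "
          f"input={ds.tags_input.total:,}")
    print(f"domains: {len(ds.domains)} intervals")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
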