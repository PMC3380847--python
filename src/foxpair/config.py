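"""Configuration for the synthetic two-factor ChIP-seq experiment.

The defaults define the package's reference benchmark: a 1 Mb two-chromosome
genome carrying 100 shared, 50 A-only and 50 B-only planted forkhead sites,
ChIP libraries of ~30 expected tags per visible site over sparse background,
a deep input pool, histone-style domains covering 92%/29%/68% of the shared/
A-only/B-only classes, and a knockout expression table in which 41% of DE
genes are direct (bound) targets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class SyntheticConfig:
    # genome
    genome_length: int = 1_000_000  # bp, total over all chromosomes
    n_chrom: int = 2
    tss_spacing: int = 4_000  # bp between consecutive TSS

    # planted sites
    n_shared: int = 100
    n_a_only: int = 50
    n_b_only: int = 50
    site_max_tss_offset: int = 1_000  # site center within this of its gene TSS
    flank_bias: float = 0.9  # P(shared site gets C-1/T+1; B-only gets TGTT prefix)
    a_only_perfect_frac: float = 0.25  # rest are 1-2-mismatch variants
    b_only_perfect_frac: float = 0.70

    # tag simulation
    enrichment: float = 30.0  # expected tags per site per million library tags
    background_rate: float = 5e-5  # background tags per bp (ChIP libraries)
    fragment_len: int = 150  # bp
    fragment_sd: float = 50.0  # bp, SD of fragment-center placement
    read_len: int = 36  # nt
    depth_a: int = 1_000_000  # nominal library size scaling the enrichment
    depth_b: int = 1_000_000
    depth_input: int = 50_000  # input pool size (tags actually emitted)

    # histone domains
    domain_frac_common: float = 0.92
    domain_frac_a: float = 0.29
    domain_frac_b: float = 0.68
    n_decoy_domains: int = 30

    # expression
    de_frac: float = 0.41  # P(a factor-specific-site-linked gene is DE)
    effect_log2fc: float = 1.0
    de_noise_sd: float = 0.1
    null_log2fc_sd: float = 0.2

    # regulatory edges
    n_true_edges: int = 10
    n_decoy_edges: int = 10

    # peak -> gene assignment window used by the synthetic pipeline (bp);
    # scaled to the compressed intergenic distances of the synthetic genome
    assign_window: int = 1_500

    seed: int = 7

    def __post_init__(self) -> None:
        counts = [
            self.genome_length, self.n_chrom, self.n_shared, self.n_a_only,
            self.n_b_only, self.fragment_len, self.read_len, self.depth_a,
            self.depth_b, self.depth_input,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_chrom < 1:
            raise ValueError("need at least one chromosome")
        for name in ("domain_frac_common", "domain_frac_a", "domain_frac_b",
                     "de_frac", "flank_bias", "a_only_perfect_frac",
                     "b_only_perfect_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.genome_length < 1000 * self.total_sites:
            raise ValueError(
                f"genome_length {self.genome_length} too small for "
                f"{self.total_sites} sites (need >= {1000 * self.total_sites})"
            )

    @property
    def total_sites(self) -> int:
        return self.n_shared + self.n_a_only + self.n_b_only

    @property
    def chrom_length(self) -> int:
        return self.genome_length // self.n_chrom

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
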