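"""Seeded synthetic two-factor ChIP-seq experiments with known ground truth.

The generator plants forkhead sites of three occupancy classes into a random
genome, then emits everything a real analysis would ingest: tag libraries for
both factors and input, histone-style domain intervals, knockout expression
tables, and a regulator->target edge list.  The planted roster
(:class:`SyntheticTruth`) is what downstream recovery is scored against.

Class design mirrors the biology being emulated:

* shared sites carry a perfect consensus instance, usually with a "C" one
  base upstream and a "T" immediately downstream of the core;
* B-only sites carry a mostly-perfect core, usually with "TGTT" immediately
  upstream;
* A-only sites carry a weak core: a minority perfect, the rest with one or
  two mismatching bases.

All randomness flows from a single seed through fixed named substreams, so a
fixed config is byte-reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .config import SyntheticConfig
from .genomic_io import (
    GenomicInterval,
    TagCollection,
    write_fasta,
    write_intervals,
    write_tags,
    write_tss_table,
)
from .motifs import BASES, FOXA_CONSENSUS, expand_consensus, scan_sequence

SHARED, A_ONLY, B_ONLY = "shared", "a_only", "b_only"
SITE_FLANK = 4  # bases of truth interval on each side of the 7-mer core

# fixed substream keys so operations can be re-run independently
_STREAMS = {
    "genome": 11, "sites": 12, "tags_A": 13, "tags_B": 14, "tags_input": 15,
    "domains": 16, "expression_A": 17, "expression_B": 18, "edges": 19,
}


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stream]])


@dataclass
class SyntheticSite:
    interval: GenomicInterval
    site_class: str
    motif_variant: str  # perfect | degenerate1 | degenerate2
    flank_bias: bool
    linked_gene: str
    in_domain: bool | None = None
    is_de: bool | None = None


@dataclass
class SyntheticTruth:
    sites: list[SyntheticSite]
    config: SyntheticConfig

    def by_class(self, site_class: str) -> list[SyntheticSite]:
        return [s for s in self.sites if s.site_class == site_class]

    def linked_genes(self, site_class: str) -> list[str]:
        return [s.linked_gene for s in self.by_class(site_class)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            rows.append({
                "chrom": s.interval.chrom, "start": s.interval.start,
                "end": s.interval.end, "class": s.site_class,
                "motif_variant": s.motif_variant, "flank_bias": s.flank_bias,
                "in_domain": s.in_domain, "linked_gene": s.linked_gene,
                "is_de": s.is_de,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genome and annotation


def generate_genome(config: SyntheticConfig) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Uniform-random genome plus a regularly spaced TSS annotation.

    Returns the genome as mutable uint8 base-index arrays (so sites can be
    planted in place) and a TSS table (gene_id, chrom, tss, strand) with
    genes alternating between strands at ``tss_spacing`` intervals.
    """
    rng = _rng(config, "genome")
    genome: dict[str, np.ndarray] = {}
    rows = []
    gene_i = 0
    for c in range(config.n_chrom):
        chrom = f"chr{c + 1}"
        genome[chrom] = rng.integers(0, 4, size=config.chrom_length, dtype=np.uint8)
        # keep TSS away from chromosome edges so site placement stays in bounds
        pos = config.tss_spacing
        while pos < config.chrom_length - config.tss_spacing:
            rows.append({
                "gene_id": f"g{gene_i:04d}", "chrom": chrom, "tss": pos,
                "strand": "+" if gene_i % 2 == 0 else "-",
            })
            gene_i += 1
            pos += config.tss_spacing
    return genome, pd.DataFrame(rows)


def genome_to_strings(genome: dict[str, np.ndarray]) -> dict[str, str]:
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    return {c: lut[a].tobytes().decode("ascii") for c, a in genome.items()}


# ---------------------------------------------------------------------------
# site planting

_PERFECT = sorted(expand_consensus(FOXA_CONSENSUS))
_ALLOWED = [sorted(p) for p in FOXA_CONSENSUS.pattern]


def _degenerate_core(rng: np.random.Generator, n_mismatch: int) -> str:
    """A 7-mer at Hamming distance exactly ``n_mismatch`` from the consensus:
    mutate positions to bases outside the allowed set, so no other perfect
    variant is recreated."""
    core = list(rng.choice(_PERFECT))
    positions = rng.choice(len(core), size=n_mismatch, replace=False)
    for p in positions:
        forbidden = set(_ALLOWED[p])
        choices = [b for b in BASES if b not in forbidden]
        core[p] = str(rng.choice(choices))
    return "".join(core)


def _choose_variant(rng: np.random.Generator, site_class: str,
                    config: SyntheticConfig) -> str:
    if site_class == SHARED:
        return "perfect"
    p_perfect = (config.a_only_perfect_frac if site_class == A_ONLY
                 else config.b_only_perfect_frac)
    if rng.random() < p_perfect:
        return "perfect"
    # non-perfect mass: mostly single-mismatch, some double
    return "degenerate1" if rng.random() < 0.6 else "degenerate2"


def _write_site(genome_arr: np.ndarray, rng: np.random.Generator,
                core_start: int, site_class: str, variant: str,
                biased: bool) -> None:
    n_mm = {"perfect": 0, "degenerate1": 1, "degenerate2": 2}[variant]
    core = rng.choice(_PERFECT) if n_mm == 0 else _degenerate_core(rng, n_mm)
    k = len(core)
    # randomize the flanking bases of the truth window, then apply biases
    lo, hi = core_start - SITE_FLANK, core_start + k + SITE_FLANK
    genome_arr[lo:hi] = rng.integers(0, 4, size=hi - lo, dtype=np.uint8)
    genome_arr[core_start:core_start + k] = [BASES.index(b) for b in core]
    if biased:
        if site_class == SHARED:
            genome_arr[core_start - 1] = BASES.index("C")
            genome_arr[core_start + k] = BASES.index("T")
        elif site_class == B_ONLY:
            for j, b in enumerate("TGTT"):
                genome_arr[core_start - 4 + j] = BASES.index(b)


def _scan_label(seq: str) -> str:
    """Best-match label of a site window under the consensus scanner."""
    for n_mm, label in ((0, "perfect"), (1, "degenerate1"), (2, "degenerate2")):
        if scan_sequence(seq, FOXA_CONSENSUS, max_mismatch=n_mm):
            return label
    return "none"


def plant_sites(genome: dict[str, np.ndarray], tss_table: pd.DataFrame,
                config: SyntheticConfig, max_retries: int = 50) -> SyntheticTruth:
    """Plant shared/A-only/B-only sites near the TSS of distinct genes.

    Each site is written into the genome in place and then re-scanned; if
    chance flanking bases make the window match better than the intended
    variant, the window is re-rolled (bounded retries).  Site windows are
    pairwise disjoint by construction (one site per gene, genes well spaced).
    """
    rng = _rng(config, "sites")
    n_total = config.total_sites
    if n_total > len(tss_table):
        raise ValueError(
            f"{n_total} sites requested but only {len(tss_table)} genes available"
        )
    gene_order = rng.permutation(len(tss_table))[:n_total]
    classes = ([SHARED] * config.n_shared + [A_ONLY] * config.n_a_only
               + [B_ONLY] * config.n_b_only)
    k = len(FOXA_CONSENSUS)
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    sites: list[SyntheticSite] = []
    for gi, site_class in zip(gene_order, classes):
        gene = tss_table.iloc[gi]
        arr = genome[gene.chrom]
        offset = int(rng.integers(-config.site_max_tss_offset,
                                  config.site_max_tss_offset + 1))
        core_start = int(np.clip(gene.tss + offset, SITE_FLANK + 4,
                                 len(arr) - k - SITE_FLANK - 1))
        variant = _choose_variant(rng, site_class, config)
        biased = bool(rng.random() < config.flank_bias) if site_class != A_ONLY else False
        window = (core_start - SITE_FLANK, core_start + k + SITE_FLANK)
        for attempt in range(max_retries):
            _write_site(arr, rng, core_start, site_class, variant, biased)
            seq = lut[arr[window[0]:window[1]]].tobytes().decode("ascii")
            if _scan_label(seq) == variant:
                break
        else:
            raise RuntimeError(
                f"could not realize a {variant} site at {gene.chrom}:{core_start} "
                f"after {max_retries} retries"
            )
        sites.append(SyntheticSite(
            interval=GenomicInterval(gene.chrom, window[0], window[1]),
            site_class=site_class, motif_variant=variant, flank_bias=biased,
            linked_gene=str(gene.gene_id),
        ))
    sites.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    _check_disjoint(sites)
    return SyntheticTruth(sites=sites, config=config)


def _check_disjoint(sites: list[SyntheticSite]) -> None:
    for a, b in zip(sites, sites[1:]):
        if a.interval.chrom == b.interval.chrom and b.interval.start < a.interval.end:
            raise RuntimeError(f"overlapping planted sites: {a.interval} / {b.interval}")


# ---------------------------------------------------------------------------
# tag simulation

_VISIBLE = {"A": {SHARED, A_ONLY}, "B": {SHARED, B_ONLY}, "input": set()}


def simulate_tags(truth: SyntheticTruth, config: SyntheticConfig,
                  library: str) -> TagCollection:
    """Simulate one tag library (BED-like 5' reads of extended fragments).

    ChIP libraries see their visible site classes (Poisson tag counts with
    Gaussian fragment-center placement) over sparse uniform background; the
    input library is a uniform pool of ``depth_input`` tags.  Fragments
    falling off a chromosome end are clipped, conserving totals.
    """
    if library not in _VISIBLE:
        raise ValueError(f"unknown library {library!r} (want A, B or input)")
    rng = _rng(config, f"tags_{library}")
    chroms = [f"chr{c + 1}" for c in range(config.n_chrom)]
    clen = config.chrom_length
    depth = {"A": config.depth_a, "B": config.depth_b,
             "input": config.depth_input}[library]
    F, R = config.fragment_len, config.read_len
    if F < R:
        raise ValueError("fragment_len must be >= read_len")
    records: list[GenomicInterval] = []

    def emit(chrom: str, frag_start: int, frag_end: int, strand: str) -> None:
        frag_start = max(0, frag_start)
        frag_end = min(clen, frag_end)
        if strand == "+":
            start, end = frag_start, min(frag_start + R, frag_end)
        else:
            start, end = max(frag_end - R, frag_start), frag_end
        if end <= start:  # fully clipped fragment: keep a 1-bp stub at the edge
            start, end = max(0, min(start, clen - 1)), max(1, min(end, clen))
            if end <= start:
                start, end = end - 1, end
        records.append(GenomicInterval(chrom, start, end, strand))

    # planted-site signal
    if library != "input":
        visible = [s for s in truth.sites if s.site_class in _VISIBLE[library]]
        rate = config.enrichment * depth / 1e6
        counts = rng.poisson(rate, size=len(visible))
        for site, n in zip(visible, counts):
            mid = site.interval.midpoint
            centers = np.rint(rng.normal(mid, config.fragment_sd, size=n)).astype(int)
            strands = rng.random(n) < 0.5
            for c, plus in zip(centers, strands):
                emit(site.interval.chrom, c - F // 2, c - F // 2 + F,
                     "+" if plus else "-")
        n_bg = int(rng.poisson(config.background_rate * config.genome_length))
    else:
        n_bg = depth

    # uniform background
    bg_pos = rng.integers(0, config.genome_length, size=n_bg)
    bg_strand = rng.random(n_bg) < 0.5
    for p, plus in zip(bg_pos, bg_strand):
        ci, pos = divmod(int(p), clen)
        emit(chroms[min(ci, config.n_chrom - 1)], pos, pos + F,
             "+" if plus else "-")

    records.sort(key=lambda r: (r.chrom, r.start, r.end, r.strand))
    return TagCollection(records=records, library_label=library)


# ---------------------------------------------------------------------------
# domains


def simulate_domains(truth: SyntheticTruth, config: SyntheticConfig
                     ) -> list[GenomicInterval]:
    """Cover each planted site with a histone-style domain with its class's
    configured probability; add decoy domains away from all sites.  Records
    the realized membership in ``truth`` (``in_domain``)."""
    rng = _rng(config, "domains")
    fracs = {SHARED: config.domain_frac_common, A_ONLY: config.domain_frac_a,
             B_ONLY: config.domain_frac_b}
    domains: list[GenomicInterval] = []
    for site in truth.sites:
        site.in_domain = bool(rng.random() < fracs[site.site_class])
        if site.in_domain:
            pad_l = int(rng.integers(100, 1000))
            pad_r = int(rng.integers(100, 1000))
            domains.append(GenomicInterval(
                site.interval.chrom,
                max(0, site.interval.start - pad_l),
                min(config.chrom_length, site.interval.end + pad_r),
            ))
    # decoys: placed at least 2 kb from every planted site
    site_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in truth.sites:
        site_by_chrom.setdefault(s.interval.chrom, []).append(
            (s.interval.start, s.interval.end))
    placed = 0
    attempts = 0
    while placed < config.n_decoy_domains and attempts < 100 * config.n_decoy_domains:
        attempts += 1
        p = int(rng.integers(0, config.genome_length))
        length = int(rng.integers(500, 3000))
        ci, pos = divmod(p, config.chrom_length)
        chrom = f"chr{min(ci, config.n_chrom - 1) + 1}"
        end = min(config.chrom_length, pos + length)
        if pos >= end:
            continue
        if any(pos - 2000 < se and pos + length + 2000 > ss
               for ss, se in site_by_chrom.get(chrom, [])):
            continue
        domains.append(GenomicInterval(chrom, pos, end))
        placed += 1
    domains.sort(key=lambda d: (d.chrom, d.start))
    return domains


# ---------------------------------------------------------------------------
# expression and regulatory edges


def simulate_expression(truth: SyntheticTruth, config: SyntheticConfig,
                        factor: str = "B") -> pd.DataFrame:
    """Knockout expression table for one factor.

    Genes linked to the factor's specific sites are differentially expressed
    with probability ``de_frac`` (direct response); unlinked genes are added
    as indirect response in the ratio (1 - de_frac)/de_frac to the realized
    direct count, so the direct fraction among DE genes is centred on
    ``de_frac`` (and de_frac = 0 yields a pure null table).  Null genes get
    centred log2 fold changes and uniform p-values; a BH-FDR column is added.
    """
    if factor not in {"A", "B"}:
        raise ValueError(f"unknown factor {factor!r}")
    rng = _rng(config, f"expression_{factor}")
    specific_class = A_ONLY if factor == "A" else B_ONLY
    linked = truth.linked_genes(specific_class)
    _, tss_table = generate_genome(config)  # deterministic regeneration
    all_genes = list(tss_table.gene_id)
    linked_set = set(linked)
    unlinked = [g for g in all_genes if g not in linked_set]

    direct_de = [g for g in linked if rng.random() < config.de_frac]
    if config.de_frac > 0:
        n_indirect = int(round(len(direct_de) * (1 - config.de_frac)
                               / config.de_frac))
    else:
        n_indirect = 0
    n_indirect = min(n_indirect, len(unlinked))
    indirect_de = list(rng.choice(unlinked, size=n_indirect, replace=False))
    de_set = set(direct_de) | set(indirect_de)

    rows = []
    for g in all_genes:
        if g in de_set:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            lfc = sign * config.effect_log2fc + rng.normal(0, config.de_noise_sd)
            p = 10.0 ** rng.uniform(-8, -4)
        else:
            lfc = rng.normal(0, config.null_log2fc_sd)
            p = float(rng.uniform())
        rows.append({"gene_id": g, "log2fc": lfc, "pvalue": p})
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    direct_set = set(direct_de)
    for site in truth.by_class(specific_class):
        site.is_de = site.linked_gene in direct_set
    return df


def simulate_edges(truth: SyntheticTruth, config: SyntheticConfig,
                   factor: str = "B") -> pd.DataFrame:
    """Regulator->target edges: planted edges among the factor's specific-site
    genes (detectable feed-forward loops) plus decoy edges with at least one
    unbound endpoint."""
    rng = _rng(config, "edges")
    specific_class = A_ONLY if factor == "A" else B_ONLY
    linked = truth.linked_genes(specific_class)
    _, tss_table = generate_genome(config)
    others = [g for g in tss_table.gene_id if g not in set(linked)]
    edges: set[tuple[str, str]] = set()
    n_possible = len(linked) * (len(linked) - 1)
    target = min(config.n_true_edges, n_possible)
    while len(edges) < target:
        r, t = rng.choice(linked, size=2, replace=False)
        if r != t:
            edges.add((str(r), str(t)))
    rows = [{"regulator": r, "target": t, "annotation": "planted"}
            for r, t in sorted(edges)]
    for _ in range(config.n_decoy_edges):
        r = str(rng.choice(others))
        t = str(rng.choice(linked)) if rng.random() < 0.5 and linked else str(rng.choice(others))
        if r != t:
            rows.append({"regulator": r, "target": t, "annotation": "decoy"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-call dataset


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: dict[str, str]
    tss_table: pd.DataFrame
    truth: SyntheticTruth
    tags_a: TagCollection
    tags_b: TagCollection
    tags_input: TagCollection
    domains: list[GenomicInterval]
    expression_a: pd.DataFrame
    expression_b: pd.DataFrame
    edges: pd.DataFrame


def generate_dataset(config: SyntheticConfig,
                     outdir: str | Path | None = None) -> SyntheticDataset:
    """Run every generator stage; optionally write all standard-format files."""
    genome_arr, tss_table = generate_genome(config)
    truth = plant_sites(genome_arr, tss_table, config)
    tags_a = simulate_tags(truth, config, "A")
    tags_b = simulate_tags(truth, config, "B")
    tags_input = simulate_tags(truth, config, "input")
    domains = simulate_domains(truth, config)
    expression_a = simulate_expression(truth, config, factor="A")
    expression_b = simulate_expression(truth, config, factor="B")
    edges = simulate_edges(truth, config, factor="B")
    ds = SyntheticDataset(
        config=config, genome=genome_to_strings(genome_arr),
        tss_table=tss_table, truth=truth, tags_a=tags_a, tags_b=tags_b,
        tags_input=tags_input, domains=domains, expression_a=expression_a,
        expression_b=expression_b, edges=edges,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(ds.genome, outdir / "genome.fa")
        write_tss_table(tss_table, outdir / "tss.tsv")
        write_tags(tags_a, outdir / "tags_A.bed")
        write_tags(tags_b, outdir / "tags_B.bed")
        write_tags(tags_input, outdir / "tags_input.bed")
        write_intervals(domains, outdir / "domains.bed")
        expression_a.to_csv(outdir / "expression_A.tsv", sep="\t", index=False)
        expression_b.to_csv(outdir / "expression_B.tsv", sep="\t", index=False)
        edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
        truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
        config.to_yaml(outdir / "config.yaml")
    return ds
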