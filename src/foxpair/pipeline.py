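"""End-to-end orchestration: simulate -> call -> classify -> motif ->
annotate -> integrate -> report.

Every stage writes its outputs through the standard formats, the run summary
is a flat JSON object whose every number is recomputed from the stage
outputs, and a fixed config+seed reproduces the summary byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import domain_overlap_fraction, tss_histogram
from .config import SyntheticConfig
from .expression import (
    assign_peaks_to_genes,
    direct_targets,
    filter_de,
    find_feed_forward_loops,
)
from .genomic_io import ExpressionRecord, GenomicInterval, write_intervals
from .motifs import (
    FOXA_CONSENSUS,
    DegenerateMotif,
    flanking_profile,
    perfect_fraction,
    pwm_enrichment,
    pwm_from_motif,
)

#: Core consensus extended by the flanking preferences of dual-bound sites
#: (C one base upstream, T immediately downstream); used for PWM enrichment,
#: where the 7-mer core alone is too short to separate long sequences from
#: background at the 0.8 relative-score threshold.
FLANKED_CONSENSUS = DegenerateMotif.from_string("CT[AG]TT[GT]ACT")
from .occupancy import classify_sites
from .peaks import CallerParams, Peak, consensus_call, write_peaks
from .synthetic import SyntheticDataset, generate_dataset

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    caller: CallerParams = field(default_factory=CallerParams)
    density_threshold: float = 1.0
    density_mode: str = "normalized"
    pwm_threshold: float = 0.8
    fc_min: float = 1.5
    fdr_max: float = 0.15
    flank_window: int = 120  # bp around peak midpoints for flank profiling
    seed: int | None = None  # overrides both sub-config seeds when set

    def __post_init__(self) -> None:
        if self.seed is not None:
            self.synthetic = dataclasses.replace(self.synthetic, seed=self.seed)
            self.caller = dataclasses.replace(self.caller, seed=self.seed)
        elif self.caller.seed == 0:
            self.caller = dataclasses.replace(
                self.caller, seed=self.synthetic.seed)


def _class_sequences(peaks: list[Peak], genome: dict[str, str]) -> list[str]:
    return [genome[p.interval.chrom][p.interval.start:p.interval.end]
            for p in peaks]


def _background_intervals(ds: SyntheticDataset, n: int, length: int,
                          seed: int) -> list[GenomicInterval]:
    """Random genome intervals at least 1 kb away from every planted site."""
    rng = np.random.default_rng([seed, 77])
    cfg = ds.config
    sites = {}
    for s in ds.truth.sites:
        sites.setdefault(s.interval.chrom, []).append(
            (s.interval.start, s.interval.end))
    out: list[GenomicInterval] = []
    attempts = 0
    while len(out) < n and attempts < 200 * n:
        attempts += 1
        p = int(rng.integers(0, cfg.genome_length - length))
        ci, pos = divmod(p, cfg.chrom_length)
        chrom = f"chr{min(ci, cfg.n_chrom - 1) + 1}"
        end = pos + length
        if end > cfg.chrom_length:
            continue
        if any(pos - 1000 < se and end + 1000 > ss
               for ss, se in sites.get(chrom, [])):
            continue
        out.append(GenomicInterval(chrom, pos, end))
    return out


def _recall(sites, peaks: list[Peak]) -> float:
    """Fraction of planted sites overlapping >=1 peak of the given set."""
    if not sites:
        return 0.0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(
            (p.interval.start, p.interval.end))
    n = 0
    for s in sites:
        iv = s.interval
        if any(ss < iv.end and se > iv.start
               for ss, se in by_chrom.get(iv.chrom, [])):
            n += 1
    return n / len(sites)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute every stage on a synthetic experiment and return the summary.

    When ``outdir`` is given, all per-stage outputs (BED/TSV/FASTA), the JSON
    summary and a markdown report are written beneath it.
    """
    outdir = Path(outdir) if outdir is not None else None
    syn = config.synthetic
    data_dir = outdir / "data" if outdir else None
    ds = generate_dataset(syn, data_dir)
    chrom_sizes = {f"chr{i + 1}": syn.chrom_length for i in range(syn.n_chrom)}

    # --- peak calling -----------------------------------------------------
    log.info("consensus peak calling, factor A (%d tags)", ds.tags_a.total)
    peaks_a = consensus_call(ds.tags_a, ds.tags_input, config.caller,
                             chrom_sizes, factor_label="A")
    log.info("consensus peak calling, factor B (%d tags)", ds.tags_b.total)
    peaks_b = consensus_call(ds.tags_b, ds.tags_input, config.caller,
                             chrom_sizes, factor_label="B")

    # --- occupancy classification ----------------------------------------
    cls = classify_sites(peaks_a, peaks_b, ds.tags_a, ds.tags_b,
                         threshold=config.density_threshold,
                         density_mode=config.density_mode,
                         fragment_len=config.caller.fragment_len)
    class_peaks = {"common": cls.common, "a_only": cls.a_only,
                   "b_only": cls.b_only}

    # --- motif analysis ---------------------------------------------------
    seqs = {name: _class_sequences(p, ds.genome)
            for name, p in class_peaks.items()}
    motif_stats = {}
    for name, ss in seqs.items():
        if ss:
            n, frac = perfect_fraction(ss, FOXA_CONSENSUS)
            motif_stats[name] = {"n_perfect": n, "perfect_fraction": frac}
        else:
            motif_stats[name] = {"n_perfect": 0, "perfect_fraction": 0.0}

    # flanks are profiled in a fixed window around peak midpoints: the full
    # regions are long enough to pick up chance consensus occurrences whose
    # random flanks would dilute the planted signal
    flank = {}
    if cls.common:
        half = config.flank_window // 2
        windows = []
        for p in cls.common:
            chrom, mid = p.interval.chrom, p.interval.midpoint
            lo = max(0, mid - half)
            windows.append(ds.genome[chrom][lo:mid + half])
        prof = flanking_profile(windows, FOXA_CONSENSUS, up=3, down=3)
        for off in (-1, 1):
            base, freq = prof.modal_base(off)
            flank[f"pos{off:+d}"] = {"base": base, "freq": freq}
        flank["n_matches"] = prof.n_matches

    pwm = pwm_from_motif(FLANKED_CONSENSUS, name="forkhead_flanked")
    enrich = {}
    if seqs["common"]:
        length = int(np.median([len(s) for s in seqs["common"]]))
        bg_ivs = _background_intervals(ds, len(seqs["common"]), length,
                                       seed=syn.seed)
        bg_seqs = [ds.genome[iv.chrom][iv.start:iv.end] for iv in bg_ivs]
        odds, p = pwm_enrichment(seqs["common"], bg_seqs, pwm,
                                 threshold=config.pwm_threshold)
        enrich = {"pwm": pwm.name, "odds_ratio": odds, "p_value": p,
                  "n_background": len(bg_seqs)}

    # --- annotation -------------------------------------------------------
    annotation = {}
    for name, pk in class_peaks.items():
        entry = {}
        if pk:
            hist = tss_histogram(pk, ds.tss_table)
            n_dom, frac_dom = domain_overlap_fraction(pk, ds.domains)
            entry = {"frac_within_10kb": hist.frac_within_10kb,
                     "domain_overlap_fraction": frac_dom,
                     "n_in_domain": n_dom}
        annotation[name] = entry

    # --- expression integration ------------------------------------------
    integration = {}
    loops: list = []
    for factor, table, pk in (("A", ds.expression_a, cls.a_only),
                              ("B", ds.expression_b, cls.b_only)):
        records = [ExpressionRecord(r.gene_id, r.log2fc, r.pvalue, r.fdr)
                   for r in table.itertuples(index=False)]
        de = filter_de(records, fc_min=config.fc_min, fdr_max=config.fdr_max)
        bound = assign_peaks_to_genes(pk, ds.tss_table,
                                      window=syn.assign_window)
        report = direct_targets(bound, de, factor)
        integration[factor] = {
            "n_bound_genes": report.n_bound_genes,
            "n_de_genes": report.n_de_genes,
            "n_direct": report.n_direct,
            "fraction_of_de": report.fraction_of_de,
        }
        if factor == "B":
            loops = find_feed_forward_loops("B", set(bound), ds.edges)

    # --- planted-truth recovery ------------------------------------------
    recovery = {
        "shared_to_common": _recall(ds.truth.by_class("shared"), cls.common),
        "a_only_to_a_only": _recall(ds.truth.by_class("a_only"), cls.a_only),
        "b_only_to_b_only": _recall(ds.truth.by_class("b_only"), cls.b_only),
    }

    summary = {
        "seed": syn.seed,
        "config": dataclasses.asdict(syn),
        "caller": dataclasses.asdict(config.caller),
        "density_threshold": config.density_threshold,
        "density_mode": config.density_mode,
        "library_totals": {"A": ds.tags_a.total, "B": ds.tags_b.total,
                           "input": ds.tags_input.total},
        "n_peaks": {"A": len(peaks_a), "B": len(peaks_b)},
        "site_counts": cls.counts(),
        "motif": motif_stats,
        "flank": flank,
        "pwm_enrichment": enrich,
        "annotation": annotation,
        "integration": integration,
        "n_feed_forward_loops": len(loops),
        "feed_forward_loops": [list(t) for t in loops],
        "truth_recovery": recovery,
    }

    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        write_peaks(peaks_a, outdir / "peaks_A.bed")
        write_peaks(peaks_b, outdir / "peaks_B.bed")
        for name, pk in class_peaks.items():
            write_intervals([p.interval for p in pk],
                            outdir / f"sites_{name}.bed")
        write_summary(summary, outdir / "summary.json")
        (outdir / "report.md").write_text(emit_report(summary))
    return summary


def write_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def emit_report(summary: dict) -> str:
    """Human-readable markdown report; every number comes from the summary."""
    s = summary
    lines = [
        "# Two-factor occupancy analysis report",
        "",
        f"Seed: {s['seed']}",
        "",
        "## Site classes",
        "",
        "| class | count |",
        "|---|---|",
    ]
    for k, v in s["site_counts"].items():
        lines.append(f"| {k} | {v} |")
    lines += ["", "## Motif content (perfect consensus fraction)", "",
              "| class | n with perfect | fraction |", "|---|---|---|"]
    for k, v in s["motif"].items():
        lines.append(f"| {k} | {v['n_perfect']} | {v['perfect_fraction']:.3f} |")
    if s["flank"]:
        lines += ["", "## Flanking preferences at common sites", ""]
        for off in ("pos-1", "pos+1"):
            if off in s["flank"]:
                e = s["flank"][off]
                lines.append(f"- {off}: modal base {e['base']} "
                             f"(freq {e['freq']:.3f})")
    lines += ["", "## Annotation", "",
              "| class | domain overlap | within 10 kb of TSS |",
              "|---|---|---|"]
    for k, v in s["annotation"].items():
        if v:
            lines.append(f"| {k} | {v['domain_overlap_fraction']:.3f} | "
                         f"{v['frac_within_10kb']:.3f} |")
        else:
            lines.append(f"| {k} | 0 | 0 |")
    lines += ["", "## Expression integration", "",
              "| factor | bound genes | DE genes | direct | fraction of DE |",
              "|---|---|---|---|---|"]
    for k, v in s["integration"].items():
        lines.append(f"| {k} | {v['n_bound_genes']} | {v['n_de_genes']} | "
                     f"{v['n_direct']} | {v['fraction_of_de']:.3f} |")
    lines += ["", f"Feed-forward loops (factor B): {s['n_feed_forward_loops']}",
              ""]
    return "\n".join(lines)
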