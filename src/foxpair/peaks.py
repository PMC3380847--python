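"""Enrichment peak calling with an empirical FDR and subsample consensus.

The caller finds maximal runs of fragment coverage above a floor, scores
each candidate by library-size-normalized fold change over input, and sets
the retention threshold by an empirical false-discovery estimate: a
pseudo-ChIP of the same size as the ChIP library is drawn from the input
pool and called identically, and the smallest fold change f with

    FDR(f) = #(pseudo candidates with FC >= f) / #(ChIP candidates with FC >= f)

at or below the target is used as the cutoff.

The consensus wrapper repeats the call on ``n_runs`` random subsamples of
the ChIP library, union-merges the per-run peaks, and keeps merged regions
supported by at least ``min_runs`` runs — the reproducibility filter used
for all downstream site sets.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np

from .genomic_io import GenomicInterval, TagCollection

log = logging.getLogger(__name__)


@dataclass
class Peak:
    interval: GenomicInterval
    chip_tags: int
    input_tags: int
    fold_change: float
    run_support: int = 0
    factor_label: str = ""

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")


@dataclass
class CallerParams:
    fragment_len: int = 150
    min_coverage: int = 2
    pseudocount: float = 1.0
    fdr_target: float = 0.05
    n_runs: int = 10
    subsample_size: int | None = None  # None -> 90% of chip.total per run
    min_runs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_target < 1:
            raise ValueError("fdr_target must lie in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 1 <= self.min_runs <= self.n_runs:
            raise ValueError("need 1 <= min_runs <= n_runs")


# ---------------------------------------------------------------------------
# fragment geometry


def extended_fragments(tags: TagCollection, fragment_len: int,
                       chrom_sizes: dict[str, int] | None = None
                       ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends) of tags extended to ``fragment_len`` in
    their 3' direction from the 5' end, clipped to chromosome bounds."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in tags.records:
        if fragment_len < (r.end - r.start):
            raise ValueError(
                f"fragment_len {fragment_len} shorter than read {r}"
            )
        if r.strand == "+":
            s, e = r.start, r.start + fragment_len
        else:
            s, e = r.end - fragment_len, r.end
        by_chrom.setdefault(r.chrom, []).append((s, e))
    out = {}
    for chrom, pairs in by_chrom.items():
        arr = np.array(pairs, dtype=np.int64)
        starts, ends = arr[:, 0], arr[:, 1]
        hi = chrom_sizes[chrom] if chrom_sizes else None
        starts = np.clip(starts, 0, hi)
        if hi is not None:
            ends = np.clip(ends, 0, hi)
        out[chrom] = (starts, ends)
    return out


def coverage_profile(tags: TagCollection, fragment_len: int,
                     chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-base count of extended fragments covering each position."""
    frags = extended_fragments(tags, fragment_len, chrom_sizes)
    cov = {}
    for chrom, size in chrom_sizes.items():
        diff = np.zeros(size + 1, dtype=np.int32)
        if chrom in frags:
            starts, ends = frags[chrom]
            np.add.at(diff, starts, 1)
            np.add.at(diff, ends, -1)
        cov[chrom] = np.cumsum(diff[:-1]).astype(np.int32)
    return cov


def _candidate_intervals(cov: np.ndarray, min_coverage: int) -> np.ndarray:
    """Maximal runs with coverage >= min_coverage, as an (n, 2) array."""
    above = cov >= min_coverage
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(cov)]
    return np.column_stack([starts, ends])


def _count_overlapping(frag_starts: np.ndarray, frag_ends: np.ndarray,
                       region_starts: np.ndarray, region_ends: np.ndarray
                       ) -> np.ndarray:
    """#fragments overlapping each region by >=1 bp (sorted-array counting)."""
    ss = np.sort(frag_starts)
    es = np.sort(frag_ends)
    return (np.searchsorted(ss, region_ends, side="left")
            - np.searchsorted(es, region_starts, side="right"))


def infer_chrom_sizes(*collections: TagCollection) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for tc in collections:
        for r in tc.records:
            sizes[r.chrom] = max(sizes.get(r.chrom, 0), r.end)
    return sizes


# ---------------------------------------------------------------------------
# single-run caller


def _call_raw(chip_frags, input_frags, chip_total, input_total, params,
              chrom_sizes) -> list[tuple[str, int, int, int, int, float]]:
    """Candidate regions with tag counts and fold changes (no FDR filter)."""
    pc = params.pseudocount
    out = []
    for chrom, size in chrom_sizes.items():
        if chrom not in chip_frags:
            continue
        starts, ends = chip_frags[chrom]
        diff = np.zeros(size + 1, dtype=np.int32)
        np.add.at(diff, starts, 1)
        np.add.at(diff, ends, -1)
        cov = np.cumsum(diff[:-1])
        if not (cov >= params.min_coverage).any():
            continue
        cands = _candidate_intervals(cov, params.min_coverage)
        c_counts = _count_overlapping(starts, ends, cands[:, 0], cands[:, 1])
        if chrom in input_frags:
            istarts, iends = input_frags[chrom]
            i_counts = _count_overlapping(istarts, iends, cands[:, 0], cands[:, 1])
        else:
            i_counts = np.zeros(len(cands), dtype=np.int64)
        fc = (((c_counts + pc) / chip_total)
              / ((i_counts + pc) / input_total))
        for (s, e), cc, ic, f in zip(cands, c_counts, i_counts, fc):
            out.append((chrom, int(s), int(e), int(cc), int(ic), float(f)))
    return out


def _fdr_threshold(chip_fcs: np.ndarray, pseudo_fcs: np.ndarray,
                   fdr_target: float) -> float | None:
    """Smallest candidate fold change f with FDR(f) <= target, or None."""
    if len(chip_fcs) == 0:
        return None
    thresholds = np.unique(chip_fcs)  # ascending
    chip_sorted = np.sort(chip_fcs)
    pseudo_sorted = np.sort(pseudo_fcs)
    n_chip = len(chip_fcs) - np.searchsorted(chip_sorted, thresholds, side="left")
    n_pseudo = len(pseudo_fcs) - np.searchsorted(pseudo_sorted, thresholds, side="left")
    fdr = n_pseudo / n_chip
    ok = np.flatnonzero(fdr <= fdr_target)
    if len(ok) == 0:
        return None
    return float(thresholds[ok[0]])


def call_candidate_regions(chip: TagCollection, input_tags: TagCollection,
                           params: CallerParams,
                           chrom_sizes: dict[str, int] | None = None,
                           factor_label: str = "") -> list[Peak]:
    """Call enriched regions for one ChIP library against input at the
    caller's empirical-FDR target."""
    if chip.total == 0 or input_tags.total == 0:
        raise ValueError("both chip and input libraries must be non-empty")
    if chrom_sizes is None:
        chrom_sizes = infer_chrom_sizes(chip, input_tags)
    chip_frags = extended_fragments(chip, params.fragment_len, chrom_sizes)
    input_frags = extended_fragments(input_tags, params.fragment_len, chrom_sizes)

    chip_cands = _call_raw(chip_frags, input_frags, chip.total,
                           input_tags.total, params, chrom_sizes)

    # pseudo-ChIP drawn from input; score against the remaining input.
    # The draw is seeded from the caller seed plus a fingerprint of the chip
    # library, so the caller is a deterministic function of its inputs while
    # distinct subsamples (in consensus mode) get independent pseudo draws.
    fingerprint = zlib.crc32(
        np.array([r.start for r in chip.records], dtype=np.int64).tobytes())
    rng = np.random.default_rng([abs(params.seed), 901, fingerprint])
    n = chip.total
    if input_tags.total >= n:
        perm = rng.permutation(input_tags.total)
        pseudo_idx, rest_idx = perm[:n], perm[n:]
    else:
        log.warning("input smaller than chip (%d < %d): pseudo-ChIP drawn "
                    "with replacement", input_tags.total, n)
        pseudo_idx = rng.integers(0, input_tags.total, size=n)
        rest_idx = np.arange(input_tags.total)
    if len(rest_idx) == 0:
        log.warning("no input left after pseudo-ChIP draw; scoring against "
                    "the full input pool")
        rest_idx = np.arange(input_tags.total)
    pseudo = TagCollection([input_tags.records[i] for i in pseudo_idx], "pseudo")
    rest = TagCollection([input_tags.records[i] for i in rest_idx], "rest")
    pseudo_frags = extended_fragments(pseudo, params.fragment_len, chrom_sizes)
    rest_frags = extended_fragments(rest, params.fragment_len, chrom_sizes)
    pseudo_cands = _call_raw(pseudo_frags, rest_frags, pseudo.total,
                             rest.total, params, chrom_sizes)

    chip_fcs = np.array([c[5] for c in chip_cands])
    pseudo_fcs = np.array([c[5] for c in pseudo_cands])
    f_min = _fdr_threshold(chip_fcs, pseudo_fcs, params.fdr_target)
    if f_min is None:
        return []
    return [
        Peak(GenomicInterval(chrom, s, e), cc, ic, f, factor_label=factor_label)
        for chrom, s, e, cc, ic, f in chip_cands
        if f >= f_min
    ]


# ---------------------------------------------------------------------------
# interval merging


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal disjoint set covering the union of the inputs."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def _requantify(intervals: list[GenomicInterval], chip: TagCollection,
                input_tags: TagCollection, params: CallerParams,
                chrom_sizes: dict[str, int], factor_label: str,
                supports: list[int] | None = None) -> list[Peak]:
    """Recompute tag counts and fold changes on a fixed set of intervals."""
    chip_frags = extended_fragments(chip, params.fragment_len, chrom_sizes)
    input_frags = extended_fragments(input_tags, params.fragment_len, chrom_sizes)
    pc = params.pseudocount
    peaks = []
    for i, iv in enumerate(intervals):
        cc = ic = 0
        if iv.chrom in chip_frags:
            s, e = chip_frags[iv.chrom]
            cc = int(_count_overlapping(s, e, np.array([iv.start]),
                                        np.array([iv.end]))[0])
        if iv.chrom in input_frags:
            s, e = input_frags[iv.chrom]
            ic = int(_count_overlapping(s, e, np.array([iv.start]),
                                        np.array([iv.end]))[0])
        fc = ((cc + pc) / chip.total) / ((ic + pc) / input_tags.total)
        peaks.append(Peak(iv, cc, ic, float(fc),
                          run_support=supports[i] if supports else 0,
                          factor_label=factor_label))
    return peaks


def merge_regions(*peak_sets: list[Peak], chip: TagCollection | None = None,
                  input_tags: TagCollection | None = None,
                  params: CallerParams | None = None,
                  factor_label: str = "") -> list[Peak]:
    """Union-merge any number of peak sets into disjoint regions; when the
    libraries are supplied, tag counts are recomputed on the merged regions."""
    intervals = [p.interval for ps in peak_sets for p in ps]
    merged = merge_intervals(intervals)
    if chip is None or input_tags is None:
        return [Peak(iv, 0, 0, 1.0, factor_label=factor_label) for iv in merged]
    params = params or CallerParams()
    sizes = infer_chrom_sizes(chip, input_tags)
    for iv in merged:
        sizes[iv.chrom] = max(sizes.get(iv.chrom, 0), iv.end)
    return _requantify(merged, chip, input_tags, params, sizes, factor_label)


def _support_counts(merged: list[GenomicInterval],
                    run_sets: list[list[Peak]]) -> list[int]:
    """#runs contributing >=1 bp of overlap to each merged region."""
    supports = [0] * len(merged)
    by_chrom_idx: dict[str, list[int]] = {}
    for i, iv in enumerate(merged):
        by_chrom_idx.setdefault(iv.chrom, []).append(i)
    for run in run_sets:
        hit = set()
        frags: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for p in run:
            frags.setdefault(p.interval.chrom, ([], []))
            frags[p.interval.chrom][0].append(p.interval.start)
            frags[p.interval.chrom][1].append(p.interval.end)
        for chrom, idxs in by_chrom_idx.items():
            if chrom not in frags:
                continue
            ss = np.sort(np.array(frags[chrom][0]))
            es = np.sort(np.array(frags[chrom][1]))
            for i in idxs:
                iv = merged[i]
                n = (np.searchsorted(ss, iv.end, side="left")
                     - np.searchsorted(es, iv.start, side="right"))
                if n > 0:
                    hit.add(i)
        for i in hit:
            supports[i] += 1
    return supports


def consensus_call(chip: TagCollection, input_tags: TagCollection,
                   params: CallerParams,
                   chrom_sizes: dict[str, int] | None = None,
                   factor_label: str = "") -> list[Peak]:
    """Random-subsample consensus peak calling.

    ``n_runs`` independent subsamples of the ChIP library (without
    replacement) are each called against input; the per-run peak sets are
    union-merged, each merged region's run support is the number of runs
    contributing at least one overlapping peak, and regions supported by
    fewer than ``min_runs`` runs are dropped.  Counts and fold changes of
    the surviving regions are recomputed on the full libraries.
    """
    if chrom_sizes is None:
        chrom_sizes = infer_chrom_sizes(chip, input_tags)
    size = params.subsample_size
    if size is None:
        size = max(1, int(0.9 * chip.total))
    if size > chip.total:
        log.warning("subsample_size %d > chip total %d: using all tags",
                    size, chip.total)
        size = chip.total
    run_sets: list[list[Peak]] = []
    for r in range(params.n_runs):
        rng = np.random.default_rng([abs(params.seed), 701, r])
        idx = rng.choice(chip.total, size=size, replace=False)
        sub = TagCollection([chip.records[i] for i in np.sort(idx)],
                            f"{chip.library_label}#run{r}")
        # run-to-run variation comes from the chip subsample alone: the
        # pseudo-ChIP draw is seeded identically, so a full-size subsample
        # makes every run identical (run_support 0 or n_runs)
        run_sets.append(call_candidate_regions(
            sub, input_tags, params, chrom_sizes, factor_label))
    merged = merge_intervals([p.interval for rs in run_sets for p in rs])
    supports = _support_counts(merged, run_sets)
    keep = [(iv, s) for iv, s in zip(merged, supports) if s >= params.min_runs]
    if not keep:
        return []
    intervals, supports = [list(t) for t in zip(*keep)]
    return _requantify(intervals, chip, input_tags, params, chrom_sizes,
                       factor_label, supports)


# ---------------------------------------------------------------------------
# peak I/O (BED6+3: name, FC as score, strand '.', chip, input, run_support)


def write_peaks(peaks: list[Peak], path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak{i}\t"
                f"{p.fold_change:.6g}\t.\t{p.chip_tags}\t{p.input_tags}\t"
                f"{p.run_support}\n"
            )


def read_peaks(path, factor_label: str = "") -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            peaks.append(Peak(
                GenomicInterval(f[0], int(f[1]), int(f[2])),
                chip_tags=int(f[6]) if len(f) > 6 else 0,
                input_tags=int(f[7]) if len(f) > 7 else 0,
                fold_change=float(f[4]),
                run_support=int(f[8]) if len(f) > 8 else 0,
                factor_label=factor_label,
            ))
    return peaks
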