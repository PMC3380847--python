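"""Independent brute-force oracles used to validate the package's optimized
implementations.  These deliberately share no code with the package beyond
the public data types."""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import hypergeom

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(COMP[b] for b in reversed(s))


def brute_scan(seq: str, variants: set[str], max_mismatch: int
               ) -> set[tuple[int, str, int]]:
    """All (offset, strand, mismatches) by enumerating every offset, strand
    and expanded variant."""
    k = len(next(iter(variants)))
    out = set()
    for strand in ("+", "-"):
        targets = variants if strand == "+" else {revcomp(v) for v in variants}
        for off in range(len(seq) - k + 1):
            window = seq[off:off + k]
            d = min(sum(a != b for a, b in zip(window, v)) for v in targets)
            if d <= max_mismatch:
                out.add((off, strand, d))
    return out


def brute_pwm_max_relative(seq: str, matrix: np.ndarray,
                           background: np.ndarray, eps: float = 1e-4) -> float:
    """Max relative PWM score by looping over every offset of both strands."""
    lo = np.log(np.maximum(matrix, eps) / np.maximum(background, eps)[None, :])
    s_min, s_max = lo.min(axis=1).sum(), lo.max(axis=1).sum()
    L = matrix.shape[0]
    best = -math.inf
    for s in (seq, revcomp(seq)):
        for off in range(len(s) - L + 1):
            score = sum(lo[j, "ACGT".index(s[off + j])] for j in range(L))
            best = max(best, score)
    return (best - s_min) / (s_max - s_min)


def brute_merge(intervals: list[tuple[str, int, int]]
                ) -> list[tuple[str, int, int]]:
    """Union of intervals via a per-base boolean mask."""
    out = []
    for chrom in sorted({c for c, _, _ in intervals}):
        ivs = [(s, e) for c, s, e in intervals if c == chrom]
        hi = max(e for _, e in ivs)
        mask = np.zeros(hi + 1, dtype=bool)
        for s, e in ivs:
            mask[s:e] = True
        d = np.diff(mask.astype(int))
        starts = list(np.flatnonzero(d == 1) + 1)
        ends = list(np.flatnonzero(d == -1) + 1)
        if mask[0]:
            starts = [0] + starts
        if mask[-1]:
            ends = ends + [len(mask)]
        out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out


def brute_nearest_tss(chrom: str, mid: int, tss_rows: list[dict]
                      ) -> tuple[str | None, float]:
    """All-pairs minimization with ties toward the smaller signed value."""
    best = None
    for row in tss_rows:
        if row["chrom"] != chrom:
            continue
        d = mid - row["tss"]
        if row["strand"] == "-":
            d = -d
        key = (abs(d), d)
        if best is None or key < best[0]:
            best = (key, row["gene_id"], d)
    if best is None:
        return None, math.inf
    return best[1], float(best[2])


def brute_gene_map(peaks: list[tuple[str, int, int]], tss_rows: list[dict],
                   window: int) -> dict[str, set[int]]:
    out: dict[str, set[int]] = {}
    for i, (chrom, s, e) in enumerate(peaks):
        mid = (s + e) // 2
        for row in tss_rows:
            if row["chrom"] == chrom and abs(mid - row["tss"]) <= window:
                out.setdefault(row["gene_id"], set()).add(i)
    return out


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p by point-probability enumeration over the
    hypergeometric distribution with fixed margins."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, row1, col1)
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(lo, hi + 1):
        p = rv.pmf(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def brute_ffl(factor: str, bound: set[str],
              edges: list[tuple[str, str]]) -> list[tuple[str, str, str]]:
    out = set()
    for r, t in edges:
        if r != t and r in bound and t in bound:
            out.add((factor, r, t))
    return sorted(out)
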