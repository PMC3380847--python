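"""Partition two factors' peak sets into common, factor-specific, and
ambiguous occupancy classes.

A site is *common* when a factor-A peak overlaps a factor-B peak by at least
one base (overlapping peaks are union-merged).  A remaining factor-A peak is
*A-only* when the normalized density of factor-B tags over it,

    d = n_B * (1e6 / total_B) * (1e3 / L)   [tags per million per kb],

stays at or below the threshold (default 1.0); otherwise the peak is
*ambiguous* — there is cross-factor signal but no called cross-factor peak.
A raw mode (tag count <= threshold, no normalization) is available as the
alternative stringency reading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genomic_io import GenomicInterval, TagCollection
from .peaks import Peak, extended_fragments, merge_intervals

log = logging.getLogger(__name__)


@dataclass
class OccupancyClassification:
    common: list[Peak]
    a_only: list[Peak]
    b_only: list[Peak]
    ambiguous_a: list[Peak]
    ambiguous_b: list[Peak]
    density_threshold: float = 1.0
    density_mode: str = "normalized"

    def counts(self) -> dict[str, int]:
        return {
            "common": len(self.common), "a_only": len(self.a_only),
            "b_only": len(self.b_only), "ambiguous_a": len(self.ambiguous_a),
            "ambiguous_b": len(self.ambiguous_b),
        }


def _overlap_count(frags: dict[str, tuple[np.ndarray, np.ndarray]],
                   iv: GenomicInterval) -> int:
    if iv.chrom not in frags:
        return 0
    starts, ends = frags[iv.chrom]
    ss, es = np.sort(starts), np.sort(ends)
    return int(np.searchsorted(ss, iv.end, side="left")
               - np.searchsorted(es, iv.start, side="right"))


def cross_density(peak: Peak | GenomicInterval, other_tags: TagCollection,
                  fragment_len: int = 150,
                  _frags: dict | None = None) -> float:
    """Tags-per-million-per-kilobase density of the other factor's library
    over a peak; tags count when their extended fragment overlaps by >=1 bp."""
    iv = peak.interval if isinstance(peak, Peak) else peak
    length = iv.end - iv.start
    if length <= 0:
        raise ValueError("zero-length peak")
    if other_tags.total == 0:
        raise ValueError("empty cross-factor library")
    frags = _frags if _frags is not None else extended_fragments(
        other_tags, fragment_len)
    n = _overlap_count(frags, iv)
    return n * (1e6 / other_tags.total) * (1e3 / length)


def _peak_overlaps_any(iv: GenomicInterval,
                       other: dict[str, tuple[np.ndarray, np.ndarray]]) -> bool:
    return _overlap_count(other, iv) > 0


def _interval_index(peaks: list[Peak]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    idx: dict[str, list[list[int]]] = {}
    for p in peaks:
        idx.setdefault(p.interval.chrom, [[], []])
        idx[p.interval.chrom][0].append(p.interval.start)
        idx[p.interval.chrom][1].append(p.interval.end)
    return {c: (np.array(v[0]), np.array(v[1])) for c, (v) in idx.items()}


def classify_sites(peaks_a: list[Peak], peaks_b: list[Peak],
                   tags_a: TagCollection, tags_b: TagCollection,
                   threshold: float = 1.0, density_mode: str = "normalized",
                   fragment_len: int = 150) -> OccupancyClassification:
    """Classify both factors' peaks into common / factor-only / ambiguous.

    The five output sets are pairwise disjoint; every input peak of factor A
    ends up in exactly one of common (via merge), a_only, or ambiguous_a
    (symmetrically for B).
    """
    if density_mode not in {"normalized", "raw"}:
        raise ValueError(f"unknown density_mode {density_mode!r}")
    chroms_a = {p.interval.chrom for p in peaks_a}
    chroms_b = {p.interval.chrom for p in peaks_b}
    if peaks_a and peaks_b and chroms_a.isdisjoint(chroms_b):
        log.warning("peak sets share no chromosome: classification will "
                    "find no common sites")

    idx_a = _interval_index(peaks_a)
    idx_b = _interval_index(peaks_b)
    common_src_a = [p for p in peaks_a if _peak_overlaps_any(p.interval, idx_b)]
    common_src_b = [p for p in peaks_b if _peak_overlaps_any(p.interval, idx_a)]
    common_ivs = merge_intervals(
        [p.interval for p in common_src_a + common_src_b])
    common = [Peak(iv, 0, 0, 1.0, factor_label="common") for iv in common_ivs]

    frags_b = extended_fragments(tags_b, fragment_len)
    frags_a = extended_fragments(tags_a, fragment_len)

    def split(peaks, common_src, other_tags, other_frags, label):
        only, ambiguous = [], []
        common_ids = {id(p) for p in common_src}
        for p in peaks:
            if id(p) in common_ids:
                continue
            if density_mode == "normalized":
                d = cross_density(p, other_tags, fragment_len, _frags=other_frags)
            else:
                d = _overlap_count(other_frags, p.interval)
            (only if d <= threshold else ambiguous).append(p)
        return only, ambiguous

    a_only, ambiguous_a = split(peaks_a, common_src_a, tags_b, frags_b, "a")
    b_only, ambiguous_b = split(peaks_b, common_src_b, tags_a, frags_a, "b")
    return OccupancyClassification(
        common=common, a_only=a_only, b_only=b_only,
        ambiguous_a=ambiguous_a, ambiguous_b=ambiguous_b,
        density_threshold=threshold, density_mode=density_mode,
    )
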