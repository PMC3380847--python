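"""Degenerate consensus scanning, flanking-base profiling, and PWM enrichment.

The forkhead core recognition consensus used throughout is the degenerate
7-mer T[A/G]TT[G/T]AC (4 exact sequences; the second and fifth positions
vary).  A "degenerate" occurrence is one whose best match to the consensus
carries one or two mismatching bases.

Scanning covers both strands: a minus-strand match is a match of the
reverse-complement pattern on the given sequence.  For a set-valued pattern
the minimum Hamming distance to any expanded variant equals the number of
positions whose base falls outside the allowed set, which is what the
scanner computes (the equivalence is exercised against a brute-force
enumeration in the test suite).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The forkhead core consensus, T[A/G]TT[G/T]AC.
FOXA_CONSENSUS_STRING = "T[AG]TT[GT]AC"


@dataclass(frozen=True)
class DegenerateMotif:
    """An ordered tuple of allowed-base sets, one per motif position."""

    pattern: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        for i, pos in enumerate(self.pattern):
            if not pos or not pos <= set(BASES):
                raise ValueError(f"position {i}: invalid base set {pos!r}")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def n_variants(self) -> int:
        return math.prod(len(p) for p in self.pattern)

    def reverse_complement(self) -> "DegenerateMotif":
        rc = tuple(
            frozenset(_COMP[b] for b in pos) for pos in reversed(self.pattern)
        )
        return DegenerateMotif(rc)

    @classmethod
    def from_string(cls, s: str) -> "DegenerateMotif":
        """Parse a bracket pattern such as ``T[AG]TT[GT]AC``."""
        pattern: list[frozenset[str]] = []
        i = 0
        while i < len(s):
            if s[i] == "[":
                j = s.index("]", i)
                pattern.append(frozenset(s[i + 1 : j]))
                i = j + 1
            else:
                pattern.append(frozenset(s[i]))
                i += 1
        return cls(tuple(pattern))


FOXA_CONSENSUS = DegenerateMotif.from_string(FOXA_CONSENSUS_STRING)


@dataclass(frozen=True)
class MotifMatch:
    sequence_index: int
    offset: int
    strand: str
    mismatches: int


def expand_consensus(motif: DegenerateMotif) -> set[str]:
    """All exact k-mers matching the pattern (count = product of set sizes)."""
    return {
        "".join(combo)
        for combo in itertools.product(*(sorted(p) for p in motif.pattern))
    }


def reverse_complement(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def _mismatch_counts(seq: str, motif: DegenerateMotif) -> np.ndarray:
    """Per-offset minimum Hamming distance of seq windows to the pattern."""
    k = len(motif)
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    mism = np.zeros(n, dtype=np.int64)
    for j, allowed in enumerate(motif.pattern):
        codes = np.array([ord(b) for b in allowed], dtype=np.uint8)
        col = arr[j : j + n]
        ok = np.isin(col, codes)
        mism += ~ok
    return mism


def scan_sequence(
    seq: str,
    motif: DegenerateMotif = FOXA_CONSENSUS,
    max_mismatch: int = 0,
    sequence_index: int = 0,
) -> list[MotifMatch]:
    """Find all occurrences on both strands with at most ``max_mismatch``
    mismatching positions; overlapping matches are all reported."""
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    seq = seq.upper()
    out: list[MotifMatch] = []
    for strand, pat in (("+", motif), ("-", motif.reverse_complement())):
        mism = _mismatch_counts(seq, pat)
        for off in np.flatnonzero(mism <= max_mismatch):
            out.append(MotifMatch(sequence_index, int(off), strand, int(mism[off])))
    out.sort(key=lambda m: (m.offset, m.strand, m.mismatches))
    return out


def perfect_fraction(
    sequences: list[str], motif: DegenerateMotif = FOXA_CONSENSUS
) -> tuple[int, float]:
    """How many sequences contain >=1 perfect (0-mismatch) occurrence on
    either strand, and the corresponding fraction."""
    if not sequences:
        raise ValueError("empty sequence list")
    n = sum(1 for s in sequences if scan_sequence(s, motif, max_mismatch=0))
    return n, n / len(sequences)


@dataclass
class FlankProfile:
    """Position-frequency tables for the bases flanking perfect motif
    occurrences, in match orientation (upstream offsets -up..-1, downstream
    +1..+down)."""

    upstream: pd.DataFrame  # index: offset (-up..-1), columns: A,C,G,T counts
    downstream: pd.DataFrame  # index: offset (1..down)
    n_matches: int

    def modal_base(self, offset: int) -> tuple[str, float]:
        """The most frequent base at a signed flank offset and its frequency."""
        table = self.upstream if offset < 0 else self.downstream
        row = table.loc[offset]
        base = row.idxmax()
        return str(base), float(row[base] / self.n_matches)


def flanking_profile(
    sequences: list[str],
    motif: DegenerateMotif = FOXA_CONSENSUS,
    up: int = 3,
    down: int = 3,
) -> FlankProfile:
    """Tabulate flanking-base counts around every perfect occurrence.

    Matches whose flanks would run off a sequence edge are skipped.  Minus-
    strand flanks are extracted in motif orientation (reverse-complemented).
    """
    k = len(motif)
    up_counts = {off: dict.fromkeys(BASES, 0) for off in range(-up, 0)}
    down_counts = {off: dict.fromkeys(BASES, 0) for off in range(1, down + 1)}
    n_matches = 0
    for seq in sequences:
        seq = seq.upper()
        for m in scan_sequence(seq, motif, max_mismatch=0):
            o = m.offset
            if m.strand == "+":
                if o - up < 0 or o + k + down > len(seq):
                    continue
                up_seq = seq[o - up : o]
                down_seq = seq[o + k : o + k + down]
            else:
                if o - down < 0 or o + k + up > len(seq):
                    continue
                up_seq = reverse_complement(seq[o + k : o + k + up])
                down_seq = reverse_complement(seq[o - down : o])
            n_matches += 1
            for j, base in enumerate(up_seq):  # j=0 is offset -up
                up_counts[j - up][base] += 1
            for j, base in enumerate(down_seq):
                down_counts[j + 1][base] += 1
    if n_matches == 0:
        raise ValueError("no perfect matches; cannot profile flanks")
    up_df = pd.DataFrame(up_counts).T[list(BASES)]
    down_df = pd.DataFrame(down_counts).T[list(BASES)]
    return FlankProfile(upstream=up_df, downstream=down_df, n_matches=n_matches)


# ---------------------------------------------------------------------------
# Position weight matrices


@dataclass
class PWM:
    """Per-position base probabilities with a background distribution.

    ``matrix`` has shape (length, 4), columns ordered A,C,G,T; each row sums
    to 1.  Relative scores rescale the log-odds sum to [0, 1] between the
    worst and best attainable sequence.
    """

    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    name: str = ""

    EPS = 1e-4

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (length, 4)")
        if np.any(self.matrix < 0):
            raise ValueError("PWM entries must be >= 0")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        p = np.maximum(self.matrix, self.EPS)
        bg = np.maximum(self.background, self.EPS)
        return np.log(p / bg[None, :])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    @classmethod
    def from_counts(cls, counts: np.ndarray, name: str = "",
                    background: np.ndarray | None = None,
                    pseudocount: float = 0.0) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        matrix = counts / counts.sum(axis=1, keepdims=True)
        kwargs = {} if background is None else {"background": background}
        return cls(matrix=matrix, name=name, **kwargs)


def pwm_from_motif(motif: DegenerateMotif, name: str = "consensus",
                   pseudocount: float = 0.5) -> PWM:
    """Build a PWM from the expanded variants of a degenerate consensus."""
    counts = np.zeros((len(motif), 4))
    for variant in expand_consensus(motif):
        for i, b in enumerate(variant):
            counts[i, BASES.index(b)] += 1
    return PWM.from_counts(counts, name=name, pseudocount=pseudocount)


def read_jaspar_pfm(path) -> list[PWM]:
    """Read JASPAR plain-text PFM records (4 count rows per motif, optional
    A/C/G/T row labels and bracketed counts)."""
    pwms: list[PWM] = []
    name = ""
    rows: list[list[float]] = []
    order: list[str] = []

    def flush():
        nonlocal rows, order
        if rows:
            counts = np.array(rows).T  # (length, 4) in row order
            if order == list("ACGT") or not order:
                mat = counts
            else:
                mat = np.empty_like(counts)
                for i, b in enumerate(order):
                    mat[:, BASES.index(b)] = counts[:, i]
            pwms.append(PWM.from_counts(mat, name=name, pseudocount=0.8))
        rows, order = [], []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].strip()
                continue
            parts = line.replace("[", " ").replace("]", " ").split()
            if parts[0].upper() in set(BASES):
                order.append(parts[0].upper())
                parts = parts[1:]
            rows.append([float(x) for x in parts])
    flush()
    return pwms


def pwm_relative_score(seq: str, pwm: PWM) -> float:
    """Maximum relative log-odds score of the PWM over all offsets of both
    strands of ``seq``, rescaled to [0, 1]."""
    seq = seq.upper()
    L = len(pwm)
    if len(seq) < L:
        raise ValueError("sequence shorter than PWM")
    lo = pwm.log_odds
    s_min = lo.min(axis=1).sum()
    s_max = lo.max(axis=1).sum()
    idx = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(BASES):
        code[ord(b)] = i
    bidx = code[idx]
    if np.any(bidx < 0):
        raise ValueError("sequence contains non-ACGT characters")
    n = len(seq) - L + 1
    best = -np.inf
    for strand_lo in (lo, lo[::-1, ::-1]):  # forward, reverse-complement
        # score of window at offset o: sum_j strand_lo[j, base[o+j]]
        scores = np.zeros(n)
        for j in range(L):
            scores += strand_lo[j, bidx[j : j + n]]
        best = max(best, float(scores.max()))
    return (best - s_min) / (s_max - s_min)


def pwm_enrichment(
    positive_seqs: list[str],
    negative_seqs: list[str],
    pwm: PWM,
    threshold: float = 0.8,
) -> tuple[float, float]:
    """Sequence-based PWM enrichment: a sequence is a hit iff its maximum
    relative score reaches ``threshold``; the 2x2 hit table is tested by
    Fisher's exact test (two-sided).  Returns (odds ratio, p).

    The odds ratio uses the Haldane half-count correction when any cell is
    zero; the p-value is always the uncorrected exact test.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    if not positive_seqs or not negative_seqs:
        raise ValueError("both sequence sets must be non-empty")
    hp = sum(pwm_relative_score(s, pwm) >= threshold for s in positive_seqs)
    hn = sum(pwm_relative_score(s, pwm) >= threshold for s in negative_seqs)
    a, b = hp, len(positive_seqs) - hp
    c, d = hn, len(negative_seqs) - hn
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)
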