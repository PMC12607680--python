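"""PWM promoter scanning and Yes-vs-No binding-site enrichment.

Scoring is min-max normalised log-odds (Match-style): the raw window score
is the sum of pseudocount-smoothed log-odds weights against a uniform
background, rescaled so the consensus window scores 1.0 and the
anti-consensus 0.0.  N contributes a position's background-expected weight.
Enrichment contrasts site counts against scanned base pairs in the Yes and
No promoter sets with a one-sided Fisher exact test (binomial alternative
by config) and Benjamini-Hochberg control across matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._util import bh_adjust
from .io_formats import PromoterRecord, PromoterSet, PWMatrix

_CODE = np.full(256, 4, dtype=np.int8)  # everything unknown behaves as N
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_PSEUDOCOUNT = 0.1
_BACKGROUND = 0.25


@dataclass(frozen=True)
class SiteMatch:
    matrix_id: str
    gene_id: str
    start: int  # 0-based offset of the site's 5'-most base on the forward strand
    strand: str  # '+' | '-'
    norm_score: float


@dataclass(frozen=True)
class EnrichmentRow:
    matrix_id: str
    tf_symbols: tuple[str, ...]
    yes_site_density: float  # sites per kb
    no_site_density: float
    yes_no_ratio: float  # inf when the No set has zero sites
    p_value: float
    adj_p: float
    enriched: bool


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _weight_table(matrix: PWMatrix) -> tuple[np.ndarray, float, float]:
    """Per-position weights for A,C,G,T,N plus the min/max achievable raw score."""
    counts = matrix.counts
    probs = (counts + _PSEUDOCOUNT) / (counts.sum(axis=1, keepdims=True) + 4 * _PSEUDOCOUNT)
    w = np.log(probs / _BACKGROUND)
    expected = (w * _BACKGROUND).sum(axis=1, keepdims=True)  # N column
    table = np.hstack([w, expected])
    return table, float(w.min(axis=1).sum()), float(w.max(axis=1).sum())


def normalized_pwm_score(matrix: PWMatrix, window_sequence: str) -> float:
    """Normalised score of one window; the window must have the matrix length."""
    if len(window_sequence) != matrix.length:
        raise ValueError(
            f"window length {len(window_sequence)} != matrix length {matrix.length}"
        )
    bad = set(window_sequence.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in window: {sorted(bad)}")
    table, lo, hi = _weight_table(matrix)
    codes = encode_sequence(window_sequence.upper())
    raw = float(table[np.arange(matrix.length), codes].sum())
    return (raw - lo) / (hi - lo)


def window_scores(matrix: PWMatrix, seq_codes: np.ndarray) -> np.ndarray:
    """Normalised scores of every window of one encoded strand (vectorised)."""
    table, lo, hi = _weight_table(matrix)
    length = matrix.length
    n_win = seq_codes.size - length + 1
    if n_win <= 0:
        return np.empty(0)
    raw = np.zeros(n_win)
    for offset in range(length):
        raw += table[offset, seq_codes[offset : offset + n_win]]
    return (raw - lo) / (hi - lo)


def scan_sequence(
    matrix: PWMatrix, gene_id: str, sequence: str, cutoff: float | None = None
) -> list[SiteMatch]:
    """All matches of one matrix on both strands, sorted by forward start.

    Reverse-strand matches are found by scanning the reverse complement and
    reported at the forward coordinate of the site's 5'-most base.
    """
    if cutoff is None:
        cutoff = matrix.cutoff
    seq = sequence.upper()
    n, length = len(seq), matrix.length
    matches: list[SiteMatch] = []
    fwd = window_scores(matrix, encode_sequence(seq))
    for start in np.flatnonzero(fwd >= cutoff):
        matches.append(SiteMatch(matrix.matrix_id, gene_id, int(start), "+", float(fwd[start])))
    rev = window_scores(matrix, encode_sequence(reverse_complement(seq)))
    for start in np.flatnonzero(rev >= cutoff):
        fwd_start = n - length - int(start)
        matches.append(SiteMatch(matrix.matrix_id, gene_id, fwd_start, "-", float(rev[start])))
    matches.sort(key=lambda m: (m.start, m.strand))
    return matches


def scan_promoter(
    matrix: PWMatrix, promoter: PromoterRecord, cutoff: float | None = None
) -> list[SiteMatch]:
    return scan_sequence(matrix, promoter.gene_id, promoter.sequence, cutoff)


def count_sites(
    matrix: PWMatrix, records: Sequence[PromoterRecord], cutoff: float | None = None
) -> int:
    if cutoff is None:
        cutoff = matrix.cutoff
    total = 0
    for rec in records:
        fwd = window_scores(matrix, encode_sequence(rec.sequence))
        rev = window_scores(matrix, encode_sequence(reverse_complement(rec.sequence)))
        total += int((fwd >= cutoff).sum() + (rev >= cutoff).sum())
    return total


def enrich_matrices(
    pwm_library: Sequence[PWMatrix],
    promoters: PromoterSet,
    alpha: float = 0.01,
    cutoff: float | None = None,
    method: str = "fisher",
    background: Sequence[PromoterRecord] | None = None,
) -> list[EnrichmentRow]:
    """Per-matrix Yes-vs-No site enrichment with BH control across matrices.

    ``background`` optionally replaces the No subset with caller-supplied
    sequences (e.g. sampled genomic regions).  ``method`` is 'fisher'
    (one-sided exact, default) or 'binomial'.
    """
    yes = promoters.yes_records
    no = list(background) if background is not None else promoters.no_records
    if not yes or not no:
        raise ValueError("enrichment requires non-empty Yes and No sets")
    yes_bp = sum(len(r.sequence) for r in yes)
    no_bp = sum(len(r.sequence) for r in no)
    if yes_bp == 0 or no_bp == 0:
        raise ValueError("zero scanned bp")
    p_values: list[float] = []
    partial: list[tuple[str, tuple[str, ...], float, float, float]] = []
    for matrix in pwm_library:
        n_yes = count_sites(matrix, yes, cutoff)
        n_no = count_sites(matrix, no, cutoff)
        yes_density = n_yes / yes_bp * 1000.0
        no_density = n_no / no_bp * 1000.0
        ratio = yes_density / no_density if no_density > 0 else float("inf")
        if method == "fisher":
            table = [[n_yes, yes_bp - n_yes], [n_no, no_bp - n_no]]
            p = float(stats.fisher_exact(table, alternative="greater")[1])
        elif method == "binomial":
            rate = (n_yes + n_no) / (yes_bp + no_bp)
            p = float(stats.binomtest(n_yes, yes_bp, rate, alternative="greater").pvalue)
        else:
            raise ValueError(f"unknown enrichment method {method!r}")
        p_values.append(p)
        partial.append((matrix.matrix_id, matrix.tf_symbols, yes_density, no_density, ratio))
    adj = bh_adjust(p_values)
    rows = [
        EnrichmentRow(
            matrix_id=mid,
            tf_symbols=syms,
            yes_site_density=yd,
            no_site_density=nd,
            yes_no_ratio=ratio,
            p_value=p,
            adj_p=float(q),
            enriched=bool(q < alpha),
        )
        for (mid, syms, yd, nd, ratio), p, q in zip(partial, p_values, adj)
    ]
    return rows
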