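"""Motif discovery and testing in short RNAs, and MAZ GA-box scanning.

The nucleus-enriched mature miRNAs of the modeled system share an exact
4-mer ("GAGG"-type) motif.  This module enumerates k-mer support with
per-sequence presence semantics, assembles the motif x localization 2x2
contingency table, computes Fisher's exact test by direct hypergeometric
summation in log space, and scans sequences for the MAZ zinc-finger
GA-box consensus G^n A G^n (n = 2..6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import gammaln, logsumexp

from .containers import MiRNARecord
from .errors import ParameterError
from .seq import require_strict_rna

__all__ = [
    "MotifResult", "ContingencyTable2x2", "MazHit",
    "kmer_support", "find_recurrent_motif", "divergent_members",
    "motif_contingency", "fisher_exact", "maz_scan", "scan_element",
]


@dataclass(frozen=True)
class MotifResult:
    motif: str
    support_enriched: int
    n_enriched: int
    support_background: int = 0
    n_background: int = 0

    def __post_init__(self):
        if not 0 <= self.support_enriched <= self.n_enriched:
            raise ParameterError("enriched support out of range")
        if not 0 <= self.support_background <= max(self.n_background, 0):
            raise ParameterError("background support out of range")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Motif x localization counts.

    a: motif-positive enriched, b: motif-negative enriched,
    c: motif-positive depleted, d: motif-negative depleted.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ParameterError("contingency cells must be non-negative integers")


@dataclass(frozen=True)
class MazHit:
    """One GA-box consensus match: sequence[start : start+2n+1] == G^n A G^n."""

    start: int
    n: int
    matched: str

    def __post_init__(self):
        if len(self.matched) != 2 * self.n + 1:
            raise ParameterError("matched element length must be 2n+1")


# --------------------------------------------------------------------------
# k-mer motif discovery

def kmer_support(seqs, k: int) -> dict[str, int]:
    """Number of sequences containing each k-mer at least once.

    Presence is binary per sequence (multiple copies count once).  Sequences
    shorter than k contribute nothing.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    support: dict[str, int] = {}
    for seq in seqs:
        s = require_strict_rna(seq, context="kmer_support input")
        seen = {s[i:i + k] for i in range(len(s) - k + 1)}
        for kmer in seen:
            support[kmer] = support.get(kmer, 0) + 1
    return support


def find_recurrent_motif(enriched: list[MiRNARecord], k: int,
                         min_support_frac: float = 0.5) -> list[MotifResult]:
    """k-mers supported by at least ceil(min_support_frac * n) of the
    enriched mature sequences, sorted by support (descending), then
    lexicographically."""
    if not 0 < min_support_frac <= 1:
        raise ParameterError("min_support_frac must lie in (0, 1]")
    n = len(enriched)
    if n == 0:
        return []
    support = kmer_support([r.mature_seq for r in enriched], k)
    need = math.ceil(min_support_frac * n)
    hits = [(kmer, cnt) for kmer, cnt in support.items() if cnt >= need]
    hits.sort(key=lambda kc: (-kc[1], kc[0]))
    return [MotifResult(kmer, cnt, n) for kmer, cnt in hits]


def divergent_members(records: list[MiRNARecord], motif: str) -> list[str]:
    """Names of records whose mature sequence lacks ``motif`` (the divergent
    members of a motif-sharing group)."""
    m = require_strict_rna(motif, context="motif")
    return [r.name for r in records
            if m not in require_strict_rna(r.mature_seq, context=r.name)]


# --------------------------------------------------------------------------
# contingency + Fisher's exact test

def motif_contingency(enriched: list[MiRNARecord], background: list[MiRNARecord],
                      motif: str) -> ContingencyTable2x2:
    """Assemble motif-presence counts for the enriched vs depleted groups."""
    names_e = {r.name for r in enriched}
    names_b = {r.name for r in background}
    overlap = names_e & names_b
    if overlap:
        raise ParameterError(f"groups overlap by name: {sorted(overlap)}")
    m = require_strict_rna(motif, context="motif")

    def n_carriers(records):
        return sum(m in require_strict_rna(r.mature_seq, context=r.name)
                   for r in records)

    a = n_carriers(enriched)
    c = n_carriers(background)
    return ContingencyTable2x2(a, len(enriched) - a, c, len(background) - c)


def _log_hypergeom_pmf(a: int, row1: int, row2: int, col1: int) -> float:
    """log P(first cell = a) for fixed margins (row1, row2; col1)."""
    n = row1 + row2

    def logc(nn, kk):
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    return logc(row1, a) + logc(row2, col1 - a) - logc(n, col1)


def fisher_exact(table: ContingencyTable2x2, alternative: str = "greater") -> float:
    """Fisher's exact test by explicit hypergeometric summation.

    ``greater`` sums the tail of tables at least as enriched (first cell >=
    observed); ``two_sided`` sums every table whose point probability does not
    exceed the observed one.  Log-space accumulation keeps tiny tails stable.
    """
    if alternative not in ("greater", "two_sided"):
        raise ParameterError(f"alternative must be 'greater' or 'two_sided', "
                             f"got {alternative!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, row2, col1 = a + b, c + d, a + c
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    log_pmfs = {x: _log_hypergeom_pmf(x, row1, row2, col1) for x in range(lo, hi + 1)}
    if alternative == "greater":
        terms = [lp for x, lp in log_pmfs.items() if x >= a]
    else:
        cutoff = log_pmfs[a] + 1e-9  # tolerate FP ties, as is conventional
        terms = [lp for lp in log_pmfs.values() if lp <= cutoff]
    p = float(math.exp(logsumexp(terms)))
    return min(p, 1.0)


# --------------------------------------------------------------------------
# MAZ GA-box consensus scanning

def maz_scan(seq: str, n_min: int = 2, n_max: int = 6,
             nested: bool = False) -> list[MazHit]:
    """Scan for the MAZ GA-box consensus G^n A G^n with n in [n_min, n_max].

    For each adenosine center the largest admissible arm length is reported
    (maximal munch per center); overlapping centers are all reported.  U and
    T are treated identically (only G and A matter).  With ``nested=True``
    every admissible arm length per center is reported, largest first.
    """
    if n_min < 1:
        raise ParameterError("n_min must be >= 1")
    if n_min > n_max:
        raise ParameterError("n_min must not exceed n_max")
    s = seq.upper().replace("T", "U")
    L = len(s)
    # run of G ending at i (inclusive), and starting at i
    g_end = [0] * L
    g_start = [0] * L
    for i in range(L):
        if s[i] == "G":
            g_end[i] = (g_end[i - 1] if i else 0) + 1
    for i in range(L - 1, -1, -1):
        if s[i] == "G":
            g_start[i] = (g_start[i + 1] if i < L - 1 else 0) + 1
    hits: list[MazHit] = []
    for i in range(L):
        if s[i] != "A":
            continue
        left = g_end[i - 1] if i > 0 else 0
        right = g_start[i + 1] if i < L - 1 else 0
        n = min(left, right, n_max)
        if n < n_min:
            continue
        arms = range(n, n_min - 1, -1) if nested else (n,)
        for m in arms:
            hits.append(MazHit(start=i - m, n=m, matched=s[i - m:i + m + 1]))
    hits.sort(key=lambda h: (h.start, -h.n))
    return hits


def scan_element(records: list[MiRNARecord], element: str,
                 where: str = "mature") -> dict[str, bool]:
    """Plain substring scan of an exact element over a record set.

    Useful for checking candidate localization elements (e.g. the
    hexanucleotide reported to direct miR-29b nuclear import) against a group
    of sequences.  ``where`` selects 'mature' or 'premir' sequences.
    """
    if where not in ("mature", "premir"):
        raise ParameterError("where must be 'mature' or 'premir'")
    e = require_strict_rna(element, context="element")
    out = {}
    for r in records:
        seq = r.mature_seq if where == "mature" else (r.premir_seq or "")
        out[r.name] = e in require_strict_rna(seq, context=r.name) if seq else False
    return out
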