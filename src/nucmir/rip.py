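"""Downstream Ago1/Ago2 RIP-seq computation.

Starting from per-pull-down gene x sample read-count tables (alignment and
counting are upstream), genes with low read counts are filtered out as
amplification noise, the survivors' 3'UTRs are scanned for canonical seed
sites of the nucleus-enriched miRNAs, and the resulting Ago1/Ago2 target sets
are partitioned into unique and shared transcripts.

Seed-site classes follow the canonical taxonomy: a 6mer core is a
Watson-Crick match to miRNA positions 2-7; adding a position-8 pair gives
7mer-m8, an adenosine opposite position 1 gives 7mer-A1, and both give the
8mer.  G:U wobble pairs are not accepted unless requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .containers import CountTable, MiRNARecord
from .errors import ParameterError
from .seq import require_strict_rna, revcomp_rna, comp_rna

log = logging.getLogger(__name__)

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

__all__ = [
    "TargetSite", "RipPartition",
    "filter_counts", "seed_sites", "targets_of_enriched", "partition_targets",
]


@dataclass(frozen=True)
class TargetSite:
    """One seed-match locus in a 3'UTR (0-based, half-open span)."""

    gene_id: str
    mirna: str
    site_type: str
    start: int

    def __post_init__(self):
        if self.site_type not in SITE_TYPES:
            raise ParameterError(f"unknown site type {self.site_type!r}")

    @property
    def length(self) -> int:
        return {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}[self.site_type]

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class RipPartition:
    """Pairwise-disjoint split of two pull-downs' target sets."""

    unique_ago1: frozenset
    unique_ago2: frozenset
    shared: frozenset


def filter_counts(t: CountTable, floor: int) -> CountTable:
    """Retain genes whose total read count across samples reaches ``floor``.

    ``floor=10`` drops genes with fewer than 10 reads; idempotent, and
    monotone in the floor.
    """
    if floor < 0:
        raise ParameterError("count floor must be >= 0")
    keep = t.counts.sum(axis=1) >= floor
    return CountTable(t.counts.loc[keep], t.pulldown)


def seed_sites(utr: str, mature: str, gene_id: str = "", mirna: str = "",
               allow_wobble: bool = False) -> list[TargetSite]:
    """Scan a 3'UTR (5'->3') for canonical seed matches to a mature miRNA.

    The 6mer core in the UTR is the reverse complement of miRNA positions
    2-7.  Each core match is classified once, as its strongest class:
    8mer (position-8 pair + A opposite position 1) > 7mer-m8 > 7mer-A1 >
    6mer.  Reported starts are 0-based offsets of the full matched span.
    """
    u = require_strict_rna(utr, context=f"UTR {gene_id or '<anon>'}")
    m = require_strict_rna(mature, context=f"miRNA {mirna or '<anon>'}")
    if len(m) < 8:
        raise ParameterError("mature miRNA must be at least 8 nt for seed scanning")
    core = revcomp_rna(m[1:7])          # pairs positions 2-7
    m8_base = comp_rna(m[7])            # UTR base pairing miRNA position 8

    def pairs_m8(base: str) -> bool:
        if base == m8_base:
            return True
        if allow_wobble:
            return (base, m[7]) in (("G", "U"), ("U", "G"))
        return False

    sites = []
    pos = u.find(core)
    while pos != -1:
        has_m8 = pos > 0 and pairs_m8(u[pos - 1])
        has_a1 = pos + 6 < len(u) and u[pos + 6] == "A"
        if has_m8 and has_a1:
            site_type, start = "8mer", pos - 1
        elif has_m8:
            site_type, start = "7mer-m8", pos - 1
        elif has_a1:
            site_type, start = "7mer-A1", pos
        else:
            site_type, start = "6mer", pos
        sites.append(TargetSite(gene_id=gene_id, mirna=mirna,
                                site_type=site_type, start=start))
        pos = u.find(core, pos + 1)
    return sites


def targets_of_enriched(t: CountTable, enriched_mirnas: list[MiRNARecord],
                        utrs: dict[str, str]) -> dict[str, set[str]]:
    """Map count-filtered genes to the nucleus-enriched miRNAs with at least
    one seed site in their 3'UTR.

    Genes lacking a UTR sequence are skipped with a logged warning; genes with
    no site for any enriched miRNA are absent from the result.
    """
    targets: dict[str, set[str]] = {}
    skipped = 0
    for gene in t.gene_ids:
        utr = utrs.get(gene)
        if utr is None:
            skipped += 1
            log.warning("gene %s has no UTR sequence; skipped", gene)
            continue
        hits = {r.name for r in enriched_mirnas
                if seed_sites(utr, r.mature_seq, gene_id=gene, mirna=r.name)}
        if hits:
            targets[gene] = hits
    if skipped:
        log.warning("%d gene(s) skipped for missing UTR sequence", skipped)
    return targets


def partition_targets(ago1: set, ago2: set) -> RipPartition:
    """Split two pull-downs' target sets into unique and shared transcripts."""
    a1, a2 = set(ago1), set(ago2)
    part = RipPartition(
        unique_ago1=frozenset(a1 - a2),
        unique_ago2=frozenset(a2 - a1),
        shared=frozenset(a1 & a2),
    )
    log.info("partition sizes: unique_ago1=%d unique_ago2=%d shared=%d",
             len(part.unique_ago1), len(part.unique_ago2), len(part.shared))
    return part
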