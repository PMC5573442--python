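"""Synthetic-data generators with the statistical structure the analysis assumes.

Every generator returns its dataset together with a :class:`SimTruth` record
of what was planted, and is fully determined by its seed.  The defaults
emulate the modeled study's conditions: 847 miRNA probes measured in
triplicate nuclear/cytoplasmic fractions with a planted minority of 13
nucleus-enriched probes; mature miRNA sets of 13 enriched (12 carrying the
4-mer motif) versus 30 background non-carriers; hairpin precursors up to
80 nt carrying GA-box elements; Ago1/Ago2 RIP count tables with planted
target sets; and exon tables with planted compartment-differential splicing.

Where a feature's chance occurrence cannot be excluded (motif copies created
by insertion, seed sites arising at random), the truth fields are recomputed
by scanning the generated sequences, so they are honest rather than nominal.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import SampleMeta
from .containers import (CountTable, ExonSignalTable, ExpressionMatrix,
                         MiRNARecord, SimTruth)
from .errors import ParameterError
from .motif import maz_scan
from .rip import seed_sites
from .seq import require_strict_rna, revcomp_rna

RNA = "ACGU"
_MAX_REJECTION = 10_000

# Log-normal total-abundance model of raw array units: meanlog 7, sdlog 1.5
# (natural-log scale) puts a realistic fraction of probes under the
# detection floor of 30 so the low-signal filter is exercised.
_ABUNDANCE_MEANLOG = 7.0
_ABUNDANCE_SDLOG = 1.5
# Planted nucleus-enriched probes are resampled above this total abundance:
# they emulate candidates that were, by construction, detected on the array.
_MIN_ENRICHED_ABUNDANCE = 100.0

__all__ = [
    "gen_expression", "gen_mirna_set", "gen_premir",
    "gen_rip_dataset", "gen_exon_table",
    "triplicate_meta",
]


def _noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and the stated CV."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=shape)


def triplicate_meta(reps_per_compartment: int = 3) -> tuple[SampleMeta, ...]:
    """Standard sample sheet: N1..Nr then C1..Cr."""
    meta = [SampleMeta(f"N{r}", "nuclear", r) for r in range(1, reps_per_compartment + 1)]
    meta += [SampleMeta(f"C{r}", "cytoplasmic", r) for r in range(1, reps_per_compartment + 1)]
    return tuple(meta)


def _as_interval(x, name: str) -> tuple[float, float]:
    if np.isscalar(x):
        lo = hi = float(x)
    else:
        lo, hi = float(x[0]), float(x[1])
    if not (0.0 <= lo <= hi <= 1.0):
        raise ParameterError(f"{name} must lie within [0, 1], got ({lo}, {hi})")
    return lo, hi


# --------------------------------------------------------------------------
# compartment-fractionated expression arrays

def gen_expression(n_probes: int = 847, n_enriched: int = 13,
                   reps_per_compartment: int = 3,
                   enriched_nuclear_frac=(0.75, 0.95),
                   background_nuclear_frac=(0.2, 0.6),
                   noise_cv: float = 0.1,
                   seed: int = 0) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate triplicate nuclear/cytoplasmic array signals with a planted
    nucleus-enriched minority.

    Each probe draws a total abundance (log-normal raw units) that is split
    between compartments by a nuclear fraction: uniform on
    ``enriched_nuclear_frac`` for planted probes and on
    ``background_nuclear_frac`` for the rest.  Replicates receive
    multiplicative log-normal noise with CV ``noise_cv``; ``noise_cv=0``
    yields the compartment means exactly.
    """
    if n_enriched > n_probes:
        raise ParameterError("n_enriched must not exceed n_probes")
    if noise_cv < 0:
        raise ParameterError("noise_cv must be >= 0")
    e_lo, e_hi = _as_interval(enriched_nuclear_frac, "enriched_nuclear_frac")
    b_lo, b_hi = _as_interval(background_nuclear_frac, "background_nuclear_frac")
    rng = np.random.default_rng(seed)

    width = len(str(n_probes))
    probe_ids = [f"probe_{i + 1:0{width}d}" for i in range(n_probes)]
    total = rng.lognormal(_ABUNDANCE_MEANLOG, _ABUNDANCE_SDLOG, size=n_probes)
    enriched_idx = rng.choice(n_probes, size=n_enriched, replace=False)
    for i in enriched_idx:  # planted candidates are detectable by design
        while total[i] < _MIN_ENRICHED_ABUNDANCE:
            total[i] = rng.lognormal(_ABUNDANCE_MEANLOG, _ABUNDANCE_SDLOG)

    frac = rng.uniform(b_lo, b_hi, size=n_probes)
    frac[enriched_idx] = rng.uniform(e_lo, e_hi, size=n_enriched)

    mean_nuc = total * frac
    mean_cyt = total * (1.0 - frac)
    r = reps_per_compartment
    sig_nuc = mean_nuc[:, None] * _noise(rng, noise_cv, (n_probes, r))
    sig_cyt = mean_cyt[:, None] * _noise(rng, noise_cv, (n_probes, r))
    meta = triplicate_meta(r)
    signals = pd.DataFrame(
        np.hstack([sig_nuc, sig_cyt]),
        index=pd.Index(probe_ids, name="probe_id"),
        columns=[m.sample_id for m in meta],
    )
    truth = SimTruth(
        rng_seed=seed,
        enriched_probe_ids=frozenset(probe_ids[i] for i in enriched_idx),
    )
    return ExpressionMatrix(signals, meta), truth


# --------------------------------------------------------------------------
# mature miRNA sets with a planted motif

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RNA), size=length))


def _seq_with_motif(rng, length: int, motif: str) -> str:
    s = list(_random_seq(rng, length))
    pos = int(rng.integers(0, length - len(motif) + 1))
    s[pos:pos + len(motif)] = motif
    return "".join(s)


def _seq_without_motif(rng, length: int, motif: str) -> str:
    for _ in range(_MAX_REJECTION):
        s = _random_seq(rng, length)
        if motif not in s:
            return s
    raise ParameterError(
        f"could not sample a {length}-nt sequence lacking {motif!r} in "
        f"{_MAX_REJECTION} attempts"
    )


def gen_mirna_set(n_enriched: int = 13, n_background: int = 30,
                  motif: str = "GAGG",
                  prevalence_enriched: float = 12 / 13,
                  prevalence_background: float = 0.0,
                  length_range: tuple[int, int] = (18, 24),
                  seed: int = 0) -> tuple[list[MiRNARecord], SimTruth]:
    """Simulate mature miRNA sequence sets with a planted motif prevalence.

    Defaults emulate the modeled 13-versus-30 design: 12 of 13
    nucleus-enriched sequences carry the motif, none of the 30
    least-nuclear background sequences do.  (Genome-wide, a 4-mer of this
    kind is carried by roughly 25% of human miRNAs; pass
    ``prevalence_background=0.25`` to emulate that comparison instead.)

    The designated fraction of each group gets the motif inserted at a random
    position; designated non-carriers are rejection-sampled to be motif-free.
    Carrier truth is recomputed by scanning, so any chance second copy is
    counted honestly.
    """
    motif = require_strict_rna(motif, context="motif")
    for name, p in (("prevalence_enriched", prevalence_enriched),
                    ("prevalence_background", prevalence_background)):
        if not 0 <= p <= 1:
            raise ParameterError(f"{name} must lie in [0, 1]")
    lo, hi = length_range
    if len(motif) > lo:
        raise ParameterError("motif longer than the minimum sequence length")
    rng = np.random.default_rng(seed)

    def make_group(prefix: str, n: int, prevalence: float) -> list[MiRNARecord]:
        n_carriers = int(round(prevalence * n))
        carrier = np.zeros(n, dtype=bool)
        carrier[rng.choice(n, size=n_carriers, replace=False)] = True
        records = []
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            seq = (_seq_with_motif(rng, length, motif) if carrier[i]
                   else _seq_without_motif(rng, length, motif))
            records.append(MiRNARecord(name=f"{prefix}-{i + 1:02d}", mature_seq=seq))
        return records

    enriched = make_group("nuc-mir", n_enriched, prevalence_enriched)
    background = make_group("cyt-mir", n_background, prevalence_background)
    truth = SimTruth(
        rng_seed=seed,
        planted_motif=motif,
        motif_carriers_enriched=frozenset(
            r.name for r in enriched if motif in r.mature_seq),
        motif_carriers_background=frozenset(
            r.name for r in background if motif in r.mature_seq),
    )
    return enriched + background, truth


# --------------------------------------------------------------------------
# precursor hairpins with GA-box elements

def gen_premir(arm_len: int = 25, loop_len: int = 8,
               element_n: int | None = None, name: str = "sim-pre-mir",
               seed: int = 0) -> MiRNARecord:
    """Simulate a hairpin-like precursor: a random 5' arm, a loop, and the
    3' reverse complement of the arm, at most 80 nt total (the length of the
    modeled binding-assay oligos).

    With ``element_n=n`` a GA-box G^n A G^n is planted at a random position
    in the 5' arm; with ``element_n=None`` the hairpin is rejection-sampled
    to contain no GA-box of arm length >= 2 anywhere.
    """
    total_len = 2 * arm_len + loop_len
    if total_len > 80:
        raise ParameterError(f"hairpin length {total_len} exceeds the 80-nt limit")
    if arm_len < 1 or loop_len < 1:
        raise ParameterError("arm_len and loop_len must be positive")
    rng = np.random.default_rng(seed)

    if element_n is not None:
        element = "G" * element_n + "A" + "G" * element_n
        if len(element) > arm_len:
            raise ParameterError(
                f"element G^{element_n}AG^{element_n} ({len(element)} nt) "
                f"does not fit in a {arm_len}-nt arm")
        arm5 = _seq_with_motif(rng, arm_len, element)
        seq = arm5 + _random_seq(rng, loop_len) + revcomp_rna(arm5)
    else:
        for _ in range(_MAX_REJECTION):
            arm5 = _random_seq(rng, arm_len)
            seq = arm5 + _random_seq(rng, loop_len) + revcomp_rna(arm5)
            if not maz_scan(seq, n_min=2, n_max=arm_len):
                break
        else:
            raise ParameterError("could not sample a GA-box-free hairpin")
    mature = arm5[:min(21, arm_len)]
    return MiRNARecord(name=name, mature_seq=mature, premir_seq=seq)


# --------------------------------------------------------------------------
# RIP-seq count tables with planted targets

def _nb_counts(rng, mean: float, dispersion: float, size) -> np.ndarray:
    """Negative-binomial draws parameterized by mean and dispersion
    (var = mean + dispersion * mean^2)."""
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def gen_rip_dataset(n_genes: int = 400, n_ago1: int = 19, n_ago2: int = 44,
                    n_shared: int = 66, utr_len: int = 200,
                    mirnas: list[MiRNARecord] | None = None,
                    n_samples: int = 2, count_floor: int = 10,
                    target_mean: float = 50.0, background_mean: float = 2.0,
                    dispersion: float = 0.3,
                    seed: int = 0) -> tuple[CountTable, CountTable,
                                            dict[str, str], SimTruth]:
    """Simulate Ago1/Ago2 RIP count tables and synthetic 3'UTRs.

    Planted target genes (disjoint unique-Ago1, unique-Ago2 and shared sets,
    structure scaled down from the modeled 189/435/657 partition) receive
    negative-binomial counts at or above the count floor in the matching
    pull-down(s) and carry a planted 8mer seed site for one of the supplied
    nucleus-enriched miRNAs; all other genes stay below the floor in both
    pull-downs.  The gene-to-miRNA truth map is recomputed by scanning the
    generated UTRs, so chance seed sites are included.
    """
    if n_ago1 + n_ago2 + n_shared > n_genes:
        raise ParameterError("planted sets exceed the number of genes")
    if mirnas is None:
        mirnas, _ = gen_mirna_set(seed=seed)
        mirnas = mirnas[:13]
    if not mirnas:
        raise ParameterError("at least one nucleus-enriched miRNA is required")
    rng = np.random.default_rng(seed)

    width = len(str(n_genes))
    genes = [f"gene_{i + 1:0{width}d}" for i in range(n_genes)]
    order = rng.permutation(n_genes)
    set1 = [genes[i] for i in order[:n_ago1]]
    set2 = [genes[i] for i in order[n_ago1:n_ago1 + n_ago2]]
    shared = [genes[i] for i in order[n_ago1 + n_ago2:n_ago1 + n_ago2 + n_shared]]
    planted = set(set1) | set(set2) | set(shared)

    def draw_row(high: bool) -> np.ndarray:
        mean = target_mean if high else background_mean
        for _ in range(_MAX_REJECTION):
            row = _nb_counts(rng, mean, dispersion, n_samples)
            if high and row.sum() >= count_floor:
                return row
            if not high and row.sum() < count_floor:
                return row
        raise ParameterError("could not sample counts on the requested side "
                             "of the floor")

    c1 = np.zeros((n_genes, n_samples), dtype=int)
    c2 = np.zeros((n_genes, n_samples), dtype=int)
    for i, g in enumerate(genes):
        c1[i] = draw_row(high=g in set1 or g in shared)
        c2[i] = draw_row(high=g in set2 or g in shared)

    utrs: dict[str, str] = {}
    for g in genes:
        utr = _random_seq(rng, utr_len)
        if g in planted:
            m = mirnas[int(rng.integers(0, len(mirnas)))]
            site = revcomp_rna(m.mature_seq[1:8]) + "A"  # 8mer site
            pos = int(rng.integers(0, utr_len - len(site) + 1))
            utr = utr[:pos] + site + utr[pos + len(site):]
        utrs[g] = utr

    sample_ids = [f"S{j + 1}" for j in range(n_samples)]
    t1 = CountTable(pd.DataFrame(c1, index=pd.Index(genes, name="gene_id"),
                                 columns=sample_ids), "Ago1")
    t2 = CountTable(pd.DataFrame(c2, index=pd.Index(genes, name="gene_id"),
                                 columns=sample_ids), "Ago2")

    # honest truth: rescan planted genes' UTRs against every supplied miRNA
    target_map = {}
    for g in sorted(planted):
        hits = {m.name for m in mirnas if seed_sites(utrs[g], m.mature_seq)}
        if hits:
            target_map[g] = hits
    truth = SimTruth(
        rng_seed=seed,
        planted_target_genes_ago1=frozenset(set1) | frozenset(shared),
        planted_target_genes_ago2=frozenset(set2) | frozenset(shared),
        planted_target_map=target_map,
    )
    return t1, t2, utrs, truth


# --------------------------------------------------------------------------
# exon tables with planted differential splicing

def _planting_factor(w: float, magnitude: float) -> float:
    """Arm of the symmetric split (x u nuclear, x 1/u cytoplasmic) that makes
    the measured gene-normalized exon ratio equal ``magnitude`` exactly when
    gene signal is the mean of exon signals; w = e_j / (S - e_j)."""
    disc = w * w * (magnitude - 1.0) ** 2 + 4.0 * magnitude
    return (w * (magnitude - 1.0) + math.sqrt(disc)) / 2.0


def gen_exon_table(n_transcripts: int = 100, exons_per_transcript: int = 8,
                   n_spliced: int = 10, si_magnitude: float = 4.0,
                   reps: int = 3, noise_cv: float = 0.1,
                   seed: int = 0) -> tuple[ExonSignalTable, SimTruth]:
    """Simulate exon-level signal with planted compartment-differential
    exon usage.

    Each transcript draws a gene abundance and mildly varying exon baselines.
    For a planted (transcript, exon) pair the exon's nuclear mean is scaled
    by u and its cytoplasmic mean by 1/u, with u solved so the noiseless
    gene-normalized compartment ratio equals ``si_magnitude`` exactly;
    sibling exons absorb a small common counter-shift well below the flagging
    cutoff.  At most one exon per transcript is planted.
    """
    if n_spliced > n_transcripts:
        raise ParameterError("n_spliced must not exceed n_transcripts")
    if si_magnitude <= 0:
        raise ParameterError("si_magnitude must be > 0")
    if noise_cv < 0:
        raise ParameterError("noise_cv must be >= 0")
    E = exons_per_transcript
    if E < 2:
        raise ParameterError("need at least 2 exons per transcript")
    rng = np.random.default_rng(seed)

    tx_ids = [f"tx_{i + 1:04d}" for i in range(n_transcripts)]
    exon_ids = [f"e{j + 1}" for j in range(E)]
    gene_abund = rng.lognormal(7.0, 1.0, size=n_transcripts)
    base = gene_abund[:, None] * rng.lognormal(0.0, 0.3, size=(n_transcripts, E))

    planted_tx = rng.choice(n_transcripts, size=n_spliced, replace=False)
    planted_exon = rng.integers(0, E, size=n_spliced)
    planted = frozenset((tx_ids[t], exon_ids[e])
                        for t, e in zip(planted_tx, planted_exon))

    mean_nuc = base.copy()
    mean_cyt = base.copy()
    for t, e in zip(planted_tx, planted_exon):
        S = base[t].sum()
        w = base[t, e] / (S - base[t, e])
        u = _planting_factor(w, si_magnitude)
        mean_nuc[t, e] *= u
        mean_cyt[t, e] /= u

    meta = triplicate_meta(reps)
    nuc = (mean_nuc[:, :, None] * _noise(rng, noise_cv, (n_transcripts, E, reps)))
    cyt = (mean_cyt[:, :, None] * _noise(rng, noise_cv, (n_transcripts, E, reps)))
    values = np.concatenate([nuc.reshape(-1, reps), cyt.reshape(-1, reps)], axis=1)
    index = pd.MultiIndex.from_product([tx_ids, exon_ids],
                                       names=["transcript_id", "exon_id"])
    signals = pd.DataFrame(values, index=index,
                           columns=[m.sample_id for m in meta])
    truth = SimTruth(rng_seed=seed, planted_spliced=planted)
    return ExonSignalTable(signals, meta), truth
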