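"""Compartment-differential splicing screen.

Exon-level array signal is compared between nuclear and cytoplasmic
fractions after normalizing each exon by its transcript's gene-level signal
(the mean of that transcript's exon signals in the same sample group).  The
splicing index of an exon is

    si = log2( (exon/gene)_nuclear / (exon/gene)_cytoplasmic )

on replicate-averaged values.  Significance comes from a per-transcript
two-way fixed-effects ANOVA on log2 signals (factors: exon, compartment),
where each exon's p-value is the F-test of its single-exon-vs-rest
interaction contrast on the cell means, with the pooled within-cell residual.
An exon is flagged when its BH q-value clears the FDR level and its linear
gene-normalized fold change exceeds the splicing-index cutoff in either
direction; a transcript is flagged when any of its exons is.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExonSignalTable
from .errors import ParameterError
from ._multitest import bh_adjust

log = logging.getLogger(__name__)

__all__ = [
    "splicing_index", "exon_interaction_test", "bh_fdr",
    "analyze_splicing", "flag_spliced", "pair_with_mirna",
]


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-stable; q >= p elementwise)."""
    return bh_adjust(pvals)


def splicing_index(t: ExonSignalTable) -> pd.Series:
    """Per-exon log2 compartment ratio of gene-normalized exon signal.

    Gene-level signal is the mean of the transcript's exon signals per
    compartment (replicate-averaged).  Zero denominators give NaN (excluded
    from calling); single-exon transcripts are excluded with a warning.
    """
    t.require_both_compartments()
    nuc = t.signals[t.samples_in("nuclear")].mean(axis=1)
    cyt = t.signals[t.samples_in("cytoplasmic")].mean(axis=1)
    gene_nuc = nuc.groupby(level="transcript_id").transform("mean")
    gene_cyt = cyt.groupby(level="transcript_id").transform("mean")
    n_exons = nuc.groupby(level="transcript_id").transform("size")
    single = n_exons == 1
    if single.any():
        log.warning("%d single-exon transcript(s) excluded from splicing index",
                    int(single.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = (nuc / gene_nuc) / (cyt / gene_cyt)
        si = np.log2(ratio)
    si = pd.Series(si, index=t.signals.index, name="si")
    si[(gene_nuc == 0) | (gene_cyt == 0) | (cyt == 0)] = np.nan
    si[single] = np.nan
    return si


def _interaction_pvalues(y: np.ndarray, r_nuc: int, r_cyt: int) -> np.ndarray:
    """Single-exon-vs-rest interaction F-test p-values for one transcript.

    ``y`` has shape (E, r_nuc + r_cyt), log2 signals, nuclear replicates
    first.  The full exon x compartment cell-means model supplies the pooled
    within-cell residual; for exon j the interaction contrast on cell means is
    (m_j,nuc - m_j,cyt) - mean_{i != j}(m_i,nuc - m_i,cyt), with variance
    sigma^2 * (1/r_nuc + 1/r_cyt) * (1 + 1/(E-1)).
    """
    E = y.shape[0]
    yn, yc = y[:, :r_nuc], y[:, r_nuc:]
    mn, mc = yn.mean(axis=1), yc.mean(axis=1)
    ss_within = ((yn - mn[:, None]) ** 2).sum() + ((yc - mc[:, None]) ** 2).sum()
    df_resid = E * (r_nuc - 1) + E * (r_cyt - 1)
    d = mn - mc
    contrast = d - (d.sum() - d) / (E - 1)
    scale = (1.0 / r_nuc + 1.0 / r_cyt) * (1.0 + 1.0 / (E - 1))
    if df_resid <= 0:
        return np.full(E, np.nan)
    mse = ss_within / df_resid
    if mse == 0:
        # noiseless data: zero contrast is a perfect null fit (p = 1),
        # any non-zero contrast is incompatible with zero residual (p -> 0)
        return np.where(contrast == 0, 1.0, 0.0)
    f = contrast ** 2 / (mse * scale)
    return stats.f.sf(f, 1, df_resid)


def exon_interaction_test(t: ExonSignalTable, log_offset: float = 1.0) -> pd.Series:
    """Per-exon interaction p-values from the two-way splicing ANOVA.

    Transcripts with a single exon or without residual degrees of freedom
    (fewer than 2 replicates in both compartments) are skipped with NaN
    p-values and a logged message.
    """
    t.require_both_compartments()
    nuc_cols = t.samples_in("nuclear")
    cyt_cols = t.samples_in("cytoplasmic")
    r_nuc, r_cyt = len(nuc_cols), len(cyt_cols)
    x = np.log2(t.signals[nuc_cols + cyt_cols].to_numpy(dtype=float) + log_offset)
    p = np.full(len(t.signals), np.nan)
    skipped = 0
    frame = pd.DataFrame({"row": np.arange(len(t.signals))}, index=t.signals.index)
    for tid, grp in frame.groupby(level="transcript_id", sort=False):
        rows = grp["row"].to_numpy()
        E = len(rows)
        if E < 2 or (r_nuc < 2 and r_cyt < 2) or E * (r_nuc + r_cyt - 2) <= 0:
            skipped += 1
            continue
        p[rows] = _interaction_pvalues(x[rows], r_nuc, r_cyt)
    if skipped:
        log.warning("%d transcript(s) skipped in splicing ANOVA "
                    "(single exon or no residual df)", skipped)
    return pd.Series(p, index=t.signals.index, name="p")


def analyze_splicing(t: ExonSignalTable, fdr_alpha: float = 0.01,
                     si_threshold: float = 2.0,
                     direction_both: bool = True) -> pd.DataFrame:
    """Full per-exon screen: splicing index, interaction p, BH q, flags.

    Returns a DataFrame with columns transcript_id, exon_id, si, p, q,
    flagged.  ``direction_both=True`` (default) treats the splicing-index
    cutoff as a two-sided linear fold change (max(2^si, 2^-si) > threshold);
    False requires nuclear-inclusion only (2^si > threshold).
    """
    si = splicing_index(t)
    p = exon_interaction_test(t)
    q = pd.Series(bh_fdr(p.to_numpy()), index=p.index, name="q")
    with np.errstate(invalid="ignore"):
        fold = np.maximum(np.exp2(si), np.exp2(-si)) if direction_both else np.exp2(si)
    flagged = (q < fdr_alpha) & (fold > si_threshold)
    flagged &= si.notna()
    out = pd.DataFrame({"si": si, "p": p, "q": q, "flagged": flagged})
    return out.reset_index()


def flag_spliced(results: pd.DataFrame, fdr_alpha: float | None = None,
                 si_threshold: float | None = None) -> set[str]:
    """Transcripts with at least one flagged exon.

    With explicit thresholds the exon flags are recomputed from the si/q
    columns; otherwise the existing ``flagged`` column is used.
    """
    df = results
    if fdr_alpha is not None or si_threshold is not None:
        fdr_alpha = 0.01 if fdr_alpha is None else fdr_alpha
        si_threshold = 2.0 if si_threshold is None else si_threshold
        with np.errstate(invalid="ignore"):
            fold = np.maximum(np.exp2(df["si"]), np.exp2(-df["si"]))
        mask = (df["q"] < fdr_alpha) & (fold > si_threshold) & df["si"].notna()
    else:
        mask = df["flagged"].astype(bool)
    return set(df.loc[mask, "transcript_id"])


def pair_with_mirna(flagged: set[str], target_map: dict[str, set[str]]
                    ) -> list[tuple[str, str]]:
    """Cross flagged transcripts with their targeting miRNAs.

    One (miRNA, transcript) row per pairing, sorted for stable output.
    """
    pairs = [(mirna, tx)
             for tx in sorted(flagged)
             for mirna in sorted(target_map.get(tx, ()))]
    return pairs
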