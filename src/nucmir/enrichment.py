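"""Compartment-enrichment calling by three methods.

Triplicate nuclear and cytoplasmic fractions are profiled on the same array,
and each probe is asked: is this species preferentially nuclear?  Because
global normalization can mask genuine compartment differences, three
complementary analyses are run and candidates compared across them:

* **Method 1 (cross-sample normalization + moderated t)** — quantile
  normalization across samples followed by an empirical-Bayes moderated
  two-group t-test on log2 signals, with BH correction.
* **Method 2 (in-sample signal rank)** — each sample's signals are ranked
  against that sample's median; a probe is enriched when every nuclear sample
  outranks every cytoplasmic sample.  Being a pure rank rule it is invariant
  to any monotone within-sample transform.
* **Method 3 (no normalization)** — raw signals are averaged over replicates,
  low-expression probes dropped, and the nuclear percentage of total signal
  computed; a probe is called enriched when that percentage strictly exceeds
  the threshold (70% by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .config import AnalysisConfig, SampleMeta
from .containers import ExpressionMatrix
from .errors import ConfigError, ParameterError
from ._multitest import bh_adjust

__all__ = [
    "filter_low_signal", "nuclear_percentage", "call_method3",
    "rank_scores", "call_method2",
    "quantile_normalize", "moderated_t",
    "enrichment_table",
]


# --------------------------------------------------------------------------
# Method 3: raw nuclear percentage

def filter_low_signal(m: ExpressionMatrix, floor: float) -> ExpressionMatrix:
    """Drop probes whose raw signal is below ``floor`` in every sample.

    A probe survives if at least one sample reaches the floor; probe order is
    preserved.  An empty result is legal.
    """
    if floor <= 0:
        raise ParameterError("signal floor must be > 0")
    keep = (m.signals >= floor).any(axis=1)
    return ExpressionMatrix(m.signals.loc[keep], m.meta)


def nuclear_percentage(m: ExpressionMatrix) -> pd.Series:
    """Percent of replicate-averaged signal contributed by the nucleus.

    pct = 100 * mean_nuclear / (mean_nuclear + mean_cytoplasmic).  Probes with
    zero signal in both compartments are undefined (NaN) and never called.
    """
    means = m.compartment_means()
    total = means["nuclear"] + means["cytoplasmic"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * means["nuclear"] / total
    pct[total == 0] = np.nan
    pct.name = "nuclear_pct"
    return pct


def call_method3(pcts: pd.Series, threshold: float) -> pd.Series:
    """Strictly-greater-than-threshold call on nuclear percentages."""
    if not 0 <= threshold <= 100:
        raise ParameterError("threshold must lie in [0, 100]")
    calls = pcts > threshold  # NaN compares False: undefined -> not enriched
    calls.name = "method3_call"
    return calls


# --------------------------------------------------------------------------
# Method 2: in-sample signal rank

def rank_scores(m: ExpressionMatrix, distance: str = "rank") -> pd.DataFrame:
    """Per-sample signed distance of each probe from the sample median.

    With ``distance='rank'`` (default) signals are sorted in descending order
    within each sample, ordinal positions 1..N assigned (ties get the average
    position), and the score is median_position - position so that larger
    signal means larger score and the median probe scores 0.  With
    ``distance='signal'`` the raw-signal difference from the sample median is
    used instead.
    """
    if len(m.signals) == 0:
        raise ParameterError("rank_scores needs at least one probe")
    if distance == "rank":
        n = len(m.signals)
        # descending positions: 1 for the largest signal
        pos = m.signals.rank(axis=0, method="average", ascending=False)
        return (n + 1) / 2.0 - pos
    if distance == "signal":
        return m.signals - m.signals.median(axis=0)
    raise ParameterError(f"distance must be 'rank' or 'signal', got {distance!r}")


def call_method2(scores: pd.DataFrame, meta: tuple[SampleMeta, ...],
                 compartment: str = "nuclear") -> pd.Series:
    """Full-separation rank call.

    A probe is enriched in ``compartment`` iff its score in *every* sample of
    that compartment strictly exceeds its score in every sample of the other;
    any overlap or tie breaks the call.
    """
    other = "cytoplasmic" if compartment == "nuclear" else "nuclear"
    own = [m.sample_id for m in meta if m.compartment == compartment]
    rest = [m.sample_id for m in meta if m.compartment == other]
    if not own or not rest:
        raise ConfigError("both compartments are required for rank calling")
    calls = scores[own].min(axis=1) > scores[rest].max(axis=1)
    calls.name = "method2_call"
    return calls


# --------------------------------------------------------------------------
# Method 1: quantile normalization + moderated t

def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean-of-sorted-columns reference
    distribution, preserving within-sample order; tied values receive the
    mean of the reference values they span."""
    if m.signals.shape[1] < 2:
        raise ParameterError("quantile normalization needs at least 2 samples")
    x = m.signals.to_numpy(dtype=float)
    order = np.argsort(x, axis=0, kind="stable")
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    nrow = x.shape[0]
    rows = np.arange(nrow)
    for j in range(x.shape[1]):
        col_sorted_idx = order[:, j]
        assigned = np.empty(nrow)
        assigned[col_sorted_idx] = ref
        # tie groups share the mean of their assigned reference values
        col = x[:, j]
        sv = col[col_sorted_idx]
        bounds = np.flatnonzero(np.r_[True, sv[1:] != sv[:-1], True])
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            if b1 - b0 > 1:
                idx = col_sorted_idx[b0:b1]
                assigned[idx] = assigned[idx].mean()
        out[:, j] = assigned[rows]
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.signals.index, columns=m.signals.columns),
        m.meta,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse chi-square prior (d0, s0^2) to the
    observed per-probe sample variances, on the log scale.

    Under the hierarchical model s^2 ~ s0^2 * F(df, d0); matching the mean and
    variance of log(s^2) gives d0 via trigamma inversion.  Zero sample
    variances are offset to a negligible fraction of the median so the log
    moments stay finite; when the observed log-variance spread does not
    exceed its sampling floor the prior is degenerate (d0 infinite) and the
    prior variance is the plain mean of the sample variances.
    """
    s2 = s2[np.isfinite(s2)]
    if s2.size < 2:
        raise ParameterError("too few per-probe variances to fit a prior")
    s2 = np.maximum(s2, 0.0)
    med = np.median(s2)
    if med == 0:
        med = 1.0
    s2 = np.maximum(s2, 1e-5 * med)
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_2 = s2.mean()
    return float(d0), float(s0_2)


def moderated_t(m: ExpressionMatrix, meta: tuple[SampleMeta, ...] | None = None,
                prior_df: float | None = None, log_offset: float = 1.0) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group t-test on log2 signals.

    Per probe, the pooled two-group sample variance s^2 (df = n1 + n2 - 2) is
    shrunk toward a prior: s2_post = (d0*s0^2 + df*s^2) / (d0 + df), with
    (d0, s0^2) estimated from the spread of the per-probe variances unless
    ``prior_df`` overrides d0 (0 recovers the ordinary t-test).  The moderated
    t uses s2_post with d0 + df degrees of freedom; p-values are two-sided and
    q-values Benjamini-Hochberg.

    Signals are log2(x + log_offset)-transformed; run after
    :func:`quantile_normalize` for the cross-sample-normalized analysis.

    Returns a DataFrame (t, p, q) indexed by probe, with the fitted prior in
    ``.attrs['prior_df']`` and ``.attrs['prior_var']``.
    """
    meta = m.meta if meta is None else tuple(meta)
    nuc = [s.sample_id for s in meta if s.compartment == "nuclear"]
    cyt = [s.sample_id for s in meta if s.compartment == "cytoplasmic"]
    n1, n2 = len(nuc), len(cyt)
    if n1 < 2 or n2 < 2:
        raise ConfigError("moderated t needs >= 2 replicates per compartment")
    x = np.log2(m.signals.to_numpy(dtype=float) + log_offset)
    cols = list(m.signals.columns)
    xi = x[:, [cols.index(s) for s in nuc]]
    yi = x[:, [cols.index(s) for s in cyt]]
    df_resid = n1 + n2 - 2
    mean_diff = xi.mean(axis=1) - yi.mean(axis=1)
    ss = ((xi - xi.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((yi - yi.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if prior_df is None:
        d0, s0_2 = _fit_variance_prior(s2, df_resid)
    else:
        if prior_df < 0:
            raise ParameterError("prior_df must be >= 0")
        d0 = float(prior_df)
        s0_2 = float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else 1.0

    n_probes = len(s2)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = float(n_probes * df_resid)  # pooled-information cap
    elif d0 == 0:
        s2_post = s2
        df_total = float(df_resid)
    else:
        # total df cannot exceed the aggregate residual information
        df_total = min(d0 + df_resid, float(n_probes * df_resid))
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean_diff / se
    t[(mean_diff == 0)] = 0.0  # identical group means: t = 0, p = 1
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)
    out = pd.DataFrame({"t": t, "p": p, "q": q}, index=m.signals.index)
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_2
    return out


# --------------------------------------------------------------------------
# combined per-probe report

def enrichment_table(m: ExpressionMatrix, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Run all three methods on a raw matrix and assemble the stage report.

    Columns (fixed order): probe_id, mean_nuclear, mean_cytoplasmic,
    nuclear_pct, method2_call, method1_t, method1_p, method1_q, method3_call.
    Probes failing the low-signal floor are excluded.
    """
    config = config or AnalysisConfig()
    m.require_both_compartments()
    filt = filter_low_signal(m, config.signal_floor)
    means = filt.compartment_means()
    pcts = nuclear_percentage(filt)
    m3 = call_method3(pcts, config.nuclear_pct_threshold)
    m2 = call_method2(rank_scores(filt), filt.meta)
    mod = moderated_t(quantile_normalize(filt))
    out = pd.DataFrame({
        "probe_id": filt.signals.index,
        "mean_nuclear": means["nuclear"].to_numpy(),
        "mean_cytoplasmic": means["cytoplasmic"].to_numpy(),
        "nuclear_pct": pcts.to_numpy(),
        "method2_call": m2.to_numpy(),
        "method1_t": mod["t"].to_numpy(),
        "method1_p": mod["p"].to_numpy(),
        "method1_q": mod["q"].to_numpy(),
        "method3_call": m3.to_numpy(),
    })
    return out.reset_index(drop=True)
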