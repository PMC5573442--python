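"""Benjamini-Hochberg adjustment shared by the enrichment and splicing stages.

The step-up computation itself is delegated to statsmodels; this wrapper adds
input validation and NaN passthrough (undefined tests keep an undefined q).
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg q-values, order-stable, NaNs propagated.

    Raises :class:`ParameterError` for p-values outside [0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    flat = p.ravel()
    finite = np.isfinite(flat)
    if np.any((flat[finite] < 0) | (flat[finite] > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    q = np.full_like(flat, np.nan)
    if finite.sum() > 0:
        q[finite] = multipletests(flat[finite], method="fdr_bh")[1]
    return q.reshape(p.shape)
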