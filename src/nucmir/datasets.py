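"""Published reference measurements used by examples and acceptance checks.

These are the printed, desk-scale numbers from the modeled SH-SY5Y
neuroblastoma nuclear-fractionation experiment (triplicate nuclear and
cytoplasmic fractions, 847 mature miRNAs on the array): the nuclear
percentage of total signal for the most nucleus-enriched miRNAs, and the
motif-by-localization counts behind the motif association test.
"""

from __future__ import annotations

import pandas as pd

from .motif import ContingencyTable2x2

# (name, nuclear % of total signal, conserved-beyond-primates annotation)
_NUCLEAR_MIRNAS = [
    ("hsa-miR-768-5p", 94.17, None),
    ("hsa-miR-768-3p", 93.71, None),
    ("hsa-miR-1299", 93.17, False),
    ("hsa-miR-297", 92.72, True),
    ("hsa-miR-663b", 92.17, False),
    ("hsa-miR-647", 89.19, False),
    ("hsa-miR-595", 88.09, False),
    ("hsa-miR-921", 83.82, False),
    ("hsa-miR-593*", 80.62, False),
    ("hsa-miR-1183", 78.28, False),
    ("hsa-miR-664*", 75.44, True),
    ("hsa-miR-1275", 73.87, False),
    ("hsa-miR-574-5p", 71.94, True),
]


def nuclear_mirna_table() -> pd.DataFrame:
    """The measured nucleus-enriched miRNAs: name, nuclear_pct, conserved.

    These are the miRNAs whose nuclear share of total (nuclear + cytoplasmic)
    array signal exceeded 70% in the modeled experiment; `conserved` is None
    where no annotation was available.
    """
    return pd.DataFrame(_NUCLEAR_MIRNAS,
                        columns=["name", "nuclear_pct", "conserved"])


def gagg_contingency() -> ContingencyTable2x2:
    """Observed motif-by-localization counts: of the 13 nucleus-enriched
    mature miRNAs, 12 carry the shared "GAGG" motif (the one discordant,
    conserved member carries a divergent variant); none of the 30 miRNAs
    least abundant in the nucleus carries it."""
    return ContingencyTable2x2(a=12, b=1, c=0, d=30)
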