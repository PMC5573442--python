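"""In-memory containers: expression/count/exon tables and sequence records.

Tabular data lives in pandas DataFrames (features x samples) wrapped with the
sample metadata that the compartment comparisons need; sequences are plain
strings on dataclass records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import SampleMeta, validate_meta
from .errors import ConfigError, ParseError


def _check_sample_table(signals: pd.DataFrame, meta: tuple[SampleMeta, ...], what: str):
    if signals.index.has_duplicates:
        dups = signals.index[signals.index.duplicated()].unique().tolist()
        raise ParseError(f"duplicate {what} id(s): {dups}")
    if not np.issubdtype(np.asarray(signals.values).dtype, np.number):
        raise ParseError(f"{what} table contains non-numeric values")
    if (signals.values < 0).any():
        raise ParseError(f"{what} table contains negative values")
    ids = {m.sample_id for m in meta}
    cols = set(signals.columns)
    if ids != cols:
        raise ConfigError(
            f"sample metadata does not match table columns: "
            f"meta-only={sorted(ids - cols)}, table-only={sorted(cols - ids)}"
        )


@dataclass
class ExpressionMatrix:
    """Probe x sample raw intensities with compartment/replicate metadata."""

    signals: pd.DataFrame
    meta: tuple[SampleMeta, ...]

    def __post_init__(self):
        self.meta = validate_meta(self.meta)
        _check_sample_table(self.signals, self.meta, "probe")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.signals.index)

    def samples_in(self, compartment: str) -> list[str]:
        return [m.sample_id for m in self.meta if m.compartment == compartment]

    def require_both_compartments(self):
        for comp in ("nuclear", "cytoplasmic"):
            if not self.samples_in(comp):
                raise ConfigError(f"no {comp} samples in metadata")

    def compartment_means(self) -> pd.DataFrame:
        """Replicate-averaged signal per probe: columns 'nuclear', 'cytoplasmic'."""
        self.require_both_compartments()
        return pd.DataFrame({
            comp: self.signals[self.samples_in(comp)].mean(axis=1)
            for comp in ("nuclear", "cytoplasmic")
        })

    def subset(self, probe_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.signals.loc[probe_ids], self.meta)


@dataclass
class CountTable:
    """Gene x sample RIP-seq read counts for one pull-down."""

    counts: pd.DataFrame
    pulldown: str  # 'Ago1', 'Ago2' or 'control'

    def __post_init__(self):
        if self.pulldown not in ("Ago1", "Ago2", "control"):
            raise ConfigError(
                f"pulldown must be 'Ago1', 'Ago2' or 'control', got {self.pulldown!r}"
            )
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate gene id(s): {dups}")
        vals = self.counts.values
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ParseError("count table contains non-integer values")
            self.counts = self.counts.astype(int)
        if (self.counts.values < 0).any():
            raise ParseError("count table contains negative counts")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class ExonSignalTable:
    """Exon-level intensities: rows indexed by (transcript_id, exon_id)."""

    signals: pd.DataFrame
    meta: tuple[SampleMeta, ...]

    def __post_init__(self):
        if not isinstance(self.signals.index, pd.MultiIndex) or \
                self.signals.index.nlevels != 2:
            raise ParseError("exon table must be indexed by (transcript_id, exon_id)")
        self.signals.index = self.signals.index.set_names(["transcript_id", "exon_id"])
        self.meta = validate_meta(self.meta)
        _check_sample_table(self.signals, self.meta, "exon")

    def samples_in(self, compartment: str) -> list[str]:
        return [m.sample_id for m in self.meta if m.compartment == compartment]

    def require_both_compartments(self):
        for comp in ("nuclear", "cytoplasmic"):
            if not self.samples_in(comp):
                raise ConfigError(f"no {comp} samples in metadata")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.signals.index.get_level_values(0).unique())


@dataclass
class MiRNARecord:
    """A named miRNA: mature sequence, optional precursor hairpin and
    annotations carried along from the enrichment stage."""

    name: str
    mature_seq: str
    premir_seq: Optional[str] = None
    nuclear_pct: Optional[float] = None
    conserved: Optional[bool] = None


@dataclass
class SimTruth:
    """Ground truth emitted alongside every simulated dataset.

    Motif-carrier and target-map fields are recomputed by scanning after
    generation, so chance occurrences are counted honestly.
    """

    rng_seed: int
    enriched_probe_ids: frozenset = frozenset()
    planted_motif: Optional[str] = None
    motif_carriers_enriched: frozenset = frozenset()
    motif_carriers_background: frozenset = frozenset()
    planted_target_genes_ago1: frozenset = frozenset()
    planted_target_genes_ago2: frozenset = frozenset()
    planted_target_map: dict = field(default_factory=dict)
    planted_spliced: frozenset = frozenset()
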