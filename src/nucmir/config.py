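"""Analysis configuration and per-sample metadata.

The configuration gathers every threshold used along the pipeline in one
validated, flat object: the raw-signal detection floor, the nuclear-percentage
call threshold, the RIP read-count floor, the FDR level and linear splicing
index cutoff of the splicing screen, the motif length, and the GA-box arm
range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Mapping

import yaml

from .errors import ConfigError

COMPARTMENTS = ("nuclear", "cytoplasmic")


@dataclass(frozen=True)
class SampleMeta:
    """One array/library sample: which compartment, which replicate."""

    sample_id: str
    compartment: str
    replicate: int

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ConfigError(
                f"sample {self.sample_id!r}: compartment must be one of "
                f"{COMPARTMENTS}, got {self.compartment!r}"
            )
        if not isinstance(self.replicate, int) or self.replicate < 1:
            raise ConfigError(
                f"sample {self.sample_id!r}: replicate must be a positive "
                f"integer, got {self.replicate!r}"
            )


def validate_meta(meta: tuple[SampleMeta, ...] | list[SampleMeta]) -> tuple[SampleMeta, ...]:
    """Check uniqueness of sample ids and (compartment, replicate) pairs."""
    meta = tuple(meta)
    ids = [m.sample_id for m in meta]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate sample ids in metadata")
    pairs = [(m.compartment, m.replicate) for m in meta]
    if len(set(pairs)) != len(pairs):
        raise ConfigError("duplicate (compartment, replicate) pairs in metadata")
    return meta


@dataclass
class AnalysisConfig:
    """All pipeline thresholds, with the study's defaults.

    signal_floor : raw-signal units; probes below this in *every* sample are
        dropped before enrichment calling (default 30).
    nuclear_pct_threshold : percent of total signal that must come from the
        nucleus for an enrichment call, strict comparison (default 70).
    count_floor : minimum total RIP read count for a gene to be retained
        (default 10; genes with fewer reads are treated as amplification
        noise).
    fdr_alpha : Benjamini-Hochberg FDR level of the splicing screen
        (default 0.01).
    si_threshold : linear fold-change of gene-normalized exon signal an exon
        must exceed, in either direction, to be flagged (default 2).
    motif_k : motif length in nucleotides for de novo k-mer discovery
        (default 4).
    maz_n_min, maz_n_max : arm lengths of the MAZ GA-box consensus G^n A G^n
        scanned for (defaults 2 and 6).
    rng_seed : seed for every stochastic component.
    """

    signal_floor: float = 30.0
    nuclear_pct_threshold: float = 70.0
    count_floor: int = 10
    fdr_alpha: float = 0.01
    si_threshold: float = 2.0
    motif_k: int = 4
    maz_n_min: int = 2
    maz_n_max: int = 6
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("signal_floor", "count_floor", "si_threshold", "motif_k",
                     "maz_n_min", "maz_n_max"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not 0 < self.fdr_alpha < 1:
            raise ConfigError("fdr_alpha must lie strictly between 0 and 1")
        if not 0 <= self.nuclear_pct_threshold <= 100:
            raise ConfigError("nuclear_pct_threshold must lie in [0, 100]")
        if self.maz_n_min > self.maz_n_max:
            raise ConfigError("maz_n_min must not exceed maz_n_max")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ConfigError("config file must be a flat key: value mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        return asdict(self)
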