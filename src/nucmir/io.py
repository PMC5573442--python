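"""File readers and writers: TSV tables with sample-metadata sidecars, FASTA.

Expression, count and exon tables are tab-separated with the feature id(s) in
the leading column(s) and one column per sample; compartment/replicate
annotation travels in a sidecar TSV (columns: sample_id, compartment,
replicate) rather than being encoded in sample names.  All round-trips are
exact.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import SampleMeta
from .containers import CountTable, ExonSignalTable, ExpressionMatrix, MiRNARecord
from .errors import ConfigError, ParseError
from .seq import normalize_seq

__all__ = [
    "read_sample_meta", "write_sample_meta",
    "read_expression_tsv", "write_expression_tsv",
    "read_counts_tsv", "write_counts_tsv",
    "read_exon_tsv", "write_exon_tsv",
    "read_fasta", "write_fasta",
]


# --------------------------------------------------------------------------
# sample metadata sidecar

def read_sample_meta(path) -> tuple[SampleMeta, ...]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "compartment", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"sample metadata {path} lacks column(s): {sorted(missing)}")
    return tuple(
        SampleMeta(str(r.sample_id), str(r.compartment), int(r.replicate))
        for r in df.itertuples()
    )


def write_sample_meta(meta, path) -> None:
    pd.DataFrame(
        [{"sample_id": m.sample_id, "compartment": m.compartment,
          "replicate": m.replicate} for m in meta]
    ).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# numeric sample tables

def _read_signal_frame(path, index_cols: list[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in index_cols})
    for col in index_cols:
        if col not in df.columns:
            raise ParseError(f"{path}: expected a {col!r} column")
    df = df.set_index(index_cols)
    for col in df.columns:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ParseError(f"{path}: non-numeric {what} at row {row!r}, "
                             f"column {col!r}")
        if (parsed < 0).any():
            row = df.index[(parsed < 0).argmax()]
            raise ParseError(f"{path}: negative {what} at row {row!r}, "
                             f"column {col!r}")
        df[col] = parsed
    return df


def read_expression_tsv(path, meta_path=None) -> ExpressionMatrix:
    """Read a probe x sample signal table plus its metadata sidecar.

    With ``meta_path=None`` the sidecar is looked for next to the table as
    ``<stem>.meta.tsv``.  Duplicate probe ids, negative or non-numeric cells,
    and missing compartment annotation are rejected.
    """
    path = Path(path)
    if meta_path is None:
        meta_path = path.parent / (path.stem + ".meta.tsv")
    if not Path(meta_path).exists():
        raise ConfigError(f"no compartment annotation: expected sidecar {meta_path}")
    df = _read_signal_frame(path, ["probe_id"], "signal")
    return ExpressionMatrix(df, read_sample_meta(meta_path))


def write_expression_tsv(m: ExpressionMatrix, path, meta_path=None) -> None:
    path = Path(path)
    if meta_path is None:
        meta_path = path.parent / (path.stem + ".meta.tsv")
    out = m.signals.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")
    write_sample_meta(m.meta, meta_path)


def read_counts_tsv(path, pulldown: str) -> CountTable:
    df = _read_signal_frame(path, ["gene_id"], "count")
    return CountTable(df, pulldown)


def write_counts_tsv(t: CountTable, path) -> None:
    out = t.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_exon_tsv(path, meta_path=None) -> ExonSignalTable:
    path = Path(path)
    if meta_path is None:
        meta_path = path.parent / (path.stem + ".meta.tsv")
    if not Path(meta_path).exists():
        raise ConfigError(f"no compartment annotation: expected sidecar {meta_path}")
    df = _read_signal_frame(path, ["transcript_id", "exon_id"], "signal")
    return ExonSignalTable(df, read_sample_meta(meta_path))


def write_exon_tsv(t: ExonSignalTable, path, meta_path=None) -> None:
    path = Path(path)
    if meta_path is None:
        meta_path = path.parent / (path.stem + ".meta.tsv")
    t.signals.to_csv(path, sep="\t")
    write_sample_meta(t.meta, meta_path)


# --------------------------------------------------------------------------
# FASTA

def read_fasta(path, alphabet: str = "RNA") -> list[MiRNARecord]:
    """Read FASTA into miRNA records, upper-casing and normalizing T/U to the
    requested alphabet; empty records and non-IUPAC characters are rejected."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ParseError(f"{path}: empty record {rec.id!r}")
        records.append(MiRNARecord(
            name=rec.id,
            mature_seq=normalize_seq(seq, alphabet, context=f"record {rec.id!r}"),
        ))
    return records


def write_fasta(records: list[MiRNARecord], path, which: str = "mature") -> None:
    """Write mature ('mature') or precursor ('premir') sequences as FASTA."""
    out = []
    for r in records:
        seq = r.mature_seq if which == "mature" else r.premir_seq
        if seq is None:
            raise ParseError(f"record {r.name!r} has no {which} sequence")
        out.append(SeqRecord(Seq(seq), id=r.name, description=""))
    SeqIO.write(out, str(path), "fasta")


def write_utr_fasta(utrs: dict[str, str], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=g, description="") for g, s in utrs.items()],
        str(path), "fasta",
    )


def read_utr_fasta(path) -> dict[str, str]:
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        out[rec.id] = normalize_seq(str(rec.seq), "RNA", context=f"record {rec.id!r}")
    return out
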