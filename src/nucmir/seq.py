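"""Small nucleotide-sequence helpers (alphabet normalization, complements).

All sequences in this package are handled as plain upper-case Python strings;
RNA is the working alphabet (T is converted to U on input when RNA is
requested, and vice versa).
"""

from __future__ import annotations

from .errors import ParseError

RNA_BASES = frozenset("ACGU")
DNA_BASES = frozenset("ACGT")

# Unambiguous + ambiguity codes accepted on file input.
IUPAC_CHARS = frozenset("ACGTURYSWKMBDHVN")

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def normalize_seq(seq: str, alphabet: str = "RNA", context: str = "") -> str:
    """Upper-case ``seq``, convert T/U to the requested alphabet, and validate.

    Raises :class:`ParseError` on any non-IUPAC character (e.g. gaps).
    """
    if alphabet not in ("RNA", "DNA"):
        raise ValueError(f"alphabet must be 'RNA' or 'DNA', got {alphabet!r}")
    s = seq.upper()
    bad = set(s) - IUPAC_CHARS
    if bad:
        where = f" in {context}" if context else ""
        raise ParseError(f"non-IUPAC character(s) {sorted(bad)}{where}")
    if alphabet == "RNA":
        return s.replace("T", "U")
    return s.replace("U", "T")


def require_strict_rna(seq: str, context: str = "") -> str:
    """Upper-case and require the unambiguous RNA alphabet {A, C, G, U}."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_BASES
    if bad:
        where = f" in {context}" if context else ""
        raise ParseError(f"non-RNA character(s) {sorted(bad)}{where}")
    return s


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def comp_rna(base: str) -> str:
    return base.translate(_RNA_COMPLEMENT)
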