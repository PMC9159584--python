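"""Elementary nucleic-acid utilities shared across the package.

All sequences are handled in the DNA alphabet {A, C, G, T}. RNA input
(``U``) is converted to ``T`` on ingestion, and ``N`` is converted to the
missing-base marker ``-``. Missing bases are only meaningful in flank
contexts; operations that require complete sequence reject them.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Data import CodonTable

ALPHABET = frozenset("ACGT")
MISSING = "-"
STOP = "*"

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid, with '*' for the three stop codons
GENETIC_CODE: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
GENETIC_CODE.update({c: STOP for c in _STANDARD_TABLE.stop_codons})

STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,-}."""


def clean_sequence(seq: str, allow_missing: bool = True) -> str:
    """Normalise raw sequence text to the internal DNA alphabet.

    Uppercases, converts U->T and N->'-', and validates the result.
    """
    s = seq.strip().upper().replace("U", "T").replace("N", MISSING)
    allowed = ALPHABET | ({MISSING} if allow_missing else set())
    bad = set(s) - allowed
    if bad:
        raise AlphabetError(f"invalid characters in sequence: {sorted(bad)}")
    return s


def require_complete(seq: str, what: str = "sequence") -> str:
    if MISSING in seq:
        raise AlphabetError(f"{what} must not contain missing bases ('-')")
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a complete DNA sequence.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    s = clean_sequence(seq, allow_missing=False)
    return s.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon under the standard genetic code.

    Returns the one-letter amino-acid symbol, or ``'*'`` for the three
    stop codons (TAG, TGA, TAA).
    """
    c = clean_sequence(codon, allow_missing=False)
    if len(c) != 3:
        raise ValueError(f"codon must have exactly 3 bases, got {codon!r}")
    return GENETIC_CODE[c]


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate(seq: str) -> str:
    """Translate successive codons; trailing incomplete codon is dropped."""
    s = clean_sequence(seq, allow_missing=False)
    return "".join(GENETIC_CODE[s[i : i + 3]] for i in range(0, len(s) - 2, 3))


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(label, sequence)`` pairs.

    The full description line is retained as the locus label; sequences
    are normalised with :func:`clean_sequence`.
    """
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.description, clean_sequence(str(rec.seq))))
    return records


def iter_codons(seq: str, start: int = 0) -> Iterator[tuple[int, str]]:
    """Yield ``(position, codon)`` for in-frame codons from ``start``."""
    for i in range(start, len(seq) - 2, 3):
        yield i, seq[i : i + 3]
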