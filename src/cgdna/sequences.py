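"""DNA and protein sequence handling.

Sequences are represented as plain validated strings (5'->3' for DNA,
N->C one-letter codes for proteins).  FASTA input goes through
Biopython's :mod:`Bio.SeqIO`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from Bio import SeqIO

DNA_ALPHABET = "ACGT"
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class SequenceError(ValueError):
    """Raised for invalid or empty sequences."""


def validate_dna(seq: str) -> str:
    """Validate a DNA string over {A,C,G,T}; returns the upper-cased sequence.

    Raises :class:`SequenceError` naming the first offending position
    (1-based) if an invalid symbol is found.
    """
    s = str(seq).strip().upper()
    if not s:
        raise SequenceError("empty DNA sequence")
    for pos, ch in enumerate(s, start=1):
        if ch not in DNA_ALPHABET:
            raise SequenceError(
                f"invalid nucleotide {ch!r} at position {pos} (alphabet A/C/G/T)"
            )
    return s


def validate_protein(seq: str) -> str:
    """Validate a one-letter amino-acid string (20 canonical residues)."""
    s = str(seq).strip().upper()
    if not s:
        raise SequenceError("empty protein sequence")
    for pos, ch in enumerate(s, start=1):
        if ch not in AA_ALPHABET:
            raise SequenceError(
                f"unknown residue {ch!r} at position {pos} (one-letter codes only)"
            )
    return s


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement (A<->T, C<->G), 5'->3'."""
    s = validate_dna(seq)
    return "".join(COMPLEMENT[ch] for ch in reversed(s))


@dataclass(frozen=True)
class FastaRecord:
    id: str
    seq: str


def read_fasta(path: str, kind: str = "dna") -> list[FastaRecord]:
    """Read a FASTA file, validating each record as DNA or protein.

    Parameters
    ----------
    path:
        FASTA file path.
    kind:
        ``"dna"`` or ``"protein"``; controls validation.
    """
    validator = validate_dna if kind == "dna" else validate_protein
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        if len(rec.seq) == 0:
            raise SequenceError(f"empty FASTA record {rec.id!r}")
        records.append(FastaRecord(id=rec.id, seq=validator(str(rec.seq))))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def read_sequences(path_or_literal: str, kind: str = "dna") -> list[FastaRecord]:
    """Accept either a FASTA path or a raw sequence literal.

    A literal gets the id ``"seq"``.
    """
    if os.path.exists(path_or_literal):
        return read_fasta(path_or_literal, kind=kind)
    validator = validate_dna if kind == "dna" else validate_protein
    return [FastaRecord(id="seq", seq=validator(path_or_literal))]
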