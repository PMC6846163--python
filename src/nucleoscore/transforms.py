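"""Sequence containers, DNA alphabet reductions and GC content.

The SW transform collapses DNA to Strong (G, C -> S) versus Weak
(A, T -> W) base pairing; the RY transform collapses it to puRines
(A, G -> R) versus pYrimidines (C, T -> Y).  The two binary channels are
orthogonal: jointly they determine the original base, separately each
destroys half the information (SW keeps GC content, RY erases it).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO

__all__ = [
    "DNA",
    "SW",
    "RY",
    "SymbolSequence",
    "to_sw",
    "to_ry",
    "gc_content",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
]

DNA = "ACGT"
SW = "SW"
RY = "RY"

_SW_MAP = str.maketrans("GCAT", "SSWW")
_RY_MAP = str.maketrans("AGCT", "RRYY")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SymbolSequence:
    """A validated sequence over a declared alphabet.

    Input is normalized to uppercase but otherwise stored verbatim:
    ambiguity codes (``N`` etc.) are *kept*, and downstream sliding-window
    scoring treats any window touching an out-of-alphabet symbol as
    missing rather than fabricating a value.  ``origin_offset`` is the
    0-based coordinate of the first symbol in its source record, so
    profiles over sub-regions keep genomic coordinates.
    """

    symbols: str
    alphabet: str = DNA
    name: str = ""
    origin_offset: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", self.symbols.upper())
        if len(self.symbols) == 0:
            raise ValueError("empty sequence")

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return self.symbols

    @classmethod
    def dna(cls, symbols: str, name: str = "", origin_offset: int = 0) -> "SymbolSequence":
        return cls(symbols, DNA, name, origin_offset)

    def valid_mask(self) -> np.ndarray:
        """Boolean array marking positions whose symbol is in the alphabet."""
        arr = np.frombuffer(self.symbols.encode("ascii", "replace"), dtype=np.uint8)
        mask = np.zeros(256, dtype=bool)
        for ch in self.alphabet:
            mask[ord(ch)] = True
        return mask[arr]

    @property
    def is_valid(self) -> bool:
        return bool(self.valid_mask().all())

    def subsequence(self, start: int, end: int) -> "SymbolSequence":
        """0-based half-open slice, preserving source coordinates."""
        if not 0 <= start < end <= len(self):
            raise ValueError(f"invalid sub-range [{start}, {end}) for length {len(self)}")
        return replace(
            self,
            symbols=self.symbols[start:end],
            origin_offset=self.origin_offset + start,
        )


def _require_dna(seq: SymbolSequence) -> None:
    if seq.alphabet != DNA:
        raise ValueError(f"expected a DNA sequence, got alphabet {seq.alphabet!r}")


def to_sw(seq: SymbolSequence) -> SymbolSequence:
    """Strong/Weak reduction: G,C -> S and A,T -> W (length preserved)."""
    _require_dna(seq)
    return SymbolSequence(seq.symbols.translate(_SW_MAP), SW, seq.name, seq.origin_offset)


def to_ry(seq: SymbolSequence) -> SymbolSequence:
    """Purine/pyrimidine reduction: A,G -> R and C,T -> Y (length preserved)."""
    _require_dna(seq)
    return SymbolSequence(seq.symbols.translate(_RY_MAP), RY, seq.name, seq.origin_offset)


def gc_content(seq: SymbolSequence) -> float:
    """Fraction (#G + #C) / length; requires a fully valid DNA sequence."""
    _require_dna(seq)
    if not seq.is_valid:
        raise ValueError("sequence contains non-ACGT symbols; mask or trim first")
    s = seq.symbols
    return (s.count("G") + s.count("C")) / len(s)


def reverse_complement(seq: SymbolSequence) -> SymbolSequence:
    _require_dna(seq)
    return replace(seq, symbols=seq.symbols.translate(_COMPLEMENT)[::-1])


def read_fasta(path: str | Path, alphabet: str = DNA) -> Iterator[SymbolSequence]:
    """Iterate records of a (multi-record, line-wrapped) FASTA file."""
    for record in SeqIO.parse(str(path), "fasta"):
        yield SymbolSequence(str(record.seq), alphabet, record.id, 0)


def write_fasta(seqs: list[SymbolSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.name or 'seq'}\n")
            for i in range(0, len(seq), width):
                fh.write(seq.symbols[i : i + width] + "\n")
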