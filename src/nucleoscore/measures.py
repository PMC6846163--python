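"""Scalar complexity measures for symbol sequences.

Six measures, all deterministic functions of (sequence, table, parameters):

``entropy``
    Plug-in Shannon entropy of overlapping k-blocks (bits per block).
``entropy_rate``
    Conditional entropy H(2-blocks) - H(1-blocks), bits per symbol.
``lzw``
    Number of codes emitted by Lempel-Ziv-Welch compression with the
    dictionary initialized to the sequence's declared alphabet.
``ctm``
    Coding Theorem Method lookup: the algorithmic-probability complexity
    estimate of a short string (<= the table's maximum key length).
``bdm``
    Block Decomposition Method: partition into fixed-length blocks and sum
    ``ctm(block) + log2(multiplicity)`` over distinct blocks.  Approximates
    entropy for long sequences but algorithmic complexity at block scale,
    which is what lets it see structure with no statistical signature.
``ld``
    Logical-depth estimate: sum over blocks (with multiplicity) of the
    minimal observed runtime of machines producing the block.  Shallow for
    both trivial and random sequences, large for "organized" ones.
``gc``
    GC content, as the classical baseline.

Blocks absent from a reduced CTM table score the table's maximum value
plus one bit (``bdm``) or the table's median runtime (``ld``); both events
are logged so reduced-table gaps are visible rather than silent.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

from .tm_engine import CTMTable
from .transforms import DNA, RY, SW, SymbolSequence, gc_content

logger = logging.getLogger(__name__)

__all__ = [
    "MeasureSpec",
    "MEASURE_NAMES",
    "shannon_entropy",
    "entropy_rate",
    "lzw_length",
    "ctm_score",
    "bdm_score",
    "ld_score",
    "compute",
    "map_to_table_alphabet",
    "supported_block_len",
]

MEASURE_NAMES = ("entropy", "entropy_rate", "lzw", "ctm", "bdm", "ld", "gc")

#: Measures whose *low* values indicate structure/regularity (used by the
#: centre-calling conventions downstream; logical depth is the exception,
#: peaking on organized rather than random sequences).
LOWER_IS_STRUCTURED = {"entropy", "entropy_rate", "lzw", "ctm", "bdm"}


@dataclass(frozen=True)
class MeasureSpec:
    """A named measure plus the parameters that pin down its value.

    ``k`` is the block size for ``entropy``; ``block_len`` the decomposition
    length for ``bdm``/``ld``; ``table`` the CTM table for ``ctm``/``bdm``/
    ``ld``.  Every profile records the spec it was computed with.
    """

    name: str
    k: int = 1
    block_len: int = 12
    table: CTMTable | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.name not in MEASURE_NAMES:
            raise ValueError(f"unknown measure {self.name!r}; choose from {MEASURE_NAMES}")
        if self.name in ("ctm", "bdm", "ld") and self.table is None:
            raise ValueError(f"measure {self.name!r} requires a CTM table")

    def label(self) -> str:
        if self.name == "entropy" and self.k != 1:
            return f"entropy(k={self.k})"
        if self.name in ("bdm", "ld") and self.block_len != 12:
            return f"{self.name}(b={self.block_len})"
        return self.name


def shannon_entropy(seq: SymbolSequence | str, k: int = 1) -> float:
    """Plug-in entropy of overlapping k-blocks, in bits per block.

    Empirical block frequencies with uniform positional weighting and no
    smoothing; bounded by ``k * log2(alphabet size)``.
    """
    s = seq if isinstance(seq, str) else seq.symbols
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(s) < k:
        raise ValueError(f"sequence of length {len(s)} has no {k}-blocks")
    counts = Counter(s[i : i + k] for i in range(len(s) - k + 1))
    n = len(s) - k + 1
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def entropy_rate(seq: SymbolSequence | str) -> float:
    """Conditional entropy H(X_{i+1} | X_i) = H2 - H1, bits per symbol."""
    s = seq if isinstance(seq, str) else seq.symbols
    if len(s) < 2:
        raise ValueError("entropy rate needs length >= 2")
    return max(0.0, shannon_entropy(s, 2) - shannon_entropy(s, 1))


def lzw_length(seq: SymbolSequence | str, alphabet: str | None = None) -> int:
    """Number of codes emitted by LZW with an alphabet-initialized dictionary.

    Implemented in-repo so code counts are platform-exact; monotone
    non-decreasing in prefix length.
    """
    if isinstance(seq, SymbolSequence):
        s, alpha = seq.symbols, seq.alphabet
    else:
        s = seq
        alpha = alphabet if alphabet is not None else "".join(sorted(set(s)))
    if len(s) == 0:
        raise ValueError("empty sequence")
    dictionary = {ch for ch in alpha} | set(s)
    n_codes = 0
    w = s[0]
    for ch in s[1:]:
        if w + ch in dictionary:
            w += ch
        else:
            n_codes += 1
            dictionary.add(w + ch)
            w = ch
    return n_codes + 1


def map_to_table_alphabet(seq: SymbolSequence | str, table: CTMTable) -> str:
    """Render a sequence in the digit alphabet of a CTM table.

    DNA against a 5-symbol table uses the default embedding A,C,G,T ->
    1,2,3,4 with the blank (0) unused — the blank is the Turing machines'
    background symbol, not a nucleotide.  DNA against a 4-symbol table maps
    A,C,G,T -> 0,1,2,3 (the alternative reading where the blank doubles as
    a base).  Binary SW/RY reductions map S,R -> 0 and W,Y -> 1.
    """
    if isinstance(seq, str):
        return seq
    if seq.alphabet == DNA:
        if table.alphabet_size == 5:
            return seq.symbols.translate(str.maketrans("ACGT", "1234"))
        if table.alphabet_size == 4:
            return seq.symbols.translate(str.maketrans("ACGT", "0123"))
        raise ValueError(
            f"DNA needs a 4- or 5-symbol table, got alphabet_size={table.alphabet_size}"
        )
    if seq.alphabet in (SW, RY):
        if table.alphabet_size < 2:
            raise ValueError("binary reductions need a table with >= 2 symbols")
        return seq.symbols.translate(str.maketrans(seq.alphabet, "01"))
    return seq.symbols  # already a digit alphabet


def ctm_score(seq: SymbolSequence | str, table: CTMTable) -> float:
    """CTM table lookup for a short sequence (length <= table.max_len)."""
    key = map_to_table_alphabet(seq, table)
    if len(key) > table.max_len:
        raise ValueError(
            f"sequence of length {len(key)} exceeds table max_len={table.max_len}; "
            "use bdm_score for longer sequences"
        )
    bits, _, found = table.lookup(key)
    if not found:
        logger.debug("CTM miss for %r; fallback %.3f bits", key, bits)
    return bits


def block_scores(
    seq: SymbolSequence | str, table: CTMTable, block_len: int = 12
) -> list[tuple[str, int, float, int | None, bool]]:
    """Per-distinct-block detail behind bdm/ld.

    Returns ``(block, multiplicity, ctm_bits, min_runtime, found)`` tuples
    for the non-overlapping decomposition starting at offset 0, trailing
    remainder kept as a shorter block.
    """
    digits = map_to_table_alphabet(seq, table)
    if len(digits) == 0:
        raise ValueError("empty sequence")
    if block_len < 1 or block_len > table.max_len:
        raise ValueError(f"block_len must be in [1, {table.max_len}]")
    multiplicities = Counter(
        digits[i : i + block_len] for i in range(0, len(digits), block_len)
    )
    out = []
    for block, mult in multiplicities.items():
        bits, runtime, found = table.lookup(block)
        out.append((block, mult, bits, runtime, found))
    return out


def bdm_score(
    seq: SymbolSequence | str, table: CTMTable, block_len: int = 12
) -> float:
    """Block Decomposition Method: sum of ctm(block) + log2(multiplicity)."""
    total = 0.0
    n_miss = 0
    for _, mult, bits, _, found in block_scores(seq, table, block_len):
        total += bits + math.log2(mult)
        n_miss += not found
    if n_miss:
        logger.debug("bdm: %d block(s) missing from table, fallback applied", n_miss)
    return total


def ld_score(
    seq: SymbolSequence | str, table: CTMTable, block_len: int = 12
) -> float:
    """Logical-depth estimate: multiplicity-weighted sum of block runtimes.

    A block's contribution is the minimal halting runtime among the machines
    that produced it; blocks absent from the table contribute the table's
    median runtime.
    """
    if not table.has_runtimes:
        raise ValueError("table has no runtime data; logical depth unavailable")
    median = table.median_runtime
    total = 0.0
    n_miss = 0
    for _, mult, _, runtime, found in block_scores(seq, table, block_len):
        rt = runtime if (found and runtime is not None) else median
        total += mult * rt
        n_miss += not found
    if n_miss:
        logger.debug("ld: %d block(s) missing from table, median fallback", n_miss)
    return total


def supported_block_len(
    table: CTMTable, min_coverage: float = 0.5, blank_free: bool = True
) -> int:
    """Largest block length the table covers at >= ``min_coverage``.

    Reduced (sampled) tables cannot cover long blocks; analyses that need
    every block scoreable (logical depth in particular) should decompose at
    a length the table actually supports.  Coverage is measured over
    blank-free strings when the table embeds a smaller alphabet.
    """
    best = 1
    for length in range(1, table.max_len + 1):
        if table.coverage(length, blank_free=blank_free) >= min_coverage:
            best = length
    return best


def compute(seq: SymbolSequence, spec: MeasureSpec) -> float:
    """Evaluate a measure spec on a sequence."""
    if spec.name == "entropy":
        return shannon_entropy(seq, spec.k)
    if spec.name == "entropy_rate":
        return entropy_rate(seq)
    if spec.name == "lzw":
        return float(lzw_length(seq))
    if spec.name == "ctm":
        return ctm_score(seq, spec.table)
    if spec.name == "bdm":
        return bdm_score(seq, spec.table, spec.block_len)
    if spec.name == "ld":
        return ld_score(seq, spec.table, spec.block_len)
    if spec.name == "gc":
        return gc_content(seq)
    raise AssertionError(spec.name)
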