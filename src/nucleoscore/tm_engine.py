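"""Small Turing machines, output-frequency distributions and CTM tables.

This module realizes the Coding Theorem Method (CTM): enumerate or sample
the space of small Turing machines in the busy-beaver formalism, run each
from a blank tape, collect the empirical distribution of halting outputs,
and convert output frequencies into algorithmic-complexity estimates via

    ctm_bits(s) = -log2( count(s) / total_halting )

The minimal halting runtime observed for each output string is kept
alongside, which is what the logical-depth estimator consumes downstream.

Machine formalism (Rado busy-beaver convention):

* ``n_states`` work states, numbered ``0 .. n_states-1``; start state 0.
* ``n_symbols`` tape symbols, numbered ``0 .. n_symbols-1``; 0 is blank.
* A transition ``(state, read) -> (write, move, next)`` always writes and
  always moves one cell (no stay-put); ``next`` may be the implicit HALT
  pseudo-state.  The halting transition counts as a step, so the classic
  busy-beaver value S(2) = 6 holds in this encoding.
* Two-way infinite tape, initially all blank, head at the origin.

The output of a halting machine is the contiguous tape segment spanning
every cell the head *scanned* (occupied at the start of an executed step),
read left to right at halt.  The cell the head rests on after the final
move is not part of the output; in particular a machine that halts on its
first step outputs a single symbol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "HALT",
    "MachineRule",
    "RunResult",
    "OutputDistribution",
    "CTMTable",
    "rule_space_size",
    "encode_rule",
    "run_machine",
    "run_batch",
    "build_distribution",
    "ctm_table_from_distribution",
    "complete_by_symmetry",
    "read_acss_table",
]

#: Sentinel for the implicit halting pseudo-state.
HALT = -1

#: Default step cutoff for (2, k) rule spaces; safely above S(2) = 6 and
#: recorded in every table's provenance.  Non-halters within the cutoff are
#: excluded from the output distribution.
DEFAULT_CUTOFF = 107

LEFT, RIGHT = 0, 1


def rule_space_size(n_states: int, n_symbols: int) -> int:
    """Number of distinct transition tables in the (n, m) machine space.

    Each of the ``n*m`` table entries picks one of ``2*m*(n+1)`` actions
    (2 moves x m write symbols x (n+1) successor states including HALT),
    so the space holds ``(2*m*(n+1))**(n*m)`` rules.
    """
    if n_states < 1 or n_symbols < 1:
        raise ValueError("n_states and n_symbols must be positive")
    return (2 * n_symbols * (n_states + 1)) ** (n_states * n_symbols)


@dataclass(frozen=True)
class MachineRule:
    """A total transition table for one (n-state, m-symbol) machine.

    ``transitions`` maps entry index ``state * n_symbols + read_symbol`` to
    an ``(write, move, next_state)`` triple; ``move`` is 0 for left, 1 for
    right; ``next_state`` is :data:`HALT` for the halting pseudo-state.
    ``rule_index`` is the mixed-radix encoding of the table and round-trips
    bijectively through :func:`encode_rule`.
    """

    n_states: int
    n_symbols: int
    rule_index: int
    transitions: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if len(self.transitions) != self.n_states * self.n_symbols:
            raise ValueError("transitions must be total over n_states * n_symbols entries")

    def action(self, state: int, read_symbol: int) -> tuple[int, int, int]:
        return self.transitions[state * self.n_symbols + read_symbol]


def _decode_action(digit: int, n_states: int, n_symbols: int) -> tuple[int, int, int]:
    write = digit % n_symbols
    digit //= n_symbols
    move = digit % 2
    nxt = digit // 2
    return (write, move, HALT if nxt == n_states else nxt)


def _encode_action(action: tuple[int, int, int], n_states: int, n_symbols: int) -> int:
    write, move, nxt = action
    nxt_digit = n_states if nxt == HALT else nxt
    return (nxt_digit * 2 + move) * n_symbols + write


def encode_rule(rule_index: int, n_states: int, n_symbols: int) -> MachineRule:
    """Decode ``rule_index`` into its :class:`MachineRule` (bijective).

    The index is read as a little-endian mixed-radix number with one digit
    per table entry, entries ordered by ``(state, read_symbol)``.  Index 0
    is the rule whose every transition is the first action in this order
    (write blank, move left, go to state 0).
    """
    size = rule_space_size(n_states, n_symbols)
    if not 0 <= rule_index < size:
        raise ValueError(
            f"rule_index {rule_index} outside the (n={n_states}, m={n_symbols}) "
            f"rule space of size {size}"
        )
    base = 2 * n_symbols * (n_states + 1)
    digits = []
    rest = rule_index
    for _ in range(n_states * n_symbols):
        digits.append(rest % base)
        rest //= base
    transitions = tuple(_decode_action(d, n_states, n_symbols) for d in digits)
    return MachineRule(n_states, n_symbols, rule_index, transitions)


def rule_to_index(rule: MachineRule) -> int:
    """Inverse of :func:`encode_rule` on the transitions alone."""
    base = 2 * rule.n_symbols * (rule.n_states + 1)
    index = 0
    for digit_pos, action in reversed(list(enumerate(rule.transitions))):
        index = index * base + _encode_action(action, rule.n_states, rule.n_symbols)
        _ = digit_pos
    return index


@dataclass(frozen=True)
class RunResult:
    """Outcome of running one machine from blank tape up to a step cutoff."""

    halted: bool
    output: str | None
    steps: int

    def __post_init__(self) -> None:
        if not self.halted and self.output is not None:
            raise ValueError("non-halting runs carry no output")


def _symbols_to_str(symbols: Iterable[int]) -> str:
    return "".join(str(s) for s in symbols)


def run_machine(rule: MachineRule, cutoff: int) -> RunResult:
    """Simulate ``rule`` from blank tape for at most ``cutoff`` steps."""
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    tape: dict[int, int] = {}
    head = 0
    state = 0
    lo = hi = 0  # extremes of scanned cells
    m = rule.n_symbols
    transitions = rule.transitions
    for step in range(1, cutoff + 1):
        write, move, nxt = transitions[state * m + tape.get(head, 0)]
        tape[head] = write
        if head < lo:
            lo = head
        elif head > hi:
            hi = head
        head += 1 if move == RIGHT else -1
        if nxt == HALT:
            out = _symbols_to_str(tape.get(p, 0) for p in range(lo, hi + 1))
            return RunResult(True, out, step)
        state = nxt
    return RunResult(False, None, cutoff)


# ---------------------------------------------------------------------------
# Vectorized batch simulation
# ---------------------------------------------------------------------------

def _decode_batch(indices: np.ndarray, n_states: int, n_symbols: int):
    """Vectorized mixed-radix decode of rule indices into transition arrays."""
    base = 2 * n_symbols * (n_states + 1)
    n_entries = n_states * n_symbols
    place = base ** np.arange(n_entries, dtype=np.int64)
    digits = (indices[:, None] // place) % base
    write_t = (digits % n_symbols).astype(np.int8)
    move_t = ((digits // n_symbols) % 2).astype(np.int8)
    next_t = (digits // (2 * n_symbols)).astype(np.int8)  # n_states encodes HALT
    return write_t, move_t, next_t


def _simulate_chunk(indices: np.ndarray, n_states: int, n_symbols: int, cutoff: int):
    """Run a chunk of machines in lockstep; returns per-machine outcome arrays.

    Returns ``(halted, steps, lo, hi, tape)`` where ``tape`` has shape
    ``(len(indices), 2*cutoff + 2)`` with the origin at column ``cutoff``,
    and ``lo``/``hi`` bound the scanned cells of each machine.
    """
    n_mach = len(indices)
    write_t, move_t, next_t = _decode_batch(indices, n_states, n_symbols)
    origin = cutoff
    tape = np.zeros((n_mach, 2 * cutoff + 2), dtype=np.int8)
    head = np.full(n_mach, origin, dtype=np.int64)
    state = np.zeros(n_mach, dtype=np.int64)
    lo = np.full(n_mach, origin, dtype=np.int64)
    hi = np.full(n_mach, origin, dtype=np.int64)
    steps = np.full(n_mach, cutoff, dtype=np.int64)
    halted = np.zeros(n_mach, dtype=bool)
    alive = np.arange(n_mach)
    for t in range(1, cutoff + 1):
        h = head[alive]
        read = tape[alive, h].astype(np.int64)
        entry = state[alive] * n_symbols + read
        w = write_t[alive, entry]
        mv = move_t[alive, entry].astype(np.int64)
        nx = next_t[alive, entry].astype(np.int64)
        tape[alive, h] = w
        np.minimum.at(lo, alive, h)
        np.maximum.at(hi, alive, h)
        head[alive] = h + 2 * mv - 1
        halt_now = nx == n_states
        if halt_now.any():
            ids = alive[halt_now]
            steps[ids] = t
            halted[ids] = True
            state[alive] = np.where(halt_now, 0, nx)
            alive = alive[~halt_now]
            if alive.size == 0:
                break
        else:
            state[alive] = nx
    return halted, steps, lo, hi, tape


_DIGIT_TRANSLATE = bytes(ord("0") + (b % 10) if b < 10 else 0 for b in range(256))


def _extract_outputs(halted, steps, lo, hi, tape):
    """Yield ``(output_string, steps)`` for every halted machine in a chunk."""
    for i in np.flatnonzero(halted):
        seg = tape[i, lo[i] : hi[i] + 1]
        yield seg.tobytes().translate(_DIGIT_TRANSLATE).decode("ascii"), int(steps[i])


def run_batch(
    indices: Iterable[int],
    n_states: int,
    n_symbols: int,
    cutoff: int = DEFAULT_CUTOFF,
) -> list[RunResult]:
    """Vectorized equivalent of :func:`run_machine` over many rule indices."""
    idx = np.asarray(list(indices), dtype=np.int64)
    halted, steps, lo, hi, tape = _simulate_chunk(idx, n_states, n_symbols, cutoff)
    results: list[RunResult] = []
    for i in range(len(idx)):
        if halted[i]:
            seg = tape[i, lo[i] : hi[i] + 1]
            out = seg.tobytes().translate(_DIGIT_TRANSLATE).decode("ascii")
            results.append(RunResult(True, out, int(steps[i])))
        else:
            results.append(RunResult(False, None, cutoff))
    return results


# ---------------------------------------------------------------------------
# Output distributions
# ---------------------------------------------------------------------------

@dataclass
class OutputDistribution:
    """Empirical distribution of halting outputs over a machine ensemble.

    ``counts[s]`` is the number of sampled machines that halted with output
    ``s``; ``min_steps[s]`` the smallest runtime among them (the empirical
    proxy for the runtime of the shortest program, used by logical depth).
    """

    counts: dict[str, int]
    min_steps: dict[str, int]
    total_halting: int
    total_run: int
    n_states: int
    n_symbols: int
    cutoff: int
    full_enumeration: bool
    sample_size: int
    seed: int | None

    @property
    def halting_fraction(self) -> float:
        return self.total_halting / self.total_run if self.total_run else 0.0


_CHUNK = 250_000  # machines simulated per lockstep chunk; bounds peak memory


def build_distribution(
    n_states: int,
    n_symbols: int,
    cutoff: int = DEFAULT_CUTOFF,
    sample_size: int | str = "all",
    seed: int = 0,
) -> OutputDistribution:
    """Aggregate halting outputs over an enumerated or sampled rule space.

    ``sample_size="all"`` enumerates the whole space (feasible for (2,2));
    a numeric ``sample_size`` draws that many rules uniformly with a seeded
    generator.  Identical arguments (including the seed) reproduce the
    distribution exactly; full enumeration ignores the seed.
    """
    size = rule_space_size(n_states, n_symbols)
    full = sample_size == "all" or sample_size == size
    if full:
        n_sample = size
        index_stream = (
            np.arange(start, min(start + _CHUNK, size), dtype=np.int64)
            for start in range(0, size, _CHUNK)
        )
    else:
        if not isinstance(sample_size, int) or sample_size < 1:
            raise ValueError('sample_size must be a positive integer or "all"')
        if sample_size > size:
            raise ValueError(
                f"sample of {sample_size} exceeds the rule space ({size} rules); "
                'pass sample_size="all" to enumerate it fully'
            )
        n_sample = sample_size
        rng = np.random.default_rng(seed)
        if size <= max(2 * sample_size, 10_000_000):
            chosen = rng.permutation(size)[:sample_size]  # without replacement
        else:
            # Space vastly larger than the sample: i.i.d. draws, collision
            # probability ~ k^2 / (2 size) is negligible.
            chosen = rng.integers(0, size, size=sample_size, dtype=np.int64)
        index_stream = (
            chosen[start : start + _CHUNK] for start in range(0, n_sample, _CHUNK)
        )

    counts: dict[str, int] = {}
    min_steps: dict[str, int] = {}
    total_halting = 0
    total_run = 0
    for idx in index_stream:
        halted, steps, lo, hi, tape = _simulate_chunk(idx, n_states, n_symbols, cutoff)
        total_run += len(idx)
        total_halting += int(halted.sum())
        for out, nsteps in _extract_outputs(halted, steps, lo, hi, tape):
            counts[out] = counts.get(out, 0) + 1
            prev = min_steps.get(out)
            if prev is None or nsteps < prev:
                min_steps[out] = nsteps
    if total_halting == 0:
        raise ValueError("no machine halted within the cutoff; distribution is empty")
    return OutputDistribution(
        counts=counts,
        min_steps=min_steps,
        total_halting=total_halting,
        total_run=total_run,
        n_states=n_states,
        n_symbols=n_symbols,
        cutoff=cutoff,
        full_enumeration=bool(full),
        sample_size=n_sample,
        seed=None if full else seed,
    )


# ---------------------------------------------------------------------------
# CTM tables
# ---------------------------------------------------------------------------

@dataclass
class CTMTable:
    """Map from short strings to (CTM bits, minimal observed runtime).

    ``entries[s] = (ctm_bits, min_runtime)``; ``min_runtime`` is ``None``
    for imported tables that publish complexity values only, in which case
    logical depth is unavailable.  ``provenance`` records how the table was
    built (machine space, cutoff, sample size, seed, symmetry completion)
    so that reduced desk-scale tables are never mistaken for exhaustive
    ones.
    """

    alphabet_size: int
    entries: dict[str, tuple[float, int | None]]
    max_len: int
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    # entries are immutable after construction; derived statistics are cached
    @property
    def max_ctm(self) -> float:
        cached = self.__dict__.get("_max_ctm")
        if cached is None:
            cached = max(v[0] for v in self.entries.values())
            self.__dict__["_max_ctm"] = cached
        return cached

    @property
    def fallback_bits(self) -> float:
        """Penalty score for strings absent from the table (max + 1 bit)."""
        return self.max_ctm + 1.0

    @property
    def median_runtime(self) -> float:
        cached = self.__dict__.get("_median_runtime")
        if cached is None:
            runtimes = [v[1] for v in self.entries.values() if v[1] is not None]
            if not runtimes:
                raise ValueError("table carries no runtime data (imported table?)")
            cached = float(np.median(runtimes))
            self.__dict__["_median_runtime"] = cached
        return cached

    @property
    def has_runtimes(self) -> bool:
        return any(v[1] is not None for v in self.entries.values())

    def lookup(self, key: str) -> tuple[float, int | None, bool]:
        """Return ``(ctm_bits, min_runtime, found)`` with fallback on miss."""
        hit = self.entries.get(key)
        if hit is not None:
            return hit[0], hit[1], True
        return self.fallback_bits, None, False

    def coverage(self, length: int, blank_free: bool = True) -> float:
        """Fraction of length-``length`` strings present in the table.

        With ``blank_free`` (default) the universe excludes strings that
        contain the blank symbol 0 — the relevant universe when a 4-letter
        DNA alphabet is embedded as symbols 1..4 of a 5-symbol space.
        """
        if blank_free and self.alphabet_size > 1:
            universe = (self.alphabet_size - 1) ** length
            n_present = sum(
                1 for k in self.entries if len(k) == length and "0" not in k
            )
        else:
            universe = self.alphabet_size ** length
            n_present = sum(1 for k in self.entries if len(k) == length)
        return n_present / universe

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the table as a diff-able TSV with provenance headers."""
        p = self.provenance
        lines = [
            f"#alphabet\t{self.alphabet_size}",
            f"#n_states\t{p.get('n_states', '-')}",
            f"#cutoff\t{p.get('cutoff', '-')}",
            f"#sample\t{p.get('sample', '-')}",
            f"#seed\t{p.get('seed', '-')}",
            f"#total_halting\t{p.get('total_halting', '-')}",
            f"#total_run\t{p.get('total_run', '-')}",
            f"#max_len\t{self.max_len}",
            f"#completed\t{int(bool(p.get('completed', False)))}",
        ]
        for key in sorted(self.entries, key=lambda s: (len(s), s)):
            bits, runtime = self.entries[key]
            rt = "-" if runtime is None else str(runtime)
            lines.append(f"{key}\t{bits!r}\t{rt}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "CTMTable":
        provenance: dict = {}
        entries: dict[str, tuple[float, int | None]] = {}
        alphabet_size = max_len = None
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                if key == "alphabet":
                    alphabet_size = int(value)
                elif key == "max_len":
                    max_len = int(value)
                elif value != "-":
                    provenance[key] = (
                        int(value) if value.lstrip("-").isdigit() else value
                    )
                continue
            s, bits, rt = line.split("\t")
            entries[s] = (float(bits), None if rt == "-" else int(rt))
        if alphabet_size is None or max_len is None:
            raise ValueError(f"{path}: missing #alphabet / #max_len headers")
        provenance["completed"] = bool(provenance.get("completed", 0))
        return cls(alphabet_size, entries, max_len, provenance)

    def verify_against(self, dist: OutputDistribution) -> bool:
        """Check bit-exactness of every entry against its distribution.

        Recomputes ``-log2(count / total_halting)`` from ``dist`` (after
        the same key truncation used at build time) and compares for exact
        float equality.  Raises ``AssertionError`` on the first mismatch.
        """
        merged: dict[str, int] = {}
        for s, c in dist.counts.items():
            k = s[: self.max_len]
            merged[k] = merged.get(k, 0) + c
        for key, (bits, _) in self.entries.items():
            expected = -math.log2(merged[key] / dist.total_halting)
            assert bits == expected, (key, bits, expected)
        return True


def ctm_table_from_distribution(
    dist: OutputDistribution, max_len: int = 12
) -> CTMTable:
    """Turn an output distribution into a CTM lookup table.

    Outputs longer than ``max_len`` are truncated to their first
    ``max_len`` symbols and merged, so that long-running machines still
    contribute frequency mass to scoreable blocks.  ``ctm_bits`` is exactly
    ``-log2(count / total_halting)`` of the (merged) count; ``min_runtime``
    is the smallest halting runtime among contributing machines.
    """
    if dist.total_halting <= 0 or not dist.counts:
        raise ValueError("cannot build a CTM table from an empty distribution")
    merged_counts: dict[str, int] = {}
    merged_steps: dict[str, int] = {}
    for s, c in dist.counts.items():
        k = s[:max_len]
        merged_counts[k] = merged_counts.get(k, 0) + c
        st = dist.min_steps[s]
        if k not in merged_steps or st < merged_steps[k]:
            merged_steps[k] = st
    entries = {
        k: (-math.log2(c / dist.total_halting), merged_steps[k])
        for k, c in merged_counts.items()
    }
    provenance = {
        "n_states": dist.n_states,
        "cutoff": dist.cutoff,
        "sample": "all" if dist.full_enumeration else dist.sample_size,
        "seed": "-" if dist.seed is None else dist.seed,
        "total_halting": dist.total_halting,
        "total_run": dist.total_run,
        "completed": False,
    }
    return CTMTable(dist.n_symbols, entries, max_len, provenance)


def complete_by_symmetry(table: CTMTable) -> CTMTable:
    """Close a table under string reversal and global symbol permutation.

    Machine spaces are invariant under mirroring the move directions
    (outputs reverse) and under relabelling the tape symbols, so every
    member of an entry's orbit is assigned the orbit's minimum observed
    ``ctm_bits`` (and minimum runtime).  The operation is idempotent and
    recorded in provenance; it is how reduced sampled tables recover
    coverage the sample missed.
    """
    alphabet = [str(i) for i in range(table.alphabet_size)]
    perm_maps = [
        str.maketrans(dict(zip(alphabet, perm)))
        for perm in permutations(alphabet)
    ]
    new_entries: dict[str, tuple[float, int | None]] = {}
    seen: set[str] = set()
    for key, value in table.entries.items():
        if key in seen:
            continue
        orbit: set[str] = set()
        for pm in perm_maps:
            img = key.translate(pm)
            orbit.add(img)
            orbit.add(img[::-1])
        members = [table.entries[s] for s in orbit if s in table.entries]
        best_bits = min(v[0] for v in members)
        runtimes = [v[1] for v in members if v[1] is not None]
        best_rt = min(runtimes) if runtimes else None
        for s in orbit:
            prev = new_entries.get(s)
            if prev is None or best_bits < prev[0]:
                new_entries[s] = (best_bits, best_rt)
        seen |= orbit & table.entries.keys()
    provenance = dict(table.provenance)
    provenance["completed"] = True
    return CTMTable(table.alphabet_size, new_entries, table.max_len, provenance)


def read_acss_table(
    path: str | Path, alphabet_size: int, max_len: int = 12
) -> CTMTable:
    """Read an externally published table of ``string<TAB>ctm_bits`` pairs.

    Published Coding-Theorem tables (acss-style) ship complexity values
    without runtimes, so logical depth cannot be computed from them; all
    other measures work unchanged.
    """
    entries: dict[str, tuple[float, int | None]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split("\t")
        s, bits = parts[0].strip().strip('"'), float(parts[1])
        entries[s] = (bits, None)
    if not entries:
        raise ValueError(f"{path}: no entries found")
    return CTMTable(
        alphabet_size, entries, max_len, provenance={"source": "imported"}
    )
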