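"""Seeded generators for every synthetic input the analyses and tests need.

Everything here is deterministic given its spec (including the seed), so
the whole pipeline builds and tests without downloading any external data.
The synthetic genome segment emulates the one robust sequence determinant
of nucleosome occupancy that a generator can honestly reproduce: occupancy
driven by windowed GC content, with nucleosome-depleted regions realized as
planted AT-rich low-complexity elements (poly-dA/dT tracts and short
tandem repeats), the way real depleted regions are.  What it does *not*
emulate: MNase digestion bias, k-mer periodicity of rotational positioning,
read-level noise, or chromatin-remodeller effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .profiler import OccupancyTrack
from .transforms import DNA, SymbolSequence

__all__ = [
    "FixtureSpec",
    "make_sequence",
    "make_occupancy",
    "iid_dna",
    "periodic",
    "homopolymer",
    "shuffled",
    "planted_sequence",
    "genome_segment",
    "curvature_panel",
    "windowed_gc",
]

BASES = np.array(list(DNA))


def _gc_probs(gc: float) -> list[float]:
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    return [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T


def iid_dna(length: int, gc: float = 0.5, seed: int = 0, name: str = "iid") -> SymbolSequence:
    """i.i.d. DNA with P(G) = P(C) = gc/2 and P(A) = P(T) = (1 - gc)/2."""
    rng = np.random.default_rng(seed)
    sym = "".join(rng.choice(BASES, size=length, p=_gc_probs(gc)))
    return SymbolSequence(sym, DNA, name)


def periodic(motif: str, n_copies: int, name: str = "") -> SymbolSequence:
    """``motif`` repeated ``n_copies`` times."""
    return SymbolSequence(motif.upper() * n_copies, DNA, name or f"rep_{motif}")


def homopolymer(base: str, length: int) -> SymbolSequence:
    return SymbolSequence(base.upper() * length, DNA, f"poly{base.upper()}")


def shuffled(seq: SymbolSequence, seed: int = 0) -> SymbolSequence:
    """Symbol shuffle: identical composition, order destroyed."""
    rng = np.random.default_rng(seed)
    arr = list(seq.symbols)
    rng.shuffle(arr)
    return SymbolSequence("".join(arr), seq.alphabet, seq.name + "_shuf")


def planted_sequence(
    length: int = 1000,
    plant: str = "ACGT" * 37,
    position: int | None = None,
    gc: float = 0.5,
    seed: int = 0,
) -> tuple[SymbolSequence, int]:
    """i.i.d. background with a low-complexity 147-mer planted inside.

    The default plant is a period-4 tandem repeat of GC content 0.5, i.e.
    GC-matched to the default background, so GC profiling carries no
    information about where it sits.  Returns ``(sequence, plant_start)``.
    """
    rng = np.random.default_rng(seed)
    if position is None:
        position = int(rng.integers(0, length - len(plant) + 1))
    if not 0 <= position <= length - len(plant):
        raise ValueError("plant does not fit at the requested position")
    bg = rng.choice(BASES, size=length, p=_gc_probs(gc))
    bg[position : position + len(plant)] = list(plant)
    return SymbolSequence("".join(bg), DNA, "planted"), position


def genome_segment(
    length: int = 50_000,
    gc: float = 0.45,
    n_elements: int = 40,
    seed: int = 0,
    name: str = "synthetic_segment",
) -> SymbolSequence:
    """Synthetic genomic segment: i.i.d. backbone plus AT-rich elements.

    ``n_elements`` low-complexity elements — poly-dA tracts, poly-dT
    tracts, and short AT tandem repeats of 20-80 nt — are overwritten at
    uniform positions, emulating nucleosome-depleted regions.
    """
    rng = np.random.default_rng(seed)
    arr = rng.choice(BASES, size=length, p=_gc_probs(gc))
    for _ in range(n_elements):
        kind = int(rng.integers(3))
        if kind == 0:
            elem = "A" * int(rng.integers(20, 60))
        elif kind == 1:
            elem = "T" * int(rng.integers(20, 60))
        else:
            motif = "".join(rng.choice(list("AT"), size=int(rng.integers(2, 5))))
            elem = (motif * 40)[: int(rng.integers(30, 80))]
        pos = int(rng.integers(0, length - len(elem)))
        arr[pos : pos + len(elem)] = list(elem)
    return SymbolSequence("".join(arr), DNA, name)


def windowed_gc(seq: SymbolSequence, window: int = 147) -> np.ndarray:
    """Per-position GC fraction in a centred window (clipped at the ends)."""
    is_gc = np.isin(np.array(list(seq.symbols)), ["G", "C"]).astype(float)
    half = window // 2
    cs = np.concatenate([[0.0], np.cumsum(is_gc)])
    idx = np.arange(len(seq))
    lo = np.clip(idx - half, 0, None)
    hi = np.clip(idx + window - half, None, len(seq))
    return (cs[hi] - cs[lo]) / (hi - lo)


def make_occupancy(
    seq: SymbolSequence,
    coupling: Callable[[np.ndarray], np.ndarray] | None = None,
    noise_sd: float = 0.02,
    seed: int = 0,
    window: int = 147,
    source: str = "synthetic",
) -> OccupancyTrack:
    """Occupancy = coupling(windowed GC) + Gaussian noise, clipped at 0.

    The identity coupling (default) gives a track that follows local GC
    content — the dominant sequence signal of occupancy — so the planted
    AT-rich elements of :func:`genome_segment` become occupancy minima.
    """
    rng = np.random.default_rng(seed)
    gc = windowed_gc(seq, window)
    base = gc if coupling is None else np.asarray(coupling(gc), dtype=float)
    occ = base + rng.normal(0.0, noise_sd, size=len(base))
    return OccupancyTrack(np.clip(occ, 0.0, None), seq.name, 0, source)


def curvature_panel(seed: int = 0, length: int = 147) -> list[SymbolSequence]:
    """Twenty synthetic sequences spanning the structural classes used to
    probe curvature-versus-complexity sign structure.

    Four homopolymers; three period-10 motifs carrying phased AA steps
    (constructive helical phasing, hence high modelled curvature); three
    AA-free short-period repeats; five i.i.d. random sequences; and the
    symbol shuffles of those five randoms.
    """
    rng = np.random.default_rng(seed)
    panel: list[SymbolSequence] = []
    for base in DNA:
        panel.append(homopolymer(base, length))
    for motif in ("AAATTTCGCG", "AATGCACGTG", "AAGGAACCGG"):
        panel.append(SymbolSequence((motif * 20)[:length], DNA, f"phased_{motif}"))
    for motif in ("ACGT", "AC", "AGC"):
        panel.append(SymbolSequence((motif * length)[:length], DNA, f"rep_{motif}"))
    randoms = [
        SymbolSequence(
            "".join(rng.choice(BASES, size=length)), DNA, f"rand_{i}"
        )
        for i in range(5)
    ]
    panel.extend(randoms)
    panel.extend(shuffled(r, seed=int(rng.integers(2**31))) for r in randoms)
    return panel


# ---------------------------------------------------------------------------
# Declarative spec (CLI / JSON entry point)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of one synthetic input.

    ``kind`` is one of ``iid_dna``, ``periodic``, ``homopolymer``,
    ``shuffled``, ``planted``, ``genome_segment``; ``params`` feeds the
    matching generator.  Identical specs yield identical outputs.
    """

    kind: str
    length: int = 147
    seed: int = 0
    params: tuple = field(default_factory=tuple)

    def as_kwargs(self) -> dict:
        return dict(self.params)


def make_sequence(spec: FixtureSpec) -> SymbolSequence:
    kw = spec.as_kwargs()
    if spec.kind == "iid_dna":
        return iid_dna(spec.length, kw.get("gc", 0.5), spec.seed)
    if spec.kind == "periodic":
        motif = kw.get("motif", "AC")
        n = -(-spec.length // len(motif))
        return SymbolSequence(
            (motif.upper() * n)[: spec.length], DNA, f"rep_{motif}"
        )
    if spec.kind == "homopolymer":
        return homopolymer(kw.get("base", "A"), spec.length)
    if spec.kind == "shuffled":
        return shuffled(iid_dna(spec.length, kw.get("gc", 0.5), spec.seed), spec.seed)
    if spec.kind == "planted":
        return planted_sequence(spec.length, seed=spec.seed, gc=kw.get("gc", 0.5))[0]
    if spec.kind == "genome_segment":
        return genome_segment(
            spec.length,
            kw.get("gc", 0.45),
            kw.get("n_elements", 40),
            spec.seed,
        )
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
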