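# nucleoscore

Training-free complexity scoring of DNA sequences for nucleosome-occupancy
analysis.

Nucleosomes package ~147 bp of DNA around histone octamers; where they sit
(and where they don't) shapes transcription-factor access and gene
regulation. The dominant sequence predictors of occupancy are trained —
k-mer models, HMM-based interaction models — and lean heavily on GC
content. `nucleoscore` implements the complementary, *training-free*
approach: score DNA windows with information-theoretic and
algorithmic-complexity measures that require no prior knowledge of
informative motifs, and ask how much occupancy signal they recover.

## The measures

For a window *s* over the alphabet {A,C,G,T} (or its binary SW/RY
reductions):

- **GC content** — (#G + #C) / |s|; the classical baseline.
- **Shannon entropy** — plug-in entropy of overlapping k-blocks,
  H_k(s) = −Σ p̂_i log₂ p̂_i (bits per block).
- **Entropy rate** — H₂(s) − H₁(s), the conditional entropy of the next
  symbol.
- **LZW** — number of codes emitted by Lempel-Ziv-Welch compression with
  an alphabet-initialized dictionary (implemented in-repo so code counts
  are platform-exact).
- **CTM** (Coding Theorem Method) — estimate the algorithmic probability
  m(s) as the output frequency of *s* over an ensemble of small Turing
  machines run from blank tape, then K(s) ≈ −log₂ m(s) by the algorithmic
  coding theorem. Direct values exist only for short strings, so the
  machine ensemble, its step cutoff and its sample size are first-class,
  inspectable provenance of every table.
- **BDM** (Block Decomposition Method) — extend CTM to long sequences:
  partition *s* into fixed-length blocks and sum CTM(b) + log₂ n_b over
  distinct blocks b with multiplicity n_b. Approximates entropy in the
  long-sequence limit but algorithmic complexity at block scale.
- **Logical depth (LD)** — Bennett's "organization" measure, estimated as
  the multiplicity-weighted sum of the minimal halting runtime among the
  machines that produced each block. Trivial *and* random sequences are
  shallow; organized ones are deep. LD is the one measure expected to
  *invert*: what is maximally random for BDM is shallow for LD.

On top of the measures the package provides: the Turing-machine engine
that enumerates/samples (n-state, m-symbol) rule spaces and builds CTM
tables (`tm_engine`), SW/RY transforms (`transforms`), sliding-window
profiling and occupancy-track correlation (`profiler`), the wedge
dinucleotide curvature model — 8.7° per AA step summed at helical phase
(`curvature`), the GC-matched nucleosome centre-location test
(`location`), extreme-occupancy separation analysis (`extremes`), and
seeded synthetic-data generators (`fixtures`).

## Worked example

```python
import numpy as np
import nucleoscore as ns
from nucleoscore.measures import MeasureSpec, supported_block_len

# build a reduced CTM table: 1e6 sampled 2-state 5-symbol machines,
# DNA mapped onto the four non-blank symbols
dist = ns.build_distribution(n_states=2, n_symbols=5, cutoff=107,
                             sample_size=1_000_000, seed=0)
table = ns.complete_by_symmetry(ns.ctm_table_from_distribution(dist))
bl = supported_block_len(table)   # largest block length the table covers
print(f"halting fraction: {dist.halting_fraction:.3f}, "
      f"table entries: {len(table)}, supported block length: {bl}")

rep = ns.SymbolSequence.dna("AC" * 73 + "A")
rnd = ns.fixtures.iid_dna(147, seed=1)
for name, seq in (("repeat 147-mer", rep), ("random 147-mer", rnd)):
    print(f"BDM({name}) = {ns.bdm_score(seq, table, bl):7.2f} bits   "
          f"LD = {ns.ld_score(seq, table, bl):6.1f} steps")

# localize a GC-matched tandem-repeat plant in random DNA by the BDM minimum
seq, pos = ns.fixtures.planted_sequence(1000, ("ACGT" * 37)[:147], seed=5)
prof = ns.normalize01(ns.profile(seq, MeasureSpec("bdm", table=table)))
called = int(prof.window_centers()[np.nanargmin(prof.values)])
print(f"plant centre: {pos + 73}, BDM-minimum call: {called}")
```

prints

```
halting fraction: 0.500, table entries: 24965, supported block length: 6
BDM(repeat 147-mer) =   37.04 bits   LD =  365.0 steps
BDM(random 147-mer) =  474.80 bits   LD =  356.0 steps
plant centre: 645, BDM-minimum call: 647
```

The repeat scores ~13× lower BDM than random DNA of the same length and
GC content (its blocks collapse into few distinct types), while its
logical depth is *higher* — the sign inversion that makes LD a useful
companion signal. The planted repeat, invisible to GC content by
construction, is localized to within 2 nt by the BDM minimum.

A command-line surface wraps the same operations:

```bash
nucleoscore ctm-build --states 2 --symbols 5 --sample 1000000 --seed 0 \
    --complete --out table.tsv
nucleoscore profile --fasta region.fa --measure bdm --table table.tsv \
    --window 147 --normalize --out profile.tsv
nucleoscore locate --nucs nucleosomes.fa --dyads dyads.tsv \
    --table table.tsv --measures bdm,ld,entropy,gc --out calls.tsv
nucleoscore extremes --fasta region.fa --track occupancy.tsv \
    --measures gc,entropy,bdm,ld --table table.tsv --out report.json
```

Occupancy tracks are read from two-column TSV, bedGraph or fixed-step
wiggle; experimental tracks (in vivo / in vitro / model scores) drop in
wherever the synthetic tracks are used here.

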