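# Methods

This note records the models, conventions and parameter choices behind
`nucleoscore`, in enough detail to reproduce or deliberately change any of
them.

## Machine formalism and rule coding

Turing machines follow the busy-beaver convention: `n` work states, `m`
tape symbols with 0 the blank, a two-way infinite tape that starts blank,
head at the origin, start state 0. Every transition writes a symbol and
moves one cell (no stay-put); the successor may be the implicit HALT
pseudo-state, and the halting transition counts as a step. The rule space
therefore holds `(2·m·(n+1))^(n·m)` machines; rules are addressed by a
mixed-radix integer index (one digit per `(state, read)` entry, entries in
`(state, read)` lexicographic order, little-endian), which makes
encode/decode a checked bijection. Under this convention the full (2,2)
enumeration reproduces the classical busy-beaver bound S(2) = 6, which the
test suite asserts.

**Output extraction.** The output of a halting machine is the contiguous
tape segment spanning every cell the head *scanned* — occupied at the
start of an executed step — read left to right at halt. The cell the head
lands on after the final move is excluded; a machine that halts on its
first step outputs exactly one symbol. This convention is not forced by
the theory; it is fixed here because every downstream number depends on
it, and both the scalar and the vectorized simulator implement it
identically (a third, deliberately naive implementation in the test suite
and acceptance script cross-checks them on 10⁴ random machines).

**Cutoff.** Machines are run at most 107 steps (configurable); non-halters
are excluded from the distribution. For 2-state spaces this is far above
S(2) = 6. Machines that would halt after the cutoff with very long
computations are lost — an inherent, documented truncation of any
coding-theorem estimate (halting is undecidable), recorded in table
provenance.

## CTM tables

An output distribution maps each produced string to its frequency and its
minimal observed halting runtime. The table derives
`ctm_bits(s) = −log₂(count(s)/total_halting)` bit-exactly (asserted
against the paired distribution), with outputs longer than `max_len = 12`
truncated to their first 12 symbols and merged, so long computations still
contribute mass to scoreable blocks.

**Desk-scale sampling.** The (2,2) space (20,736 rules) is enumerated
fully. The (2,5) space (30¹⁰ ≈ 5.9·10¹⁴ rules) is sampled uniformly —
default 4·10⁶ machines, seeded — which is the deliberate desk-scale
reduction of the reference builds of this method, which used ensembles on
the order of 10¹³ machines. Tables carry their sample size, cutoff and
seed in provenance and in the TSV header, and must never be mistaken for
exhaustive tables.

**Symmetry completion.** Reversal (mirror all moves) is an exact symmetry
of the rule space; so is any relabelling of the non-blank symbols.
Relabellings that move the blank are *not* exact — the blank is
distinguished by the initial tape — and measurably so: in the full (2,2)
enumeration, count("00") = 728 but count("11") = 680. `complete_by_symmetry`
nevertheless closes tables under reversal and *all* symbol permutations,
assigning each orbit its minimum observed value: for reduced sampled
tables the coverage gain (≈ 17× for the default (2,5) build) outweighs the
approximation, and the operation is flagged in provenance. Two side
effects are worth knowing: completed values are biased low for strings
with large orbits, and the exact-symmetry tests restrict themselves to the
provable group (reversal, blank-fixing permutations).

**What 2-state tables can and cannot cover.** A 2-state machine cannot
count to 12, so no (2,k) ensemble of any size produces 12-symbol
blank-free outputs in practice: coverage of DNA 12-mers is exactly zero,
and even period-2 alternations like `121212` are absent at length 6.
Measured blank-free coverage of the default (2,5, 4·10⁶) completed table:
100% at length ≤ 5, ≈ 96% at length 6, ≈ 2% at length 8, 0 beyond. The
present length-6 values span only ≈ 2 bits, so at desk scale the
single-block CTM resolution is coarse; BDM's discriminative power comes
mainly from the multiplicity term and the missing-block penalty, and LD's
from the present-versus-missing runtime structure. These are honest
properties of reduced tables, not of the method at reference scale.

**Fallbacks.** A block absent from the table scores the table's maximum
value + 1 bit in BDM (penalize unseen, preserve ranking, never abort) and
the table's median runtime in LD; both events are logged at debug level.

**Block length.** BDM defaults to the conventional 12-symbol blocks.
Analyses that need every block scoreable — logical depth above all — use
`supported_block_len(table)`: the largest length the table covers at
≥ 50% (6 for the default build). Both choices are recorded in each
profile's metadata.

**DNA mapping.** DNA scores against a 5-symbol table as A,C,G,T →
1,2,3,4 with the blank unused (the blank is the machines' background
symbol, not a base); a 4-symbol table maps A,C,G,T → 0,1,2,3 for the
alternative reading. SW/RY reductions score against binary tables as
S,R → 0 and W,Y → 1.

## Measures

Entropy and entropy rate use plug-in (empirical-frequency) estimators on
overlapping blocks with uniform positional weighting and no smoothing;
the rate is H₂ − H₁, clipped at 0. LZW initializes its dictionary with
the declared alphabet and reports the emitted-code count. All measures
are deterministic functions of (sequence, table, parameters); the exact
estimator choices are parameterized rather than asserted as canonical,
since plug-in estimation is one of several defensible readings.

## Profiling and correlation

A profile assigns each length-147 window's score (147 nt = nucleosomal
DNA) to its start index internally; comparisons with occupancy use
window-centre alignment. Windows touching any out-of-alphabet symbol
(N, gaps) are missing, never zero. By default a window's score is
compared with the *mean* occupancy over its footprint; the alternative
(occupancy at the centre position) is a flag. Correlations are Spearman
with average ranks on ties and pairwise deletion of missing pairs;
normalization to [0,1] is rank-preserving, so correlations are invariant
under it. The sliding correlation window (default 4000 profile points)
reports the per-window correlation series plus its maximum and minimum.

## Curvature (wedge model)

Bending is modelled as a fixed 8.7° wedge at every AA dinucleotide step
and nothing else; successive wedges act at the helical phase of their
step (34.3°/step, period ≈ 10.5 bp) and are summed as planar vectors; a
window's bend magnitude is the resultant's norm, in degrees. The helical
twist and the vector-sum geometry are the standard presentation of the
wedge model; all angles are configurable (TSV-loadable), and an optional
flag treats TT as AA read from the opposite strand (off by default: the
minimal model attributes bending solely to AA). Because a window shift
only rotates all terms by a common phase, bend magnitude depends on AA
phasing, not absolute position — phased A-tracts at the helical period
add coherently, half-period spacing cancels; both facts are tested.

## Centre-location test

Candidate nucleosomal 147-mers are interleaved with pseudo-random
backgrounds (i.i.d. draws at a target GC, 147 nt each) whose GC matches
their immediate *left* nucleosomal neighbour — the leading background
uses the first nucleosome's GC, trailing extras the last's — erasing GC
contrast by construction (14 nucleosomes + 16 backgrounds → 30 segments).
Centres are called at the profile extremum within the segment span
widened by 36 nt (tolerates profile edge effects; ties break toward the
segment midpoint): minimum for the structure-seeking measures, maximum
for LD, and both for GC content (its "extra edge"). A call within 73 bp
of the known dyad — or of the segment midpoint when no dyad is known —
counts as a hit; calls farther out are reported as outside-window, never
silently dropped. The search-span widening and tie-break are this
package's choices; both are configurable.

Score histograms bin normalized values into 0.05-wide bins over [0,1]
with a normal reference curve whose moments come from the GC profile
(the measure expected to behave normally here), plus a KS
departure-from-normal statistic.

## Extreme-occupancy separation

Positions strictly above the 98th percentile ("high", top 2%) and
strictly below the 0.2nd percentile ("low") of a track — type-7
interpolated quantiles, which the set sizes depend on — are expanded to
147-nt windows (clipped at track ends) and scored with every measure.
Separation is summarized by per-set five-number summaries (the box-plot
view) plus Cliff's delta, a rank-based effect size chosen because it is
distribution-free and matches the visual box-plot comparison; a
permutation null (shuffled track) calibrates what "informative" means.
Empty sets are flagged, not fabricated.

## Synthetic data: what it emulates, what it does not

The generators are the package's study conditions, fixed once:

- **Genome segment** (default 50 kb): i.i.d. backbone at GC 0.45 with 40
  planted AT-rich low-complexity elements (poly-dA/dT tracts of 20–60 nt,
  AT tandem repeats of 30–80 nt). This emulates the one robust sequence
  feature a generator can honestly claim: nucleosome-depleted regions are
  poly-dA:dT-like — AT-rich *and* repetitive.
- **Occupancy**: windowed (147 nt) GC content through a monotone coupling
  (identity by default) plus Gaussian noise (sd 0.02), clipped at 0 —
  the GC-driven picture of occupancy.
- **Curvature panel** (20 sequences, 147 nt): 4 homopolymers, 3
  period-10 phased-AA motifs, 3 AA-free short repeats, 5 i.i.d. randoms
  and their shuffles.
- **Planted-construct**: a period-4 tandem repeat of GC 0.5 inside
  GC-0.5 i.i.d. DNA — zero GC contrast, maximal complexity contrast.
- **Synthetic nucleosome stand-in set**: 14 partially structured
  147-mers with alternating known/unknown dyads; a stand-in exercising
  the S5-shaped pipeline, *not* real nucleosome positioning sequences.

Not emulated: MNase bias, the ~10-bp rotational dinucleotide
periodicity, k-mer-specific binding preferences, in vivo remodelling.
Passing tests therefore demonstrate that the machinery recovers planted
complexity/GC structure under controlled conditions — they do not certify
performance on experimental tracks, which the I/O layer accepts but the
repository does not ship.

## Determinism and numerics

Every stochastic step takes an explicit seed (numpy `default_rng`);
identical inputs give byte-identical serialized tables and fixtures.
Constant profiles normalize to 0.5 with a warning; constant inputs to
correlations report NaN rather than a fabricated value; quantile and
tie-break conventions are stated above because results depend on them.

## Known limitations

- 2-state machine spaces cannot cover long blocks (see above); scores of
  sequences dominated by uncovered blocks rest on the fallback rules.
- The coding-theorem estimate inherits the cutoff truncation and, for
  sampled spaces, sampling noise; single-block values at desk scale carry
  ≈ 1–2 bits of resolution at length 6.
- The wedge model is the minimal dinucleotide geometry; junction,
  trinucleotide and elastic models are out of scope.
- Experimental headline numbers (correlations with in vivo / in vitro
  yeast tracks, genome-scale window counts) require external data and
  reference-scale tables; the pipeline ingests such data but the
  repository neither ships nor reproduces it.
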