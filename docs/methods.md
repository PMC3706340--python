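# Methods

## Problem and model

The package asks when a circular DNA sequence `s` of length `G` can be
*completely reconstructed* — recovered exactly, up to rotation — from `N`
error-free reads of fixed length `L` whose start positions are i.i.d.
uniform on the circle.  Reconstruction must succeed with probability at
least `1 − ε` (ε < 1/2).  This is the single-strand, noiseless idealisation
of shotgun sequencing: no base errors, no mate pairs, no reverse
complement, no length variation.  Within it, feasibility is governed by two
forces:

1. **Coverage.** The reads must cover the circle and chain together.  With
   Poisson-approximated starts the required read count is the fixed point
   `N_LW = (G/L) ln(N_LW/ε)`; all depths are reported normalised,
   `c̄ = N/N_LW`.
2. **Repeats.** Substrings occurring more than once confuse assembly.  The
   relevant statistics are the maximal repeat counts `a_m`, the interleaved
   pair counts `b_{m,n}` and the triple repeat counts `c_m`.  Two repeats
   are *interleaved* when their copy starts alternate around the circle;
   the pair's length is the shorter of the two.  If an interleaved pair or
   a triple repeat has *all* copies unbridged — no read covers a base on
   both sides of a copy — the read likelihood is identical under a second
   sequence (the segment swap of `fixtures.make_confusable`), so no
   algorithm can commit to an answer.  This yields the hard threshold
   `L_crit = max(ℓ_interleaved, ℓ_triple) + 1` and, above it, a depth lower
   bound from requiring each confusing event to be bridged with probability
   `1 − 2ε`.

A length-`ℓ` interval is bridged when a read starts in the preceding window
of `L − ℓ − 1` positions; under the Poisson model an interval is unbridged
with probability `p_ℓ = exp(−(N/G)(L − ℓ − 1)⁺)`.

## Algorithms and their guarantees

All four assemblers are implemented blind: they see read strings only.

* **GREEDY** merges the pair of fragments with the largest suffix–prefix
  overlap until one fragment remains, then closes the circle on the
  fragment's largest border.  It reconstructs exactly whenever every
  maximal repeat is bridged and the reads cover the circle.  The
  implementation sweeps overlap levels `w = L−1 … 1` with prefix
  dictionaries (equal-length reads can overlap by at most `L−1`), which is
  the same algorithm with near-linear cost; ties are broken
  lexicographically so runs are reproducible, and the guarantee does not
  depend on the tie-break.
* **DEBRUIJN(K)** builds the K-mer graph of the reads (edge set = distinct
  (K+1)-mers), condenses unambiguous paths, and spells the Eulerian cycle.
  It succeeds when no interleaved or triple repeat reaches length `K` and
  adjacent reads overlap by at least `K`; the depth cost of the overlap
  condition is the coverage fixed point with spacing `L − K`, i.e.
  `c̄ ≈ 1/(1 − K/L)` at the theorem-minimal `K = L_crit`.
* **SIMPLEBRIDGING(K)** additionally splits *bridged 2-X-nodes*: a condensed
  node with in/out degree two traversed twice corresponds to a two-copy
  repeat; a read threading through it pairs one entry edge with one exit
  edge, and the node is duplicated accordingly.  Self-overlapping repeats
  (self-loops) are handled by letting the loop's entry and exit slots land
  on different copies.  Its conditions: all interleaved repeats bridged,
  `K > ℓ_triple`, adjacent overlap ≥ `K`.
* **MULTIBRIDGING(K)** resolves *any* bridged X-node locally by extending
  each neighbour one base into the node (edge weights grow by one), wiring
  entry extensions to exit extensions as witnessed by reads, and inferring
  the single missing pair when exactly one entry and one exit remain
  unmatched — so a two-copy repeat needs only one bridged copy, while a
  triple repeat needs all three copies bridged.  A self-loop of weight `a`
  is replaced by an edge from the right-extension to the left-extension
  with weight `a + 2` (suffix/prefix algebra on the node's border forces
  this direction).  Its conditions: all interleaved repeats bridged, all
  triple repeats all-bridged, and the (K+1)-spectrum observed.

Eulerian-cycle uniqueness is decided structurally on the found cycle: the
cycle is non-unique iff some node is traversed three or more times (its
segments can be cyclically permuted) or two twice-traversed nodes alternate
(their parallel segments can be exchanged) — the graph mirror of triple and
interleaved repeats.  Ambiguous assemblies return one spelling plus a
witness alternative; they are never silently resolved.

### Coverage versus spectrum completeness

The sufficient condition for MULTIBRIDGING is often stated with bare
coverage, but with a fixed `K` a (K+1)-mer straddling two reads that
overlap by fewer than `K` bases is observed by neither read and the graph
breaks.  Coverage and overlap-by-K coincide only in the continuous limit
with `K ≪ L`.  The condition checker therefore reports both flags, and the
conditional-guarantee harness certifies MULTIBRIDGING trials with the
(slightly stronger, provably sufficient) overlap-by-K condition.  At the
scales simulated here the two events differ in a few trials per thousand.

## Feasibility curves

`feasibility.build_feasibility_table` evaluates, per read length `L`, the
minimal `N` for the lower bound and the four algorithms.  Constraint sums
are inverted by bisection (all are strictly decreasing in `N`); coverage
conditions are fixed points of the generalised Lander–Waterman equation
with spacing `L − K`.  Natural logarithms throughout.  Each probabilistic
constraint receives the full error budget `ε`, which reproduces the
standard curves; a stricter equal-split mode is not provided because the
union-bound slack already dominates.

The curves are *K-aware*: with parameter `K` only repeats of length ≥ `K`
materialise as X-nodes, so the bridging sums are floored at `K`.  This
matters numerically: the exact triple count at small lengths is of order
`G³` (about `10¹²` at `G = 10⁵` for single bases), and summing it down to
`m = 1` would inflate the MULTIBRIDGING curve roughly three-fold while
describing an algorithm nobody would run.  MULTIBRIDGING's curve takes the
cheaper of two natural parameter choices — `K` at the background floor
(`⌊2 log₄ G⌋ + 2`, just above the longest repeat an i.i.d. sequence of that
length typically carries) and `K = ℓ_triple + 1` — mirroring how the
parameter is chosen in practice.

When a single long triple repeat dominates the statistics, the ratio of
MULTIBRIDGING's depth to the lower bound approaches
`3·ln(3/ε)/ln(1/(2ε))`: all three copies must be bridged instead of one.
`gap_factor` returns the commonly printed simplification
`3·ln(3/ε)/ln(1/ε)` (≈ 3.72 at ε = 10⁻²); the extra factor 2 inside the
lower bound's logarithm is kept in the curves themselves.

The transition from repeat-limited to coverage-limited depth happens over a
read-length window of width `W ≈ L_crit/(2r+1)` with
`r = ln(G/L_crit)/ln(1/ε)`.  This is a report-only diagnostic, never a
constraint.

## Repeat statistics

Counts `a_m` and `c_m` are exact at every length.  They are accumulated
over the LCP-interval tree of the doubled sequence (suffix array by numpy
prefix doubling, Kasai LCP): a tree node of string depth `d` groups the
occurrences of a repeated length-`d` substring, its children partition them
by right flank, and the left flank is a per-leaf class, so maximal pairs
and triples are counted per node by inclusion–exclusion over the two flank
partitions without materialising them.  Explicit occurrence lists — needed
for the interleaving table and for bridging checks — are enumerated down to
length 1 for `G ≤ 600` and down to `⌊2 log₄ G⌋ − 3` above that; the `b`
table additionally floors the repeat length at 2 for `G > 120` (interleaved
pairs of single-base repeats number ~`G⁴/512` and carry weight `~e^{−4c}`
in every formula) and caps the quadratic interleaving test at the 10⁴
longest repeats, with truncation flagged.  Circular genomes use the doubled
string with occurrences restricted to the first copy; repeats of length
≥ G/2 (self-overlapping on the circle) are excluded and flagged.  A
substring-grouping brute-force enumerator with identical semantics is the
test oracle.

Conventions: 0-based positions, half-open intervals, circular arithmetic
mod G; a linear sequence's boundary flanks are unique sentinels, so copies
abutting an end are maximal there.  `b_{m,n}` is stored with `m ≤ n` and
counts pairs of two-copy occurrences (a substring occurring `f` times
contributes its `C(f,2)` pairs individually).

## Synthetic data

The fixture generator emulates exactly the study conditions of the model:
i.i.d. uniform background sequence with planted repeat structure — pairs,
interleaved pairs, nested pairs, triples — whose copies are written at
spaced positions and whose flanks are perturbed to pairwise-distinct bases,
making the planted elements maximal by construction.  Each fixture is
re-analysed after generation and rejected (fresh subseed) unless the
planted elements are realised as the extremal repeat lengths and no
accidental background repeat exceeds `⌊2 log₄ G⌋ + 8`.  Two canned regimes
cover the qualitatively different parts of parameter space: interleaved-
dominant (`ℓ_interleaved ≫ ℓ_triple`, the common case in sequenced
genomes, where MULTIBRIDGING is near-optimal) and triple-dominant (where
the 3.7× gap opens).

What the generator does **not** emulate: base composition bias, repeat
families with diverged copies, tandem expansions, sequencing error, double-
strandedness.  Passing tests therefore certify the combinatorial and
probabilistic machinery under the stated model, not performance on real
instruments' data; on a real genome the statistics pipeline applies
unchanged (FASTA in), but the guarantees inherit the model's idealisations.

## Numerical and procedural choices

* Read sampling uses numpy's PCG64 with explicit integer seeds; trial
  batches derive child seeds from a master seed via `SeedSequence`, so
  every simulation is reproducible bit for bit.
* Fixed-point and bisection solves run to relative tolerance `10⁻⁹`
  (residual asserted at `10⁻⁶·N`); curves are declared infeasible beyond
  `10³·N_LW`.
* All graph tie-breaks (Hierholzer next-edge choice, surgery order) are
  lexicographic on node labels, then node id.
* Degenerate inputs: empty read sets, `K ≥ L`, reads as long as the
  genome, and non-ACGT characters are rejected with specific errors;
  ambiguity codes in FASTA can optionally split the record into linear
  contigs instead.
* Success is exact circular-rotation equality with the reference; reverse-
  complement matches are deliberately *not* accepted (single-strand model).

## Problem sizes used by the test-suite and acceptance script

Conditional-guarantee harness: randomized genomes of `G ∈ [200, 400]` in
five repeat regimes, `L ∈ [36, 60]`, `N ≈ 1.6·G(ln G + 3)/(L−2)` (deep
enough that the hypotheses usually certify), ≥ 500 certified trials per
algorithm in the acceptance suite.  Finder/oracle equivalence: 100 random
genomes up to `G = 500`, both topologies.  Curve-versus-simulation: one
interleaved-dominant genome of `G = 10⁵`, ε = 0.05, 100 trials at an
(N, L) point on the MULTIBRIDGING curve just beyond the critical window,
plus a half-coverage control.  The acceptance script repeats these
computations at moderately reduced trial counts and writes every quantity
it computes to JSON.

## Known limitations

* SIMPLEBRIDGING leaves X-nodes of multiplicity ≥ 3 to the Eulerian step,
  as specified; genomes with triple repeats above its `K` produce honest
  `ambiguous`/`failed` results rather than resolutions.
* MULTIBRIDGING skips (and reports) X-nodes with more than one unwitnessed
  entry/exit pair, and nodes whose neighbour labels are too short to donate
  an extension base; under the theorem hypotheses neither occurs.
* The repeat-pattern lower bound takes the binding single event
  (`mode="max"`); the summed-events variant (`mode="sum"`) is available
  but floors its triple events at the enumeration length, as the exact
  small-length counts would swamp the sum numerically.
* `l_interleaved` is exact whenever occurrence enumeration is exact
  (`G ≤ 600` by default); with truncated enumeration it is a lower bound,
  dominated in practice by the planted/long repeats that drive the curves.
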