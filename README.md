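# debridge

When is complete genome reconstruction from shotgun reads *possible*, and
which assembly algorithm achieves it at the lowest coverage depth?

`debridge` answers this for the idealised shotgun model — `N` error-free
reads of fixed length `L` drawn uniformly from a circular genome of length
`G`, target success probability `1 − ε` — where feasibility is controlled
entirely by the genome's **repeat statistics**:

* `a_m` — maximal repeats of length `m` (flanks differ on both sides),
* `b_{m,n}` — interleaved repeat pairs (copy starts alternate around the
  circle; the pair's length is the shorter repeat's),
* `c_m` — triple repeats (three copies, flanks not all equal on either side).

Below the critical read length
`L_crit = max(ℓ_interleaved, ℓ_triple) + 1` reconstruction is impossible at
any depth: an interleaved pair or triple repeat whose copies are all
*unbridged* (no read covers a base on both sides of a copy) makes a second
sequence — the segment swap produced by `make_confusable` — exactly as
likely as the truth.  Above `L_crit`, the minimal number of reads for each
algorithm follows from requiring its sufficient conditions to hold with
probability `1 − ε`, using the unbridged-interval probability
`p_ℓ = exp(−(N/G)(L−ℓ−1)⁺)` and the Lander–Waterman coverage fixed point
`N_LW = (G/L) ln(N_LW/ε)`.  Depths are reported as `c̄ = N/N_LW`.

The package provides, end to end:

* exact repeat statistics of a FASTA genome (suffix array + LCP-interval
  counting; an exhaustive oracle ships alongside for validation);
* the feasibility curves: the repeat-pattern lower bound and the minimal-`N`
  curves of **GREEDY**, **DEBRUIJN**, **SIMPLEBRIDGING** and
  **MULTIBRIDGING**, plus the critical-window width
  `W ≈ L_crit/(2r+1)`, `r = ln(G/L_crit)/ln(1/ε)`;
* the four assemblers themselves, run blind on read strings, with honest
  `ambiguous` reporting (one spelling plus a witness alternative);
* a seeded read simulator that checks, per trial, which algorithm's
  sufficient conditions hold — e.g. *every repeat bridged* (GREEDY) or
  *all triples all-bridged* (MULTIBRIDGING);
* a verified synthetic-genome generator that plants pairs, interleaved
  pairs, nested pairs and triples with exact maximality.

## Worked example

```python
from debridge import (interleaved_dominant_fixture, critical_window,
                      multibridging_curve_N, lander_waterman_N,
                      sample_reads, multibridging_assemble, rotations_equal)

fx = interleaved_dominant_fixture(G=100_000, seed=11)
st = fx.stats
print(st.l_interleaved, st.l_triple, st.L_crit)
# 285 35 286          <- longest interleaved pair 285, longest triple 35

cw = critical_window(100_000, st.L_crit, eps=0.05)
print(round(cw.W, 1), round(cw.r, 2))
# 58.2 1.96           <- depth collapses to coverage within ~58 bp of L_crit

L = 364               # just beyond L_crit + W
N = multibridging_curve_N(L, st, 100_000, 0.05)
print(round(N), round(N / lander_waterman_N(100_000, L, 0.05), 3))
# 3198 1.057          <- MULTIBRIDGING needs only ~6% more than bare coverage

reads = sample_reads(fx.genome, N=3199, L=364, seed=5000).sequences()
res = multibridging_assemble(reads, K=18)
print(res.status, rotations_equal(res.sequence, fx.genome.sequence))
# unique True         <- exact circular reconstruction, blind
```

The same numbers flow through the CLI:

```sh
debridge make-fixture --g 100000 --seed 11 --regime interleaved --out fx.fa
debridge stats fx.fa --out-json stats.json --out-spectrum spectrum.csv
debridge feasibility --stats-json stats.json --eps 0.05 --out-csv curves.csv
debridge simulate --genome fx.fa --algorithm multibridging -L 364 -N 3199 --trials 20 --seed 1
debridge assemble --algorithm multibridging --k 18 --reads reads.fa --out asm.fa --expect fx.fa
```

`curves.csv` holds `(algorithm, L, N_min, c_bar, feasible)` rows for all
five curves; infeasible points (below each algorithm's read-length
asymptote) carry `N_min = inf`.

## Scope

Single-strand, error-free, fixed-length reads.  Sequencing errors, mate
pairs, reverse-complement (double-strand) repeat analysis, heterogeneous
read lengths and non-uniform coverage are outside the model, as are
contig-level outputs for failed assemblies (diagnostics only).
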