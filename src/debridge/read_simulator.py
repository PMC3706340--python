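"""Error-free shotgun read simulation and theorem-hypothesis checking.

Reads are exact substrings of fixed length ``L`` whose start positions are
drawn i.i.d. uniform on the circular genome (the fixed-``N`` counterpart of
the Poisson model used by the analytic formulas).  Start positions are kept
only to decide, per trial, which reconstruction-guarantee hypotheses hold;
assemblers never see them.

Bridging: a length-``ell`` interval starting at ``t`` is bridged when some
read covers at least one base on each side, i.e. some read start lies in the
length ``L - ell - 1`` window ``[t + ell + 1 - L, t - 1]`` (mod G).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .genome import Genome
from .repeat_stats import RepeatStats


class Read(NamedTuple):
    start: int
    bases: str


@dataclass
class ReadSet:
    """N reads of length L with known (hidden-from-assemblers) starts."""

    genome: Genome
    L: int
    starts: np.ndarray
    seed: int | None = None
    _sorted: np.ndarray = field(default=None, repr=False, compare=False)

    @property
    def N(self) -> int:
        return len(self.starts)

    @property
    def G(self) -> int:
        return len(self.genome)

    def reads(self) -> list[Read]:
        return [Read(int(t), self.genome.substr(int(t), self.L)) for t in self.starts]

    def sequences(self) -> list[str]:
        return [self.genome.substr(int(t), self.L) for t in self.starts]

    def sorted_starts(self) -> np.ndarray:
        if self._sorted is None:
            object.__setattr__(self, "_sorted", np.sort(self.starts))
        return self._sorted

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, t in enumerate(self.starts):
                fh.write(
                    f">read{i} start={int(t)} L={self.L} seed={self.seed}\n"
                    f"{self.genome.substr(int(t), self.L)}\n"
                )


def sample_reads(genome: Genome, N: int, L: int, seed: int) -> ReadSet:
    """Draw N uniform, independent read starts; bit-reproducible per seed."""
    G = len(genome)
    if not (2 <= L < G):
        raise ValueError("need 2 <= L < G")
    if N < 1:
        raise ValueError("need N >= 1")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, G, size=N, dtype=np.int64)
    return ReadSet(genome=genome, L=L, starts=starts, seed=seed)


def bridged_mask(readset: ReadSet, t, ell) -> np.ndarray:
    """Vectorised bridging test for copies at positions ``t`` of lengths ``ell``."""
    t = np.atleast_1d(np.asarray(t, dtype=np.int64))
    ell = np.broadcast_to(np.asarray(ell, dtype=np.int64), t.shape)
    G, L = readset.G, readset.L
    S = readset.sorted_starts()
    w = L - ell - 1  # window length
    lo = (t + ell + 1 - L) % G
    hi = lo + w - 1
    wrap = hi >= G
    hi_mod = hi % G
    cnt_nowrap = np.searchsorted(S, hi + 1) - np.searchsorted(S, lo)
    cnt_wrap = (len(S) - np.searchsorted(S, lo)) + np.searchsorted(S, hi_mod + 1)
    cnt = np.where(wrap, cnt_wrap, cnt_nowrap)
    return (w > 0) & (cnt > 0)


def is_bridged(readset: ReadSet, t: int, ell: int) -> bool:
    """True iff some read covers >= 1 base on both sides of [t, t+ell)."""
    return bool(bridged_mask(readset, [t], [ell])[0])


class ConditionReport(NamedTuple):
    """Which reconstruction-guarantee hypotheses hold for a (reads, genome) pair.

    Semantics: a repeat is *bridged* if at least one copy is bridged;
    *all-bridged* if every copy is; an interleaved pair is bridged if at least
    one of its two repeats is bridged.
    """

    every_repeat_bridged: bool
    interleaved_all_events_bridged: bool
    triples_all_bridged: bool
    no_interleaved_above_K: bool
    no_triple_above_K: bool
    adjacent_overlap_ge_K: bool
    covered: bool
    K: int

    def greedy_ok(self) -> bool:
        return self.every_repeat_bridged and self.covered

    def debruijn_ok(self) -> bool:
        return (
            self.no_interleaved_above_K
            and self.no_triple_above_K
            and self.adjacent_overlap_ge_K
        )

    def simplebridging_ok(self) -> bool:
        return (
            self.interleaved_all_events_bridged
            and self.no_triple_above_K
            and self.adjacent_overlap_ge_K
        )

    def multibridging_ok(self) -> bool:
        # adjacent_overlap_ge_K (rather than bare coverage) guarantees the
        # (K+1)-spectrum is fully observed in the reads; see docs/methods.md.
        return (
            self.interleaved_all_events_bridged
            and self.triples_all_bridged
            and self.adjacent_overlap_ge_K
        )


def _unbridged_repeat_rows(readset: ReadSet, pairs: np.ndarray) -> np.ndarray:
    """Rows of ``pairs`` (t1, t2, len) in which *both* copies are unbridged."""
    if len(pairs) == 0:
        return pairs
    b1 = bridged_mask(readset, pairs[:, 0], pairs[:, 2])
    b2 = bridged_mask(readset, pairs[:, 1], pairs[:, 2])
    return pairs[~(b1 | b2)]


def _any_interleaved(rows: np.ndarray) -> bool:
    for x in range(len(rows)):
        p, q = int(rows[x, 0]), int(rows[x, 1])
        for y in range(x + 1, len(rows)):
            u, v = int(rows[y, 0]), int(rows[y, 1])
            if len({p, q, u, v}) < 4:
                continue
            if ((p < u < q) + (p < v < q)) == 1:
                return True
    return False


def check_conditions(
    genome: Genome, readset: ReadSet, stats: RepeatStats, K: int
) -> ConditionReport:
    """Evaluate every theorem hypothesis for one (genome, reads) trial.

    Exact whenever ``stats`` was computed with full occurrence enumeration
    (``stats.exact_enumeration``); with truncated enumeration the repeat-level
    flags refer to the enumerated repeats only.
    """
    L, G = readset.L, readset.G
    if K >= L:
        raise ValueError("need K < L")

    pairs, triples = stats.pairs, stats.triples

    # Theorem-2 hypothesis: each maximal repeat has >= 1 bridged copy.
    unbridged = _unbridged_repeat_rows(readset, pairs)
    every_repeat_bridged = len(unbridged) == 0

    # An interleaved pair is unbridged iff both of its repeats are unbridged,
    # so the all-pairs check reduces to interleaving among unbridged repeats.
    interleaved_ok = not _any_interleaved(unbridged)

    if len(triples):
        # all copies of every triple bridged <=> every distinct (pos, len)
        # triple-copy is bridged; the distinct-copy array is cached on stats
        occ = getattr(stats, "_triple_copy_cache", None)
        if occ is None:
            occ = np.unique(
                np.concatenate(
                    [triples[:, [0, 3]], triples[:, [1, 3]], triples[:, [2, 3]]]
                ),
                axis=0,
            )
            stats._triple_copy_cache = occ
        triples_ok = bool(bridged_mask(readset, occ[:, 0], occ[:, 1]).all())
    else:
        triples_ok = True

    no_interleaved_above_K = stats.l_interleaved < K
    no_triple_above_K = stats.l_triple < K

    S = readset.sorted_starts()
    gaps = np.diff(S)
    closing = G - int(S[-1]) + int(S[0]) if len(S) else G
    max_gap = max(int(gaps.max()) if len(gaps) else 0, closing)

    return ConditionReport(
        every_repeat_bridged=every_repeat_bridged,
        interleaved_all_events_bridged=interleaved_ok,
        triples_all_bridged=triples_ok,
        no_interleaved_above_K=no_interleaved_above_K,
        no_triple_above_K=no_triple_above_K,
        adjacent_overlap_ge_K=max_gap <= L - K,
        covered=max_gap <= L,
        K=K,
    )
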