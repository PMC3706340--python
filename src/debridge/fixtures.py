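"""Synthetic genomes with controlled repeat structure.

Every reconstruction-guarantee regime is reachable without external data:
i.i.d. background sequence plus *planted* elements — a repeat pair, an
interleaved pair, a nested pair, or a triple repeat — whose flanks are
perturbed so that the planted copies are exactly maximal (pairwise-different
flanks for pairs; pairwise-distinct flanks for triples).  After generation
the genome is re-analysed with :func:`debridge.repeat_stats.compute_stats`
and rejected (and re-drawn with a fresh subseed) unless the planted elements
are realised as the extremal repeat lengths and no accidental background
repeat exceeds its cap.

``make_confusable`` builds the likelihood-equality witness: given an
interleaved pair, swapping the two segments that run from the first repeat to
the second yields a different sequence with identical k-mer content for every
k up to the pair length + 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome import Genome
from .repeat_stats import RepeatStats, compute_stats

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantElement:
    kind: str  # pair | interleaved_pair | nested_pair | triple
    lengths: tuple  # one length per distinct repeat (1 or 2 entries)
    positions: tuple | None = None  # explicit copy starts, else auto

    def copy_count(self) -> int:
        return {"pair": 2, "interleaved_pair": 4, "nested_pair": 4, "triple": 3}[
            self.kind
        ]


@dataclass(frozen=True)
class FixtureSpec:
    G: int
    seed: int
    elements: tuple = ()
    max_background_repeat: int | None = None  # default: 2 log4 G + 8

    def background_cap(self) -> int:
        if self.max_background_repeat is not None:
            return self.max_background_repeat
        return int(2 * math.log(self.G, 4)) + 8


def random_genome(G: int, seed: int) -> Genome:
    """i.i.d. uniform circular genome."""
    if G < 4:
        raise ValueError("need G >= 4")
    rng = np.random.default_rng(seed)
    arr = _BASES[rng.integers(0, 4, size=G)]
    return Genome(arr.tobytes().decode(), "circular", f"random_G{G}_s{seed}")


def _copy_layout(element: PlantElement):
    """(repeat index, length) per copy, in genomic order."""
    if element.kind == "pair":
        (la,) = element.lengths
        return [(0, la), (0, la)]
    if element.kind == "triple":
        (la,) = element.lengths
        return [(0, la), (0, la), (0, la)]
    la, lb = element.lengths
    if element.kind == "interleaved_pair":
        return [(0, la), (1, lb), (0, la), (1, lb)]
    if element.kind == "nested_pair":
        return [(0, la), (1, lb), (1, lb), (0, la)]
    raise ValueError(f"unknown element kind {element.kind!r}")


def _auto_positions(spec: FixtureSpec, rng) -> list[list[int]]:
    """Copy start positions per element: sequential layout with evenly
    distributed slack and jitter, keeping a flank margin between intervals."""
    sizes = []
    for el in spec.elements:
        layout = _copy_layout(el)
        sizes.append([length for _, length in layout])
    total = sum(len(s) for s in sizes)
    if total == 0:
        return []
    total_len = sum(sum(s) for s in sizes)
    slack = spec.G - total_len - 8 * total
    if slack < 0:
        raise ValueError(
            f"infeasible placement: need {total_len + 8 * total} > G={spec.G}"
        )
    per_gap = slack // total
    cursor = 0
    positions = []
    for s in sizes:
        here = []
        for length in s:
            jitter = int(rng.integers(0, max(1, per_gap // 2)))
            pos = cursor + 4 + jitter
            here.append(pos)
            cursor = pos + length + 4
        positions.append(here)
    return positions


def plant(genome: Genome, spec: FixtureSpec) -> Genome:
    """Write the planted copies of ``spec.elements`` into ``genome``.

    Copy contents are drawn from a high-entropy generator; flanks are then
    perturbed to enforce exact (triple-)maximality.  No post-verification
    here — use :func:`make_fixture` for the verified constructor.
    """
    g, _ = _plant_with_positions(genome, spec)
    return g


def _plant_with_positions(genome: Genome, spec: FixtureSpec):
    """As :func:`plant`, also returning the realised copy starts per element."""
    G = len(genome)
    rng = np.random.default_rng(spec.seed ^ 0x5EED)
    arr = np.frombuffer(genome.sequence.encode(), dtype=np.uint8).copy()

    auto = _auto_positions(spec, rng)
    realised: list[list[int]] = []
    occupied: list[tuple[int, int]] = []
    for ei, el in enumerate(spec.elements):
        layout = _copy_layout(el)
        if el.positions is not None:
            starts = list(el.positions)
        else:
            starts = auto[ei]
        if len(starts) != len(layout):
            raise ValueError("positions do not match element copy count")
        realised.append(list(starts))
        # repeat contents
        content = {
            ri: _BASES[rng.integers(0, 4, size=ln)]
            for ri, ln in dict(layout).items()
        }
        copies_by_repeat: dict[int, list[tuple[int, int]]] = {}
        for (ri, ln), t in zip(layout, starts):
            if t < 3 or t + ln + 3 > G:
                raise ValueError("planted copy too close to the origin")
            for a, b in occupied:
                if t - 2 < b and a < t + ln + 2:
                    raise ValueError("planted segments overlap")
            occupied.append((t - 2, t + ln + 2))
            arr[t : t + ln] = content[ri]
            copies_by_repeat.setdefault(ri, []).append((t, ln))
        # flank enforcement: pairwise-distinct flank bases on each side
        for copies in copies_by_repeat.values():
            for side in (0, 1):
                perm = rng.permutation(4)[: len(copies)]
                for (t, ln), b in zip(copies, perm):
                    pos = t - 1 if side == 0 else t + ln
                    arr[pos] = _BASES[b]
    out = Genome(arr.tobytes().decode(), genome.topology, genome.name + "+planted")
    return out, realised


@dataclass
class Fixture:
    genome: Genome
    stats: RepeatStats
    spec: FixtureSpec
    planted_truth: dict = field(default_factory=dict)


def _expected_extremes(spec: FixtureSpec):
    l_rep = l_int = l_tri = 0
    for el in spec.elements:
        l_rep = max(l_rep, *el.lengths)
        if el.kind == "interleaved_pair":
            l_int = max(l_int, min(el.lengths))
        if el.kind == "triple":
            l_tri = max(l_tri, el.lengths[0])
    return l_rep, l_int, l_tri


def make_fixture(spec: FixtureSpec, max_tries: int = 40) -> Fixture:
    """Generate, plant and verify; rejection-resample until the planted
    elements are the extremal repeats and background stays under the cap."""
    cap = spec.background_cap()
    exp_rep, exp_int, exp_tri = _expected_extremes(spec)
    last = None
    for attempt in range(max_tries):
        sub = (spec.seed + 7919 * attempt) % (2**31)
        g = random_genome(spec.G, sub)
        g, realised = _plant_with_positions(
            g, FixtureSpec(spec.G, sub, spec.elements, spec.max_background_repeat)
        )
        stats = compute_stats(g)
        ok = True
        ok &= stats.l_repeat == exp_rep if exp_rep else stats.l_repeat <= cap
        if exp_int:
            ok &= stats.l_interleaved == exp_int
        ok &= stats.l_triple == exp_tri if exp_tri else stats.l_triple <= cap
        # background cap: long repeats must all be planted copy pairs
        planted_rows = set()
        for el, starts in zip(spec.elements, realised):
            by_rep: dict[int, list[int]] = {}
            for (ri, _), t in zip(_copy_layout(el), starts):
                by_rep.setdefault(ri, []).append(t)
            for ss in by_rep.values():
                ss = sorted(ss)
                for i in range(len(ss)):
                    for j in range(i + 1, len(ss)):
                        planted_rows.add((ss[i], ss[j]))
        if ok and len(stats.pairs):
            long_rows = stats.pairs[stats.pairs[:, 2] > cap]
            for t1, t2, m in long_rows:
                if (int(t1), int(t2)) not in planted_rows:
                    ok = False
                    break
        if ok:
            return Fixture(
                genome=g,
                stats=stats,
                spec=spec,
                planted_truth={
                    "elements": [
                        {
                            "kind": el.kind,
                            "lengths": list(el.lengths),
                            "positions": starts,
                        }
                        for el, starts in zip(spec.elements, realised)
                    ],
                    "seed_used": sub,
                },
            )
        last = stats
    raise RuntimeError(
        f"fixture generation failed after {max_tries} tries "
        f"(last extremes: {last.l_repeat}, {last.l_interleaved}, {last.l_triple})"
    )


def make_confusable(genome: Genome, pair=None) -> Genome:
    """The swapped sequence s' of Ukkonen's interleaved-repeat ambiguity.

    With repeats X (copies t1, t3) and Y (copies t2, t4), t1<t2<t3<t4, the
    segment between X-copy-1 and Y-copy-1 is exchanged with the segment
    between X-copy-2 and Y-copy-2.  s' has the same k-mer multiset as s for
    every k <= length(pair) + 1, the same length, and differs from s.
    """
    if pair is None:
        stats = compute_stats(genome)
        best = None
        for ip in stats.interleaved_pairs():
            if best is None or ip.length > best.length:
                best = ip
        if best is None:
            raise ValueError("genome has no interleaved repeat pair")
        pair = best
    ra, rb = pair.repeat_a, pair.repeat_b
    starts = sorted(
        [(t, 0) for t in ra.copy_positions] + [(t, 1) for t in rb.copy_positions]
    )
    order = [w for _, w in starts]
    if order not in ([0, 1, 0, 1], [1, 0, 1, 0]):
        raise ValueError("repeats are not interleaved")
    t1, t2, t3, t4 = (t for t, _ in starts)
    lx = (ra if order[0] == 0 else rb).length
    ly = (rb if order[0] == 0 else ra).length
    s = genome.sequence
    if not (t1 + lx <= t2 and t2 + ly <= t3 and t3 + lx <= t4 and t4 + ly <= len(s)):
        raise ValueError("copies overlap or wrap; cannot swap")
    swapped = (
        s[: t1 + lx]
        + s[t3 + lx : t4]  # segment Z
        + s[t2 : t3 + lx]  # Y1, V, X2 unchanged
        + s[t1 + lx : t2]  # segment U
        + s[t4:]
    )
    assert len(swapped) == len(s)
    return Genome(swapped, genome.topology, genome.name + "+swapped")


# ---------------------------------------------------------------------------
# canned regimes used across the test-suite and the validation pipeline
# ---------------------------------------------------------------------------


def interleaved_dominant_fixture(G: int, seed: int, l_int=None, l_tri=None) -> Fixture:
    """A genome in the regime where the longest interleaved pair dominates
    the longest triple repeat (the common case in sequenced genomes)."""
    cap = int(2 * math.log(G, 4)) + 8
    if l_int is None:
        l_int = max(4 * cap, G // 350)
    if l_tri is None:
        l_tri = max(cap + 4, l_int // 8)
    spec = FixtureSpec(
        G,
        seed,
        elements=(
            PlantElement("interleaved_pair", (l_int, int(l_int * 1.15))),
            PlantElement("triple", (l_tri,)),
        ),
    )
    return make_fixture(spec)


def triple_dominant_fixture(G: int, seed: int) -> Fixture:
    """The opposite regime: the longest triple repeat dominates."""
    cap = int(2 * math.log(G, 4)) + 8
    l_tri = max(6 * cap, G // 300)
    l_int = max(cap + 4, l_tri // 4)
    spec = FixtureSpec(
        G,
        seed,
        elements=(
            PlantElement("triple", (l_tri,)),
            PlantElement("interleaved_pair", (l_int, int(l_int * 1.2))),
        ),
    )
    return make_fixture(spec)
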