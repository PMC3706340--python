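"""Repeat statistics of a genome.

The feasibility analysis consumes three *sufficient statistics* of the target
sequence:

``a[m]``
    number of maximal repeats of length ``m`` — position pairs ``(t1, t2)``
    spelling the same length-``m`` string with differing left flanks and
    differing right flanks.  A substring occurring ``f`` times contributes
    ``C(f, 2)`` such pairs.
``b[(m, n)]``
    number of interleaved pairs of repeats with (sorted) lengths ``m <= n``;
    two repeats are interleaved when their four copy starts alternate around
    the genome.  The length of the pair is ``m``, the shorter of the two.
``c[m]``
    number of triple repeats of length ``m`` — position triples spelling the
    same string such that the three left flanks are not all equal and the
    three right flanks are not all equal.  ``f`` occurrences give ``C(f, 3)``.

From these, ``l_repeat``, ``l_interleaved`` and ``l_triple`` are the longest
lengths with a nonzero count, and ``L_crit = max(l_interleaved, l_triple) + 1``
is the read length below which complete reconstruction is impossible at any
coverage depth.

Counts ``a`` and ``c`` are exact at every length: they are accumulated over
the LCP-interval tree of the (doubled, for circular genomes) sequence using
inclusion-exclusion over flank classes, without materialising the pairs.
Explicit occurrence lists — needed for the interleaving table and for
read-bridging checks — are enumerated only down to ``min_enum_length``
(all lengths by default for genomes up to ``EXACT_ENUM_G``).  A naive
substring-grouping enumerator with identical semantics lives in
:mod:`debridge.bruteforce` and serves as an independent validation oracle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np

from .genome import Genome

# Full occurrence enumeration down to length 1 is the default up to this size.
EXACT_ENUM_G = 600

_CODE = {c: i for i, c in enumerate("ACGT")}


class RepeatOccurrence(NamedTuple):
    """A maximal repeat (2 copies) or triple repeat (3 copies)."""

    length: int
    copy_positions: tuple

    @property
    def start(self) -> int:
        return self.copy_positions[0]


class InterleavedPair(NamedTuple):
    """Two repeats whose copy starts alternate; length = the shorter one's."""

    repeat_a: RepeatOccurrence
    repeat_b: RepeatOccurrence

    @property
    def length(self) -> int:
        return min(self.repeat_a.length, self.repeat_b.length)


# ---------------------------------------------------------------------------
# suffix array / LCP
# ---------------------------------------------------------------------------


def suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (numpy lexsort); O(n log^2 n)."""
    codes = np.asarray(codes, dtype=np.int64)
    n = len(codes)
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = codes.copy()
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r_o, k_o = rank[order], key2[order]
        bump = np.empty(n, dtype=np.int64)
        bump[0] = 0
        bump[1:] = (r_o[1:] != r_o[:-1]) | (k_o[1:] != k_o[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(bump)
        rank = new_rank
        if rank[order[-1]] == n - 1 or k >= n:
            return order.astype(np.int64)
        k *= 2


def lcp_array(codes: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Kasai LCP: lcp[i] = longest common prefix of suffixes sa[i-1], sa[i]."""
    n = len(codes)
    seq = bytes(int(c) for c in codes)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = int(sa[r - 1])
            while i + h < n and j + h < n and seq[i + h] == seq[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


# ---------------------------------------------------------------------------
# LCP-interval scan: exact counts + occurrence enumeration
# ---------------------------------------------------------------------------


def _comb2(x):
    return x * (x - 1) // 2


def _comb3(x):
    return x * (x - 1) * (x - 2) // 6


class _ScanResult(NamedTuple):
    a: dict
    c: dict
    pairs: np.ndarray  # (P, 3): t1 < t2, length
    triples: np.ndarray  # (T, 4): t1 < t2 < t3, length
    excluded_long: bool


def _emit_pairs(pos, cid, prev, depth, out):
    f = len(pos)
    iu, ju = np.triu_indices(f, 1)
    mask = (cid[iu] != cid[ju]) & (prev[iu] != prev[ju])
    if not mask.any():
        return
    t1, t2 = pos[iu[mask]], pos[ju[mask]]
    lo, hi = np.minimum(t1, t2), np.maximum(t1, t2)
    out.append(np.column_stack([lo, hi, np.full(len(lo), depth, dtype=np.int64)]))


def _emit_triples(pos, cid, prev, depth, out):
    f = len(pos)
    if f < 3:
        return
    idx = np.arange(f)
    if f <= 220:
        i, j, k = np.meshgrid(idx, idx, idx, indexing="ij", sparse=True)
        keep = (i < j) & (j < k)
        keep &= ~((cid[i] == cid[j]) & (cid[j] == cid[k]))
        keep &= ~((prev[i] == prev[j]) & (prev[j] == prev[k]))
        ii, jj, kk = np.nonzero(keep)
    else:  # chunked fallback for very fat nodes
        parts = []
        for a0 in range(f - 2):
            j2, k2 = np.meshgrid(idx, idx, indexing="ij", sparse=True)
            keep = (j2 > a0) & (k2 > j2)
            keep &= ~((cid[a0] == cid[j2]) & (cid[j2] == cid[k2]))
            keep &= ~((prev[a0] == prev[j2]) & (prev[j2] == prev[k2]))
            jj2, kk2 = np.nonzero(keep)
            parts.append((np.full(len(jj2), a0), jj2, kk2))
        if not parts:
            return
        ii = np.concatenate([p[0] for p in parts])
        jj = np.concatenate([p[1] for p in parts])
        kk = np.concatenate([p[2] for p in parts])
    if len(ii) == 0:
        return
    trip = np.sort(np.column_stack([pos[ii], pos[jj], pos[kk]]), axis=1)
    out.append(
        np.column_stack([trip, np.full(len(trip), depth, dtype=np.int64)])
    )


def _interval_scan(codes, prev_class, eligible, max_len, min_enum_len):
    """Bottom-up traversal of the LCP-interval tree.

    Each tree node of string depth ``d`` groups the occurrences of a repeated
    substring of length ``d``; its children partition the occurrences by the
    character that follows (the right flank), while ``prev_class`` carries the
    left flank.  Maximal pairs/triples are counted per node by
    inclusion-exclusion over the two flank partitions.
    """
    n = len(codes)
    sa = suffix_array(codes)
    lcp = lcp_array(codes, sa)

    a_counts: dict = {}
    c_counts: dict = {}
    pair_out: list = []
    trip_out: list = []
    excluded = False

    # child summary: (size, prevvec[5], positions list or None)
    def leaf(t):
        if not eligible[t]:
            return (0, None, [])
        vec = np.zeros(5, dtype=np.int64)
        vec[prev_class[t]] = 1
        return (1, vec, [t])

    def finalize(depth, children):
        nonlocal excluded
        sizes = [c[0] for c in children]
        f = sum(sizes)
        keep_pos = depth >= min_enum_len
        if f >= 2 and 1 <= depth:
            same_child_pairs = sum(_comb2(s) for s in sizes)
            cross2 = _comb2(f) - same_child_pairs
            if depth > max_len:
                if cross2 > 0:
                    excluded = True
            else:
                vecs = [c[1] for c in children if c[0] > 0]
                tot = np.sum(vecs, axis=0) if vecs else np.zeros(5, dtype=np.int64)
                n_a = cross2 - sum(int(_comb2(x)) for x in tot) + sum(
                    int(_comb2(x)) for v in vecs for x in v
                )
                if n_a:
                    a_counts[depth] = a_counts.get(depth, 0) + int(n_a)
                if f >= 3:
                    n_c = (
                        _comb3(f)
                        - sum(_comb3(s) for s in sizes)
                        - sum(int(_comb3(x)) for x in tot)
                        + sum(int(_comb3(x)) for v in vecs for x in v)
                    )
                    if n_c:
                        c_counts[depth] = c_counts.get(depth, 0) + int(n_c)
                if keep_pos and f >= 2:
                    pos_list, cid_list = [], []
                    for ci, ch in enumerate(children):
                        if ch[0]:
                            pos_list.extend(ch[2])
                            cid_list.extend([ci] * ch[0])
                    pos = np.asarray(pos_list, dtype=np.int64)
                    cid = np.asarray(cid_list, dtype=np.int64)
                    prv = prev_class[pos]
                    _emit_pairs(pos, cid, prv, depth, pair_out)
                    _emit_triples(pos, cid, prv, depth, trip_out)
        # merged summary for the parent
        if f == 0:
            return (0, None, [])
        vecs = [c[1] for c in children if c[0] > 0]
        vec = np.sum(vecs, axis=0)
        if keep_pos:
            merged = []
            for ch in children:
                if ch[0]:
                    merged.extend(ch[2])
        else:
            merged = []
        return (f, vec, merged)

    # stack of [depth, children]
    stack = [[0, []]]
    for i in range(1, n + 1):
        ell = int(lcp[i]) if i < n else 0
        last = leaf(int(sa[i - 1]))
        while stack[-1][0] > ell:
            depth, children = stack.pop()
            children.append(last)
            last = finalize(depth, children)
        if stack[-1][0] == ell:
            stack[-1][1].append(last)
        else:
            stack.append([ell, [last]])
    depth, children = stack.pop()
    assert depth == 0 and not stack
    finalize(0, children)

    pairs = (
        np.concatenate(pair_out) if pair_out else np.empty((0, 3), dtype=np.int64)
    )
    triples = (
        np.concatenate(trip_out) if trip_out else np.empty((0, 4), dtype=np.int64)
    )
    return _ScanResult(a_counts, c_counts, pairs, triples, excluded)


def _encode(genome: Genome):
    """codes / prev-class / eligibility arrays for the interval scan."""
    G = len(genome)
    s = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int64)
    for ch, i in _CODE.items():
        lut[ord(ch)] = i
    base = lut[s]
    if genome.circular:
        codes = np.concatenate([base, base])
        n = 2 * G
        prev = np.empty(n, dtype=np.int64)
        prev[1:] = codes[: n - 1]
        prev[0] = codes[n - 1]
        eligible = np.zeros(n, dtype=bool)
        eligible[:G] = True
        max_len = (G - 1) // 2
    else:
        codes = np.concatenate([base, [4]])  # sentinel terminator
        n = G + 1
        prev = np.empty(n, dtype=np.int64)
        prev[1:] = codes[: n - 1]
        prev[0] = 4  # boundary flank: unique sentinel class
        eligible = np.ones(n, dtype=bool)
        eligible[G] = False
        max_len = G - 1
    return codes, prev, eligible, max_len


def default_min_enum_length(G: int) -> int:
    """Default shortest length for which occurrences are materialised."""
    if G <= EXACT_ENUM_G:
        return 1
    return max(2, int(2 * math.log(G, 4)) - 3)


def _scan(genome: Genome, min_enum_length: int | None):
    if min_enum_length is None:
        min_enum_length = default_min_enum_length(len(genome))
    codes, prev, eligible, max_len = _encode(genome)
    res = _interval_scan(codes, prev, eligible, max_len, min_enum_length)
    return res, min_enum_length


def find_maximal_repeats(
    genome: Genome, min_length: int = 1
) -> list[RepeatOccurrence]:
    """All maximal repeats (2-copy occurrences) of length >= ``min_length``."""
    if len(genome) < 2:
        raise ValueError("genome too short")
    res, _ = _scan(genome, min_length)
    return [
        RepeatOccurrence(int(r[2]), (int(r[0]), int(r[1]))) for r in res.pairs
    ]


def find_triple_repeats(
    genome: Genome, min_length: int = 1
) -> list[RepeatOccurrence]:
    """All triple repeats (3-copy occurrences) of length >= ``min_length``."""
    if len(genome) < 3:
        raise ValueError("genome too short")
    res, _ = _scan(genome, min_length)
    return [
        RepeatOccurrence(int(r[3]), (int(r[0]), int(r[1]), int(r[2])))
        for r in res.triples
    ]


# ---------------------------------------------------------------------------
# interleaving
# ---------------------------------------------------------------------------


def _interleaved_index_pairs(pairs: np.ndarray, cap: int):
    """Index pairs (i, j) of interleaved repeats among ``pairs`` rows.

    Two repeats with sorted copy starts (p, q) and (u, v) are interleaved iff
    exactly one of u, v lies strictly between p and q — the four starts then
    alternate around the (circular or linear) genome.  Repeats sharing a copy
    start are never interleaved.  Rows are considered in decreasing length
    order and at most ``cap`` of them enter the quadratic test.
    """
    P = len(pairs)
    order = np.argsort(-pairs[:, 2], kind="stable")
    capped = P > cap
    sel = order[:cap]
    sub = pairs[sel]
    out_i, out_j = [], []
    m = len(sub)
    chunk = max(1, int(4e6) // max(m, 1))
    for s0 in range(0, m, chunk):
        s1 = min(m, s0 + chunk)
        p = sub[s0:s1, 0][:, None]
        q = sub[s0:s1, 1][:, None]
        u = sub[None, :, 0]
        v = sub[None, :, 1]
        inside_u = (p < u) & (u < q)
        inside_v = (p < v) & (v < q)
        inter = inside_u ^ inside_v
        distinct = (p != u) & (p != v) & (q != u) & (q != v)
        mask = inter & distinct
        ii, jj = np.nonzero(mask)
        ii = ii + s0
        keep = ii < jj  # each unordered pair once
        out_i.append(ii[keep])
        out_j.append(jj[keep])
    ii = np.concatenate(out_i) if out_i else np.empty(0, dtype=np.int64)
    jj = np.concatenate(out_j) if out_j else np.empty(0, dtype=np.int64)
    return sel[ii], sel[jj], capped


def find_interleaved_pairs(
    repeats: list[RepeatOccurrence], cap: int = 10_000
) -> list[InterleavedPair]:
    """All interleaved pairs among ``repeats`` (2-copy occurrences)."""
    if not repeats:
        return []
    arr = np.array(
        [(r.copy_positions[0], r.copy_positions[1], r.length) for r in repeats],
        dtype=np.int64,
    )
    ii, jj, _ = _interleaved_index_pairs(arr, cap)
    return [InterleavedPair(repeats[int(i)], repeats[int(j)]) for i, j in zip(ii, jj)]


# ---------------------------------------------------------------------------
# aggregated statistics
# ---------------------------------------------------------------------------


@dataclass
class RepeatStats:
    G: int
    topology: str
    a: dict = field(default_factory=dict)
    b: dict = field(default_factory=dict)  # (m, n) m<=n -> count
    c: dict = field(default_factory=dict)
    l_repeat: int = 0
    l_interleaved: int = 0
    l_triple: int = 0
    L_crit: int = 1
    # occurrence arrays (enumerated down to min_enum_length)
    pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 3), np.int64))
    triples: np.ndarray = field(default_factory=lambda: np.empty((0, 4), np.int64))
    interleaved_i: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    interleaved_j: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    min_enum_length: int = 1
    interleaved_min_length: int = 1
    exact_enumeration: bool = True
    interleaved_capped: bool = False
    excluded_long_repeats: bool = False

    @property
    def truncated(self) -> bool:
        return (not self.exact_enumeration) or self.interleaved_capped

    def repeat_occurrences(self) -> Iterator[RepeatOccurrence]:
        for t1, t2, m in self.pairs:
            yield RepeatOccurrence(int(m), (int(t1), int(t2)))

    def triple_occurrences(self) -> Iterator[RepeatOccurrence]:
        for t1, t2, t3, m in self.triples:
            yield RepeatOccurrence(int(m), (int(t1), int(t2), int(t3)))

    def interleaved_pairs(self) -> Iterator[InterleavedPair]:
        for i, j in zip(self.interleaved_i, self.interleaved_j):
            r1, r2 = self.pairs[int(i)], self.pairs[int(j)]
            yield InterleavedPair(
                RepeatOccurrence(int(r1[2]), (int(r1[0]), int(r1[1]))),
                RepeatOccurrence(int(r2[2]), (int(r2[0]), int(r2[1]))),
            )

    # -- serialisation ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "G": self.G,
            "topology": self.topology,
            "a": {str(k): v for k, v in sorted(self.a.items())},
            "b": [[int(m), int(n), int(v)] for (m, n), v in sorted(self.b.items())],
            "c": {str(k): v for k, v in sorted(self.c.items())},
            "l_repeat": self.l_repeat,
            "l_interleaved": self.l_interleaved,
            "l_triple": self.l_triple,
            "L_crit": self.L_crit,
            "truncated": self.truncated,
            "min_enum_length": self.min_enum_length,
            "excluded_long_repeats": self.excluded_long_repeats,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RepeatStats":
        doc = json.loads(text)
        return cls(
            G=doc["G"],
            topology=doc["topology"],
            a={int(k): v for k, v in doc["a"].items()},
            b={(m, n): v for m, n, v in doc["b"]},
            c={int(k): v for k, v in doc["c"].items()},
            l_repeat=doc["l_repeat"],
            l_interleaved=doc["l_interleaved"],
            l_triple=doc["l_triple"],
            L_crit=doc["L_crit"],
            min_enum_length=doc.get("min_enum_length", 1),
            exact_enumeration=not doc.get("truncated", False),
            excluded_long_repeats=doc.get("excluded_long_repeats", False),
        )

    def spectrum_rows(self):
        """(length, a_length, log(1 + a_length)) rows for the repeat spectrum."""
        return [
            (m, n, math.log1p(n)) for m, n in sorted(self.a.items())
        ]


def compute_stats(
    genome: Genome,
    min_enum_length: int | None = None,
    interleaved_cap: int = 10_000,
    interleaved_min_length: int | None = None,
) -> RepeatStats:
    """Extract the full repeat statistics of ``genome``.

    ``a`` and ``c`` counts are exact at every length.  Occurrence lists (and
    hence the ``b`` table) cover lengths >= ``min_enum_length``
    (:func:`default_min_enum_length` when None) and at most
    ``interleaved_cap`` longest repeats enter the interleaving test.

    ``interleaved_min_length`` floors the repeat length entering the ``b``
    table (default: 1 up to G = 120, else 2): the number of interleaved pairs
    of single-base repeats grows like G^4 while their weight in every
    feasibility formula is negligible.
    """
    res, used_min = _scan(genome, min_enum_length)
    a, c = res.a, res.c
    l_repeat = max(a) if a else 0
    l_triple = max(c) if c else 0

    if interleaved_min_length is None:
        interleaved_min_length = 1 if len(genome) <= 120 else 2
    interleaved_min_length = max(interleaved_min_length, used_min)
    cand_idx = np.nonzero(res.pairs[:, 2] >= interleaved_min_length)[0]
    ii, jj, capped = _interleaved_index_pairs(res.pairs[cand_idx], interleaved_cap)
    ii, jj = cand_idx[ii], cand_idx[jj]
    b: dict = {}
    l_inter = 0
    if len(ii):
        la = res.pairs[ii, 2]
        lb = res.pairs[jj, 2]
        mm = np.minimum(la, lb)
        nn = np.maximum(la, lb)
        l_inter = int(mm.max())
        for m, n in zip(mm.tolist(), nn.tolist()):
            b[(m, n)] = b.get((m, n), 0) + 1

    return RepeatStats(
        G=len(genome),
        topology=genome.topology,
        a=a,
        b=b,
        c=c,
        l_repeat=int(l_repeat),
        l_interleaved=l_inter,
        l_triple=int(l_triple),
        L_crit=max(l_inter, int(l_triple)) + 1,
        pairs=res.pairs,
        triples=res.triples,
        interleaved_i=ii,
        interleaved_j=jj,
        min_enum_length=used_min,
        interleaved_min_length=interleaved_min_length,
        exact_enumeration=(used_min <= 1),
        interleaved_capped=capped,
        excluded_long_repeats=res.excluded_long,
    )
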