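"""Sequence-graph engine for K-mer based assembly.

A :class:`SequenceGraph` is a node-labelled directed multigraph.  Node labels
are DNA strings (length ``K`` in a fresh K-mer graph, longer after
condensation); an edge ``(v, q)`` with weight ``a`` asserts that the length-
``a`` suffix of ``label(v)`` equals the length-``a`` prefix of ``label(q)``,
so walks spell sequences by concatenating labels and dropping the overlapped
bases.  Edges have multiplicity one — the edge set of a fresh K-mer graph is
exactly the set of distinct (K+1)-mers observed in the reads — and each read
is *threaded* through the graph as the ordered walk of nodes it touches.

The module provides graph construction from reads, condensation (contracting
every unambiguous edge), X-node census (nodes with in- and out-degree >= 2,
the graph images of repeats), the single-base node extensions used for local
repeat resolution, the two repeat-resolution surgeries (2-X-node splitting
for SIMPLEBRIDGING; full X-node resolution for MULTIBRIDGING), Eulerian-cycle
finding with a structural uniqueness test, and GFA-1 import/export.

Self-loops count once toward the in-degree and once toward the out-degree.
All tie-breaking is lexicographic on node labels (then node id), so every
operation is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple


class NotEulerianError(ValueError):
    """Graph is disconnected or unbalanced — a coverage/overlap condition failed."""


class InconsistentBridgingError(ValueError):
    """Two reads pair the same entry edge of an X-node with different exits."""


class SequenceGraph:
    """Directed multigraph with string node labels and overlap-weighted edges."""

    def __init__(self):
        self.labels: dict[int, str] = {}
        self.edges: dict[int, tuple[int, int, int]] = {}  # eid -> (src, dst, w)
        self._out: dict[int, list[int]] = {}
        self._in: dict[int, list[int]] = {}
        self.threads: list[list[int]] = []
        self._nid = 0
        self._eid = 0

    # -- construction -------------------------------------------------------

    def add_node(self, label: str) -> int:
        nid = self._nid
        self._nid += 1
        self.labels[nid] = label
        self._out[nid] = []
        self._in[nid] = []
        return nid

    def add_edge(self, src: int, dst: int, weight: int) -> int:
        eid = self._eid
        self._eid += 1
        self.edges[eid] = (src, dst, weight)
        self._out[src].append(eid)
        self._in[dst].append(eid)
        return eid

    def remove_edge(self, eid: int) -> None:
        src, dst, _ = self.edges.pop(eid)
        self._out[src].remove(eid)
        self._in[dst].remove(eid)

    def remove_node(self, nid: int) -> None:
        if self._out[nid] or self._in[nid]:
            raise ValueError("node still has incident edges")
        del self.labels[nid], self._out[nid], self._in[nid]

    def redirect_edge(self, eid, src=None, dst=None, weight=None) -> None:
        s, d, w = self.edges[eid]
        if src is not None and src != s:
            self._out[s].remove(eid)
            self._out[src].append(eid)
            s = src
        if dst is not None and dst != d:
            self._in[d].remove(eid)
            self._in[dst].append(eid)
            d = dst
        if weight is not None:
            w = weight
        self.edges[eid] = (s, d, w)

    # -- queries ------------------------------------------------------------

    def out_edges(self, v: int) -> list[int]:
        return self._out[v]

    def in_edges(self, v: int) -> list[int]:
        return self._in[v]

    def out_degree(self, v: int) -> int:
        return len(self._out[v])

    def in_degree(self, v: int) -> int:
        return len(self._in[v])

    def find_edge(self, u: int, v: int) -> int | None:
        """The unique edge u -> v, or None; raises on parallel edges."""
        hits = [e for e in self._out[u] if self.edges[e][1] == v]
        if not hits:
            return None
        if len(hits) > 1:
            raise InconsistentBridgingError(
                f"parallel edges between nodes {u} and {v}"
            )
        return hits[0]

    def n_nodes(self) -> int:
        return len(self.labels)

    def n_edges(self) -> int:
        return len(self.edges)

    def check_overlaps(self) -> None:
        """Assert the suffix/prefix invariant of every edge (slow; tests)."""
        for s, d, w in self.edges.values():
            ls, ld = self.labels[s], self.labels[d]
            if w > 0 and (ls[-w:] != ld[:w] or w > len(ls) or w > len(ld)):
                raise AssertionError(f"edge overlap invariant violated: {s}->{d}")


# ---------------------------------------------------------------------------
# construction from reads
# ---------------------------------------------------------------------------


def build_kmer_graph(reads: list[str], K: int) -> SequenceGraph:
    """K-mer graph of a read set: one node per distinct K-mer, one edge (of
    weight K-1) per distinct (K+1)-mer, one thread per read."""
    if not reads:
        raise ValueError("no reads")
    if any(len(r) < K + 1 for r in reads):
        raise ValueError("need K < read length (no adjacency possible)")
    g = SequenceGraph()
    by_label: dict[str, int] = {}
    seen_edges: dict[tuple[int, int], int] = {}
    for read in reads:
        thread = []
        prev = None
        for i in range(len(read) - K + 1):
            kmer = read[i : i + K]
            nid = by_label.get(kmer)
            if nid is None:
                nid = g.add_node(kmer)
                by_label[kmer] = nid
            thread.append(nid)
            if prev is not None and (prev, nid) not in seen_edges:
                seen_edges[(prev, nid)] = g.add_edge(prev, nid, K - 1)
            prev = nid
        g.threads.append(thread)
    return g


# ---------------------------------------------------------------------------
# condensation
# ---------------------------------------------------------------------------


def condense(g: SequenceGraph) -> SequenceGraph:
    """Contract every edge (v, q) with out-degree(v) = in-degree(q) = 1 and
    v != q, merging labels with their overlap, until none remains.

    Implemented as a single pass over maximal unambiguous chains, which is
    confluent: the result does not depend on contraction order.  A cycle all
    of whose edges are contractible collapses to one node with a self-loop
    (the lexicographically smallest label starts the merged node).  Read
    threads are remapped in place.  Returns ``g`` (modified in place).
    """
    nxt: dict[int, int] = {}  # u -> eid of the contractible edge leaving u
    for u, outs in g._out.items():
        if len(outs) != 1:
            continue
        eid = outs[0]
        _, v, _ = g.edges[eid]
        if v != u and g.in_degree(v) == 1:
            nxt[u] = eid

    has_contractible_in = {g.edges[e][1] for e in nxt.values()}
    contracted_pairs: set[tuple[int, int]] = set()
    node_map: dict[int, int] = {}
    chains: list[list[int]] = []

    # head-started chains
    for u in list(nxt):
        if u in has_contractible_in:
            continue
        chain = [u]
        while chain[-1] in nxt:
            chain.append(g.edges[nxt[chain[-1]]][1])
        chains.append(chain)
    consumed = {n for ch in chains for n in ch}

    # pure cycles: every remaining nxt node sits on one
    remaining = [u for u in nxt if u not in consumed]
    seen = set()
    for u in sorted(remaining, key=lambda n: (g.labels[n], n)):
        if u in seen:
            continue
        cyc = [u]
        seen.add(u)
        v = g.edges[nxt[u]][1]
        while v != u:
            cyc.append(v)
            seen.add(v)
            v = g.edges[nxt[v]][1]
        chains.append(cyc)

    for chain in chains:
        if len(chain) < 2:
            continue
        label_parts = [g.labels[chain[0]]]
        for u in chain[:-1]:
            eid = nxt[u]
            _, v, w = g.edges[eid]
            label_parts.append(g.labels[v][w:])
            contracted_pairs.add((u, v))
        merged = g.add_node("".join(label_parts))
        for u in chain:
            node_map[u] = merged
        # contract interior edges, redirect boundary edges
        for u in chain[:-1]:
            g.remove_edge(nxt[u])
        for u in chain:
            for eid in list(g._in[u]):
                g.redirect_edge(eid, dst=merged)
            for eid in list(g._out[u]):
                g.redirect_edge(eid, src=merged)
            g.remove_node(u)

    if node_map:
        new_threads = []
        for t in g.threads:
            if not t:
                new_threads.append(t)
                continue
            out = [node_map.get(t[0], t[0])]
            for a, b in zip(t, t[1:]):
                if (a, b) in contracted_pairs:
                    continue
                out.append(node_map.get(b, b))
            new_threads.append(out)
        g.threads = new_threads
    return g


# ---------------------------------------------------------------------------
# X-nodes
# ---------------------------------------------------------------------------


class XNode(NamedTuple):
    node: int
    multiplicity: int
    is_two_x: bool
    bridged: bool
    all_bridged: bool
    witnessed_pairs: tuple  # ((in_eid, out_eid), ...)


def _witnessed_slot_pairs(g: SequenceGraph, v: int):
    """Distinct (entry edge, exit edge) pairs of reads passing through v.

    Raises :class:`InconsistentBridgingError` if one entry edge is paired
    with two different exit edges (or vice versa).
    """
    pairs = {}
    for t in g.threads:
        for i in range(1, len(t) - 1):
            if t[i] != v:
                continue
            e_in = g.find_edge(t[i - 1], v)
            e_out = g.find_edge(v, t[i + 1])
            if e_in is None or e_out is None:
                raise InconsistentBridgingError("thread walks a missing edge")
            if pairs.get(e_in, e_out) != e_out:
                raise InconsistentBridgingError(
                    f"entry edge {e_in} of node {v} paired with two exits"
                )
            pairs[e_in] = e_out
    rev = {}
    for e_in, e_out in pairs.items():
        if rev.setdefault(e_out, e_in) != e_in:
            raise InconsistentBridgingError(
                f"exit edge {e_out} of node {v} paired with two entries"
            )
    return tuple(sorted(pairs.items()))


def find_x_nodes(g: SequenceGraph) -> list[XNode]:
    """Nodes with in- and out-degree >= 2 (self-loops count once per side).

    Bridging flags come from the read threads: a copy (traversal) of the node
    is bridged iff some read enters *and* exits the node, i.e. the thread
    shows the node at an interior position.
    """
    out = []
    for v in sorted(g.labels, key=lambda n: (g.labels[n], n)):
        indeg, outdeg = g.in_degree(v), g.out_degree(v)
        if indeg < 2 or outdeg < 2:
            continue
        pairs = _witnessed_slot_pairs(g, v)
        out.append(
            XNode(
                node=v,
                multiplicity=indeg,
                is_two_x=(indeg == 2 and outdeg == 2),
                bridged=len(pairs) > 0,
                all_bridged=len(pairs) == indeg,
                witnessed_pairs=pairs,
            )
        )
    return out


# ---------------------------------------------------------------------------
# node extension
# ---------------------------------------------------------------------------


def extend_right(g: SequenceGraph, v: int, q: int) -> str:
    """Label of v extended one base to the right along the edge (v, q)."""
    eid = g.find_edge(v, q)
    if eid is None:
        raise ValueError(f"no edge {v} -> {q}")
    a = g.edges[eid][2]
    return g.labels[v] + g.labels[q][a]


def extend_left(g: SequenceGraph, p: int, v: int) -> str:
    """Label of v extended one base to the left along the edge (p, v)."""
    eid = g.find_edge(p, v)
    if eid is None:
        raise ValueError(f"no edge {p} -> {v}")
    a = g.edges[eid][2]
    lp = g.labels[p]
    return lp[len(lp) - a - 1] + g.labels[v]


# ---------------------------------------------------------------------------
# repeat-resolution surgeries
# ---------------------------------------------------------------------------


def _remap_threads_for_split(g, v, in_copy, out_copy, default):
    """Rewrite thread occurrences of ``v`` using pre-surgery edge lookups.

    ``in_copy``/``out_copy`` map edge ids to replacement node walks (lists).
    """
    new_threads = []
    for t in g.threads:
        if v not in t:
            new_threads.append(t)
            continue
        out = []
        for i, node in enumerate(t):
            if node != v:
                out.append(node)
                continue
            e_in = t_in = None
            if i > 0:
                t_in = (t[i - 1], v)
            if i + 1 < len(t):
                e_in = (v, t[i + 1])
            if t_in is not None and t_in in in_copy:
                out.extend(in_copy[t_in])
            elif e_in is not None and e_in in out_copy:
                out.extend(out_copy[e_in])
            else:
                out.extend(default)
        new_threads.append(out)
    g.threads = new_threads


def split_bridged_two_x_node(g: SequenceGraph, xn: XNode) -> None:
    """SIMPLEBRIDGING surgery: duplicate a bridged 2-X-node.

    The bridging read pairs one entry edge with one exit edge; the first copy
    inherits that pair, the second inherits the remaining pair.  Works for
    self-loops too: the self-loop's entry and exit slots may land on
    different copies, turning it into an ordinary edge between them.
    """
    v = xn.node
    ins, outs = list(g.in_edges(v)), list(g.out_edges(v))
    if not (len(ins) == 2 and len(outs) == 2):
        raise ValueError("not a 2-X-node")
    if not xn.witnessed_pairs:
        raise ValueError("2-X-node is not bridged")
    e_in_b, e_out_b = xn.witnessed_pairs[0]
    if e_in_b == e_out_b:
        raise InconsistentBridgingError("self-loop paired with itself")
    e_in_o = next(e for e in ins if e != e_in_b)
    e_out_o = next(e for e in outs if e != e_out_b)

    # pre-surgery lookup tables keyed by node pairs, for thread remapping
    def pair_key(eid):
        s, d, _ = g.edges[eid]
        return (s, d)

    v1, v2 = g.add_node(g.labels[v]), g.add_node(g.labels[v])
    in_of = {e_in_b: v1, e_in_o: v2}
    out_of = {e_out_b: v1, e_out_o: v2}
    in_copy = {pair_key(e): [n] for e, n in in_of.items()}
    out_copy = {pair_key(e): [n] for e, n in out_of.items()}
    # a thread segment [.., a, v, b, ..] must map entry and exit to the same
    # copy, unless the traversal crosses the (split) self-loop
    _remap_threads_for_split(g, v, in_copy, out_copy, [v1])

    for eid in set(ins + outs):
        src = dst = None
        if eid in in_of:
            dst = in_of[eid]
        if eid in out_of:
            src = out_of[eid]
        g.redirect_edge(eid, src=src, dst=dst)
    g.remove_node(v)


class _SkipResolution(Exception):
    pass


def resolve_bridged_x_node(g: SequenceGraph, xn: XNode) -> bool:
    """MULTIBRIDGING surgery: replace a bridged X-node by single-base
    extensions of its neighbours, wiring extensions together as witnessed by
    the bridging reads.

    For each entry edge (p, v) a left-extension node u = p->v is created (the
    edge's weight grows by one); symmetrically a right-extension w = v->q for
    each exit edge.  A self-loop (v, v) contributes one entry and one exit
    slot whose extensions are joined by an edge of weight a_vv + 2.  Each
    read through v adds the edge (u, w) of its witnessed (entry, exit) pair;
    if exactly one u and one w remain unpaired, they are joined.  Returns
    False (leaving the graph untouched) when more than one slot per side
    would remain unpaired or an extension is impossible.
    """
    v = xn.node
    lab = g.labels[v]
    ins = [e for e in g.in_edges(v) if g.edges[e][0] != v]
    outs = [e for e in g.out_edges(v) if g.edges[e][1] != v]
    self_eids = [e for e in g.in_edges(v) if g.edges[e][0] == v]
    if len(self_eids) > 1:
        return False
    self_eid = self_eids[0] if self_eids else None

    in_slots = ins + ([self_eid] if self_eid is not None else [])
    out_slots = outs + ([self_eid] if self_eid is not None else [])
    d = len(in_slots)
    witnessed = dict(xn.witnessed_pairs)
    unpaired_in = [e for e in in_slots if e not in witnessed]
    paired_out = set(witnessed.values())
    unpaired_out = [e for e in out_slots if e not in paired_out]
    if len(unpaired_in) > 1 or len(unpaired_out) > 1:
        return False  # not enough bridging information to resolve v

    # feasibility of every extension first, so failure leaves g untouched
    for e in ins:
        p, _, a = g.edges[e]
        if a + 1 > len(g.labels[p]):
            return False
    for e in outs:
        _, q, a = g.edges[e]
        if a + 1 > len(g.labels[q]):
            return False

    pre_pair_key = {e: (g.edges[e][0], g.edges[e][1]) for e in set(in_slots + out_slots)}

    u_of: dict[int, int] = {}
    w_of: dict[int, int] = {}
    for e in ins:
        p, _, a = g.edges[e]
        lp = g.labels[p]
        u_of[e] = g.add_node(lp[len(lp) - a - 1] + lab)
        g.redirect_edge(e, dst=u_of[e], weight=a + 1)
    for e in outs:
        _, q, a = g.edges[e]
        w_of[e] = g.add_node(lab + g.labels[q][a])
        g.redirect_edge(e, src=w_of[e], weight=a + 1)
    if self_eid is not None:
        a = g.edges[self_eid][2]
        u_self = g.add_node(lab[len(lab) - a - 1] + lab)
        w_self = g.add_node(lab + lab[a])
        u_of[self_eid] = u_self
        w_of[self_eid] = w_self
        # replacement for the self-loop: right-extension feeds left-extension
        g.remove_edge(self_eid)
        g.add_edge(w_self, u_self, a + 2)

    for e_in, e_out in witnessed.items():
        g.add_edge(u_of[e_in], w_of[e_out], len(lab))
    if len(unpaired_in) == 1 and len(unpaired_out) == 1:
        g.add_edge(u_of[unpaired_in[0]], w_of[unpaired_out[0]], len(lab))

    in_copy = {}
    out_copy = {}
    for e in in_slots:
        key = pre_pair_key[e]
        tail = [u_of[e]]
        if e in witnessed:
            tail = [u_of[e], w_of[witnessed[e]]]
        in_copy[key] = tail
    for e in out_slots:
        out_copy.setdefault(pre_pair_key[e], [w_of[e]])
    default = [u_of[in_slots[0]]] if in_slots else [w_of[out_slots[0]]]
    _remap_threads_for_split_mb(g, v, in_copy, out_copy, default)
    g.remove_node(v)
    return True


def _remap_threads_for_split_mb(g, v, in_copy, out_copy, default):
    """Thread remap for MULTIBRIDGING: an interior occurrence of ``v`` becomes
    [entry extension, exit extension]; boundary occurrences keep only the side
    they witness."""
    new_threads = []
    for t in g.threads:
        if v not in t:
            new_threads.append(t)
            continue
        out = []
        for i, node in enumerate(t):
            if node != v:
                out.append(node)
                continue
            key_in = (t[i - 1], v) if i > 0 else None
            key_out = (v, t[i + 1]) if i + 1 < len(t) else None
            if key_in is not None and key_in in in_copy:
                walk = in_copy[key_in]
                if key_out is None:
                    walk = walk[:1]  # read ends inside v: entry side only
                out.extend(walk)
            elif key_out is not None and key_out in out_copy:
                out.extend(out_copy[key_out])
            else:
                out.extend(default)
        new_threads.append(out)
    g.threads = new_threads


# ---------------------------------------------------------------------------
# Eulerian cycles
# ---------------------------------------------------------------------------


@dataclass
class EulerianResult:
    cycle: list[int]  # edge ids, in traversal order
    unique: bool
    witness: list[int] | None = None  # an alternative Eulerian cycle
    ambiguous_nodes: list[int] = field(default_factory=list)


def _check_eulerian(g: SequenceGraph) -> None:
    active = [v for v in g.labels if g.in_degree(v) or g.out_degree(v)]
    if not active:
        raise NotEulerianError("graph has no edges")
    for v in active:
        if g.in_degree(v) != g.out_degree(v):
            raise NotEulerianError(
                f"unbalanced node {v}: in {g.in_degree(v)} != out {g.out_degree(v)}"
            )
    # weak connectivity over active nodes
    seen = {active[0]}
    stack = [active[0]]
    while stack:
        u = stack.pop()
        for eid in g.out_edges(u) + g.in_edges(u):
            s, d, _ = g.edges[eid]
            for n in (s, d):
                if n not in seen:
                    seen.add(n)
                    stack.append(n)
    if len(seen) != len(active):
        raise NotEulerianError("graph is disconnected")


def eulerian_cycle(g: SequenceGraph) -> EulerianResult:
    """Find an Eulerian cycle (deterministic Hierholzer, lexicographic
    tie-breaks) and decide whether it is the *unique* Eulerian cycle.

    Uniqueness is structural: the cycle is non-unique iff some node is
    traversed three or more times (its inter-visit segments can be cyclically
    permuted) or two distinct twice-traversed nodes alternate around the
    cycle (their u->v segments can be exchanged) — the graph mirror of triple
    and interleaved repeats.  When non-unique, one alternative cycle is
    returned as a witness.
    """
    _check_eulerian(g)
    # deterministic next-edge choice: smallest (dst label, dst id, eid)
    pending = {
        v: sorted(
            g.out_edges(v),
            key=lambda e: (g.labels[g.edges[e][1]], g.edges[e][1], e),
            reverse=True,
        )
        for v in g.labels
    }
    start = min(
        (v for v in g.labels if g.out_degree(v)), key=lambda v: (g.labels[v], v)
    )
    stack = [(start, None)]
    cycle_rev: list[int] = []
    while stack:
        v, via = stack[-1]
        if pending[v]:
            eid = pending[v].pop()
            stack.append((g.edges[eid][1], eid))
        else:
            stack.pop()
            if via is not None:
                cycle_rev.append(via)
    cycle = cycle_rev[::-1]
    if len(cycle) != g.n_edges():
        raise NotEulerianError("graph is disconnected")  # defensive

    visits: dict[int, list[int]] = {}
    for idx, eid in enumerate(cycle):
        visits.setdefault(g.edges[eid][0], []).append(idx)

    multi = {v: pos for v, pos in visits.items() if len(pos) >= 2}
    # nodes traversed >= 3 times
    for v, pos in sorted(multi.items()):
        if len(pos) >= 3:
            i, j, k = pos[0], pos[1], pos[2]
            witness = cycle[:i] + cycle[j:k] + cycle[i:j] + cycle[k:]
            return EulerianResult(cycle, False, witness, [v])
    # alternating pair of twice-traversed nodes
    twice = sorted((v for v, pos in multi.items() if len(pos) == 2))
    for ai in range(len(twice)):
        for bi in range(ai + 1, len(twice)):
            u, v = twice[ai], twice[bi]
            (u1, u2), (v1, v2) = visits[u], visits[v]
            if u1 < v1 < u2 < v2 or v1 < u1 < v2 < u2:
                # exchange the two parallel segments between the alternating
                # visits (both run from the first node to the second)
                a, b, c2, d = sorted([u1, v1, u2, v2])
                witness = (
                    cycle[:a] + cycle[c2:d] + cycle[b:c2] + cycle[a:b] + cycle[d:]
                )
                return EulerianResult(cycle, False, witness, [u, v])
    return EulerianResult(cycle, True)


def spell(g: SequenceGraph, walk: list[int], circular: bool = False) -> str:
    """Spell the sequence of an edge walk.

    For an open walk the full first label is kept; for a ``circular`` walk
    (an Eulerian cycle) each edge contributes ``label(dst)`` minus the
    overlap, which yields the circular sequence (a rotation of the target).
    """
    if not walk:
        raise ValueError("empty walk (pass [node] spelling via g.labels)")
    parts = []
    prev_dst = None
    for eid in walk:
        s, d, w = g.edges[eid]
        if prev_dst is not None and s != prev_dst:
            raise ValueError("walk is not edge-contiguous")
        if prev_dst is None and not circular:
            parts.append(g.labels[s])
        parts.append(g.labels[d][w:])
        prev_dst = d
    if circular:
        s0 = g.edges[walk[0]][0]
        if prev_dst != s0:
            raise ValueError("walk is not closed")
    return "".join(parts)


# ---------------------------------------------------------------------------
# GFA v1 import/export and debug dump
# ---------------------------------------------------------------------------


def write_gfa(g: SequenceGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for nid in sorted(g.labels):
            fh.write(f"S\tn{nid}\t{g.labels[nid]}\n")
        for eid in sorted(g.edges):
            s, d, w = g.edges[eid]
            fh.write(f"L\tn{s}\t+\tn{d}\t+\t{w}M\n")


def read_gfa(path) -> SequenceGraph:
    g = SequenceGraph()
    name_to_id = {}
    links = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "S":
                name_to_id[fields[1]] = g.add_node(fields[2])
            elif fields[0] == "L":
                links.append((fields[1], fields[3], fields[5]))
    for a, b, cig in links:
        if not cig.endswith("M"):
            raise ValueError(f"unsupported overlap CIGAR {cig!r}")
        g.add_edge(name_to_id[a], name_to_id[b], int(cig[:-1]))
    return g


def debug_dump(g: SequenceGraph) -> dict:
    return {
        "nodes": {str(n): lab for n, lab in g.labels.items()},
        "edges": [
            {"id": e, "src": s, "dst": d, "overlap": w}
            for e, (s, d, w) in sorted(g.edges.items())
        ],
        "threads": g.threads,
    }
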