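"""The four reconstruction algorithms.

Each assembler takes error-free, equal-length reads (as plain strings; start
positions are never available to it) and returns an :class:`AssemblyResult`
whose status is

``unique``
    a single candidate circular sequence was determined;
``ambiguous``
    the reads are consistent with more than one sequence (an intrinsic limit,
    not an algorithmic failure) — one representative plus a witness
    alternative are returned;
``failed``
    a structural precondition broke (coverage gap, inconsistent bridging).

Sufficient conditions for ``unique`` + correct, with reads drawn from a
circular genome:

* GREEDY — every maximal repeat bridged, genome covered;
* DEBRUIJN(K) — no interleaved or triple repeat of length >= K, adjacent
  reads overlap by >= K;
* SIMPLEBRIDGING(K) — all interleaved repeats bridged, no triple repeat of
  length >= K, adjacent reads overlap by >= K;
* MULTIBRIDGING(K) — all interleaved repeats bridged, all triple repeats
  all-bridged, adjacent reads overlap by >= K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sequence_graph import (
    InconsistentBridgingError,
    NotEulerianError,
    SequenceGraph,
    build_kmer_graph,
    condense,
    eulerian_cycle,
    find_x_nodes,
    resolve_bridged_x_node,
    spell,
    split_bridged_two_x_node,
)

_SURGERY_CAP = 10_000


@dataclass
class AssemblyResult:
    status: str  # unique | ambiguous | failed
    sequence: str | None = None
    alternatives: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "unique"


# ---------------------------------------------------------------------------
# GREEDY
# ---------------------------------------------------------------------------


def _max_overlap(x: str, y: str) -> int:
    """Largest k with suffix_k(x) == prefix_k(y), k <= min(|x|, |y|).

    KMP prefix function of y + sep + x; linear in |x| + |y|.
    """
    s = y + "\x00" + x
    pi = [0] * len(s)
    k = 0
    for i in range(1, len(s)):
        while k and s[i] != s[k]:
            k = pi[k - 1]
        if s[i] == s[k]:
            k += 1
        pi[i] = k
    return pi[-1]


def _self_overlap(x: str) -> int:
    """Largest proper border of x (suffix == prefix, length < |x|)."""
    pi = [0] * len(x)
    k = 0
    for i in range(1, len(x)):
        while k and x[i] != x[k]:
            k = pi[k - 1]
        if x[i] == x[k]:
            k += 1
        pi[i] = k
    return pi[-1]


def greedy_assemble(reads: list[str]) -> AssemblyResult:
    """Repeatedly merge the two fragments with the largest suffix-prefix
    overlap until one remains, then close the circle on its own largest
    border.

    Implemented as the classic overlap-descending sweep: for w = L-1 down
    to 1, fragments whose length-w suffix equals another fragment's length-w
    prefix are merged (equal-length reads overlap by at most L-1, and merging
    never creates larger overlaps between genome fragments).  Within a sweep
    level, fragments are processed in lexicographic order and the
    lexicographically smallest matching partner is chosen, so the result is
    deterministic; the reconstruction guarantee (every repeat bridged +
    genome covered) holds for any tie-break.
    """
    if not reads:
        return AssemblyResult("failed", diagnostics={"reason": "no reads"})
    L = len(reads[0])
    if any(len(r) != L for r in reads):
        raise ValueError("reads must have equal length")
    frags = {i: r for i, r in enumerate(sorted(set(reads)))}
    merges = 0
    for w in range(L - 1, 0, -1):
        if len(frags) == 1:
            break
        # candidate targets by length-w prefix
        by_prefix: dict[str, list[int]] = {}
        for fid, s in frags.items():
            by_prefix.setdefault(s[:w], []).append(fid)
        for lst in by_prefix.values():
            lst.sort(key=lambda f: (frags[f], f))
        merged_away: set[int] = set()
        for fid in sorted(frags, key=lambda f: (frags[f], f)):
            # follow chains: keep extending the current fragment at level w
            while fid not in merged_away and len(frags) - len(merged_away) > 1:
                s = frags[fid]
                cands = by_prefix.get(s[-w:], ())
                nxt = next(
                    (c for c in cands if c != fid and c not in merged_away), None
                )
                if nxt is None:
                    break
                frags[fid] = s + frags[nxt][w:]
                merged_away.add(nxt)
                merges += 1
        for fid in merged_away:
            del frags[fid]
    if len(frags) > 1:
        return AssemblyResult(
            "failed",
            diagnostics={
                "reason": "no positive overlap remains (coverage gap)",
                "fragments": len(frags),
            },
        )
    final = next(iter(frags.values()))
    closure = _self_overlap(final)
    circ = final[: len(final) - closure]
    if len(circ) < L:
        return AssemblyResult(
            "failed", diagnostics={"reason": "closure shorter than read length"}
        )
    return AssemblyResult(
        "unique", circ, diagnostics={"closure_overlap": closure, "merges": merges}
    )


# ---------------------------------------------------------------------------
# K-mer pipeline
# ---------------------------------------------------------------------------


def _finish(g: SequenceGraph, diagnostics: dict) -> AssemblyResult:
    """Condense, then Eulerian cycle + spelling with ambiguity reporting."""
    condense(g)
    if g.n_edges() == 0 and g.n_nodes() == 1:
        # a single contig with no closing self-loop: coverage gap
        return AssemblyResult(
            "failed", diagnostics={**diagnostics, "reason": "graph has no cycle"}
        )
    try:
        res = eulerian_cycle(g)
    except NotEulerianError as exc:
        return AssemblyResult(
            "failed", diagnostics={**diagnostics, "reason": str(exc)}
        )
    seq = spell(g, res.cycle, circular=True)
    if res.unique:
        return AssemblyResult("unique", seq, diagnostics=diagnostics)
    alt = spell(g, res.witness, circular=True)
    return AssemblyResult(
        "ambiguous",
        seq,
        alternatives=[alt],
        diagnostics={
            **diagnostics,
            "reason": "Eulerian cycle is not unique",
            "ambiguous_nodes": [g.labels[v] for v in res.ambiguous_nodes],
        },
    )


def debruijn_assemble(reads: list[str], K: int) -> AssemblyResult:
    """Condensed K-mer graph + unique Eulerian cycle (no repeat resolution)."""
    g = build_kmer_graph(reads, K)
    return _finish(g, {"algorithm": "debruijn", "K": K})


def simplebridging_assemble(reads: list[str], K: int) -> AssemblyResult:
    """DEBRUIJN plus splitting of bridged 2-X-nodes.

    While some X-node of traversal multiplicity exactly two is bridged, the
    bridging read pairs its entry with its exit; the node is duplicated, one
    copy per (entry, exit) pair, and the graph recondensed.  Higher-
    multiplicity X-nodes are left to the Eulerian step (and may yield an
    ambiguous result) — that is the documented gap to MULTIBRIDGING.
    """
    g = build_kmer_graph(reads, K)
    condense(g)
    diagnostics: dict = {"algorithm": "simplebridging", "K": K, "splits": 0}
    for _ in range(_SURGERY_CAP):
        try:
            target = next(
                (
                    xn
                    for xn in find_x_nodes(g)
                    if xn.is_two_x and xn.bridged
                ),
                None,
            )
        except InconsistentBridgingError as exc:
            return AssemblyResult(
                "failed", diagnostics={**diagnostics, "reason": str(exc)}
            )
        if target is None:
            break
        try:
            split_bridged_two_x_node(g, target)
        except InconsistentBridgingError as exc:
            return AssemblyResult(
                "failed", diagnostics={**diagnostics, "reason": str(exc)}
            )
        diagnostics["splits"] += 1
        condense(g)
    else:
        return AssemblyResult(
            "failed", diagnostics={**diagnostics, "reason": "surgery cap reached"}
        )
    return _finish(g, diagnostics)


def multibridging_assemble(reads: list[str], K: int) -> AssemblyResult:
    """Full local repeat resolution by single-base node extension.

    While some X-node is bridged and resolvable (at most one entry/exit pair
    unwitnessed by reads), replace it by extensions of its neighbours wired
    per the bridging reads, recondense, repeat; finish with the Eulerian
    step.  Unresolvable X-nodes are left in place and reported in the census.
    """
    g = build_kmer_graph(reads, K)
    condense(g)
    diagnostics: dict = {"algorithm": "multibridging", "K": K, "resolutions": 0}
    skipped: set[str] = set()
    for _ in range(_SURGERY_CAP):
        try:
            census = find_x_nodes(g)
        except InconsistentBridgingError as exc:
            return AssemblyResult(
                "failed", diagnostics={**diagnostics, "reason": str(exc)}
            )
        progressed = False
        for xn in census:
            if not xn.bridged or g.labels[xn.node] in skipped:
                continue
            if resolve_bridged_x_node(g, xn):
                progressed = True
                diagnostics["resolutions"] += 1
                condense(g)
                break
            skipped.add(g.labels[xn.node])
        if not progressed:
            unresolved = [
                {
                    "label_length": len(g.labels[xn.node]),
                    "multiplicity": xn.multiplicity,
                    "bridged_copies": len(xn.witnessed_pairs),
                }
                for xn in census
            ]
            diagnostics["unresolved_x_nodes"] = unresolved
            break
    else:
        return AssemblyResult(
            "failed", diagnostics={**diagnostics, "reason": "surgery cap reached"}
        )
    return _finish(g, diagnostics)


ASSEMBLERS = {
    "greedy": lambda reads, K=None: greedy_assemble(reads),
    "debruijn": debruijn_assemble,
    "simplebridging": simplebridging_assemble,
    "multibridging": multibridging_assemble,
}
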