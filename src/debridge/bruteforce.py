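"""Exhaustive reference implementations of the repeat finders.

These enumerate repeats by grouping all substrings of each length and applying
the maximality definitions literally, with no suffix-array machinery.  They
are quadratic (cubic for triples) and exist to validate
:mod:`debridge.repeat_stats` on small genomes; the two routes share no code
beyond the :class:`~debridge.genome.Genome` container.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .genome import Genome

_SENT_LEFT = -1
_SENT_RIGHT = -2


def _flank_arrays(genome: Genome, length: int, positions: np.ndarray):
    """Left/right flank classes for copies of length ``length`` at ``positions``."""
    G = len(genome)
    s = np.frombuffer(genome.sequence.encode(), dtype=np.uint8).astype(np.int64)
    if genome.circular:
        left = s[(positions - 1) % G]
        right = s[(positions + length) % G]
    else:
        left = np.where(positions == 0, _SENT_LEFT, s[np.maximum(positions - 1, 0)])
        rpos = positions + length
        right = np.where(rpos == G, _SENT_RIGHT, s[np.minimum(rpos, G - 1)])
    return left, right


def _groups(genome: Genome, length: int):
    """Positions grouped by their length-``length`` substring."""
    G = len(genome)
    if genome.circular:
        text = genome.sequence + genome.sequence
        span = G
    else:
        text = genome.sequence
        span = G - length + 1
    groups = defaultdict(list)
    for t in range(span):
        groups[text[t : t + length]].append(t)
    return groups


def _max_length(genome: Genome) -> int:
    G = len(genome)
    return (G - 1) // 2 if genome.circular else G - 1


def brute_maximal_repeats(genome: Genome, min_length: int = 1) -> np.ndarray:
    """All maximal repeat pairs as rows (t1, t2, length), t1 < t2."""
    rows = []
    for ell in range(max(1, min_length), _max_length(genome) + 1):
        groups = _groups(genome, ell)
        any_group = False
        for pos_list in groups.values():
            if len(pos_list) < 2:
                continue
            any_group = True
            pos = np.asarray(pos_list, dtype=np.int64)
            left, right = _flank_arrays(genome, ell, pos)
            i, j = np.triu_indices(len(pos), 1)
            keep = (left[i] != left[j]) & (right[i] != right[j])
            if keep.any():
                rows.append(
                    np.column_stack(
                        [pos[i[keep]], pos[j[keep]], np.full(keep.sum(), ell)]
                    )
                )
        if not any_group:
            break
    if not rows:
        return np.empty((0, 3), dtype=np.int64)
    return np.concatenate(rows).astype(np.int64)


def brute_triple_repeats(genome: Genome, min_length: int = 1) -> np.ndarray:
    """All triple repeats as rows (t1, t2, t3, length), t1 < t2 < t3.

    Triple maximality: the three left flanks are not all equal and the three
    right flanks are not all equal.
    """
    rows = []
    for ell in range(max(1, min_length), _max_length(genome) + 1):
        groups = _groups(genome, ell)
        any_group = False
        for pos_list in groups.values():
            if len(pos_list) < 2:
                continue
            any_group = True
            if len(pos_list) < 3:
                continue
            pos = np.asarray(pos_list, dtype=np.int64)
            left, right = _flank_arrays(genome, ell, pos)
            f = len(pos)
            idx = np.arange(f)
            i, j, k = np.meshgrid(idx, idx, idx, indexing="ij", sparse=True)
            keep = (i < j) & (j < k)
            keep &= ~((left[i] == left[j]) & (left[j] == left[k]))
            keep &= ~((right[i] == right[j]) & (right[j] == right[k]))
            ii, jj, kk = np.nonzero(keep)
            if len(ii):
                rows.append(
                    np.column_stack(
                        [pos[ii], pos[jj], pos[kk], np.full(len(ii), ell)]
                    )
                )
        if not any_group:
            break
    if not rows:
        return np.empty((0, 4), dtype=np.int64)
    return np.concatenate(rows).astype(np.int64)


def brute_interleaved_table(pairs: np.ndarray) -> dict:
    """b[(m, n)] interleaving counts by a plain double loop over repeat rows."""
    table: dict = {}
    P = len(pairs)
    for x in range(P):
        p, q, lx = (int(v) for v in pairs[x])
        for y in range(x + 1, P):
            u, v, ly = (int(v) for v in pairs[y])
            if len({p, q, u, v}) < 4:
                continue
            inside = (p < u < q) + (p < v < q)
            if inside == 1:
                key = (min(lx, ly), max(lx, ly))
                table[key] = table.get(key, 0) + 1
    return table


def canonical(rows: np.ndarray) -> np.ndarray:
    """Rows sorted lexicographically, for set-equality comparison."""
    if len(rows) == 0:
        return rows
    order = np.lexsort(rows.T[::-1])
    return rows[order]
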