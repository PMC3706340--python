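"""Simulation protocol tying statistics, conditions and assemblers together.

A *trial* draws one seeded read set from a genome, runs one assembler blind
(reads only), checks the reconstruction against the truth up to circular
rotation, and separately records which theorem hypotheses held for that read
set.  Outcomes:

``unique-correct`` / ``unique-incorrect``
    the assembler committed to a single sequence (the latter must never
    happen when the corresponding hypotheses hold);
``ambiguous``
    the reads admit several sequences and the assembler said so;
``failed``
    a structural precondition broke (typically a coverage gap).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .assemblers import (
    debruijn_assemble,
    greedy_assemble,
    multibridging_assemble,
    simplebridging_assemble,
)
from .genome import Genome, rotations_equal
from .read_simulator import ConditionReport, check_conditions, sample_reads
from .repeat_stats import RepeatStats

ALGORITHM_NAMES = ("greedy", "debruijn", "simplebridging", "multibridging")


@dataclass
class TrialRecord:
    genome: str
    L: int
    N: int
    seed: int
    algorithm: str
    K: int
    conditions: dict
    conditions_hold: bool
    outcome: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def _run_assembler(algorithm: str, reads: list[str], K: int):
    if algorithm == "greedy":
        return greedy_assemble(reads)
    if algorithm == "debruijn":
        return debruijn_assemble(reads, K)
    if algorithm == "simplebridging":
        return simplebridging_assemble(reads, K)
    if algorithm == "multibridging":
        return multibridging_assemble(reads, K)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _conditions_hold(report: ConditionReport, algorithm: str) -> bool:
    return {
        "greedy": report.greedy_ok,
        "debruijn": report.debruijn_ok,
        "simplebridging": report.simplebridging_ok,
        "multibridging": report.multibridging_ok,
    }[algorithm]()


def default_K(stats: RepeatStats, algorithm: str) -> int:
    """Theorem-motivated default K: L_crit for DEBRUIJN (its conditions force
    K > max(l_interleaved, l_triple)); l_triple + 1 for the bridging
    algorithms, which handle interleaved repeats through reads."""
    if algorithm == "debruijn":
        return stats.L_crit
    return stats.l_triple + 1


def run_trial(
    genome: Genome,
    stats: RepeatStats,
    algorithm: str,
    K: int,
    L: int,
    N: int,
    seed: int,
) -> TrialRecord:
    readset = sample_reads(genome, N, L, seed)
    report = check_conditions(genome, readset, stats, K)
    result = _run_assembler(algorithm, readset.sequences(), K)
    if result.status == "unique":
        outcome = (
            "unique-correct"
            if rotations_equal(result.sequence, genome.sequence)
            else "unique-incorrect"
        )
    else:
        outcome = result.status
    return TrialRecord(
        genome=genome.name,
        L=L,
        N=N,
        seed=seed,
        algorithm=algorithm,
        K=K,
        conditions=report._asdict(),
        conditions_hold=_conditions_hold(report, algorithm),
        outcome=outcome,
    )


def simulate_trials(
    genome: Genome,
    stats: RepeatStats,
    algorithm: str,
    K: int,
    L: int,
    N: int,
    trials: int,
    seed: int,
) -> list[TrialRecord]:
    """``trials`` independent read sets, each with a child seed derived from
    the master seed; deterministic end to end."""
    child_seeds = np.random.SeedSequence(seed).generate_state(trials) % (2**31)
    return [
        run_trial(genome, stats, algorithm, K, L, N, int(s)) for s in child_seeds
    ]


def tally(records: list[TrialRecord]) -> dict:
    out = {"unique-correct": 0, "unique-incorrect": 0, "ambiguous": 0, "failed": 0}
    for r in records:
        out[r.outcome] += 1
    out["trials"] = len(records)
    out["certified"] = sum(r.conditions_hold for r in records)
    out["certified_correct"] = sum(
        r.conditions_hold and r.outcome == "unique-correct" for r in records
    )
    return out
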