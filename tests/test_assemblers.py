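"""Assembler contracts: exact reconstruction under each algorithm's
sufficient conditions, honest ambiguity reporting, and invariances."""

import random

import numpy as np
import pytest

from conftest import harness_point, make_trial_genome
from debridge.assemblers import (
    debruijn_assemble,
    greedy_assemble,
    multibridging_assemble,
    simplebridging_assemble,
)
from debridge.fixtures import (
    FixtureSpec,
    PlantElement,
    make_confusable,
    make_fixture,
    random_genome,
)
from debridge.genome import rotations_equal
from debridge.pipeline import default_K, run_trial
from debridge.read_simulator import sample_reads
from debridge.sequence_graph import build_kmer_graph, condense, find_x_nodes


def all_windows(genome, L):
    return [genome.substr(t, L) for t in range(len(genome))]


class TestGreedy:
    def test_exhaustive_windows_reconstruct_planted_repeat_genome(self):
        fx = make_fixture(FixtureSpec(400, 1, (PlantElement("pair", (24,)),)))
        L = 40  # every repeat has length <= L-2, every window present
        res = greedy_assemble(all_windows(fx.genome, L))
        assert res.status == "unique"
        assert rotations_equal(res.sequence, fx.genome.sequence)

    def test_zero_overlap_reads_fail_with_coverage_diagnostic(self):
        res = greedy_assemble(["AAAACCCC", "GGGGTTTT"])
        assert res.status == "failed"
        assert "overlap" in res.diagnostics["reason"]

    def test_read_order_invariance(self):
        g = random_genome(300, 6)
        reads = sample_reads(g, 120, 40, seed=2).sequences()
        shuffled = reads[:]
        random.Random(0).shuffle(shuffled)
        assert greedy_assemble(reads).sequence == greedy_assemble(shuffled).sequence


class TestDebruijn:
    def test_ambiguous_with_swap_witness(self, confusable_fixture):
        fx = confusable_fixture
        sw = make_confusable(fx.genome)
        res = debruijn_assemble(all_windows(fx.genome, 31), 20)
        assert res.status == "ambiguous"
        cands = [res.sequence] + res.alternatives
        assert any(rotations_equal(c, fx.genome.sequence) for c in cands)
        assert any(rotations_equal(c, sw.sequence) for c in cands)

    def test_coverage_gap_fails(self):
        g = random_genome(400, 8)
        reads = [g.substr(t, 40) for t in range(0, 180)]  # half the circle
        res = debruijn_assemble(reads, 12)
        assert res.status == "failed"


class TestSimpleBridging:
    def test_single_bridged_two_x_node_resolves_to_simple_cycle(self):
        fx = make_fixture(FixtureSpec(400, 4, (PlantElement("pair", (24,)),)))
        L, K = 40, 12
        reads = all_windows(fx.genome, L)
        # structural check: before surgery there is exactly one 2-X-node
        g = build_kmer_graph(reads, K)
        condense(g)
        assert sum(x.is_two_x for x in find_x_nodes(g)) == 1
        res = simplebridging_assemble(reads, K)
        assert res.status == "unique"
        assert rotations_equal(res.sequence, fx.genome.sequence)
        assert res.diagnostics["splits"] == 1

    def test_unbridged_interleaved_pair_reports_ambiguous(self, confusable_fixture):
        res = simplebridging_assemble(all_windows(confusable_fixture.genome, 31), 20)
        assert res.status == "ambiguous"


class TestMultiBridging:
    def test_all_bridged_triple_resolves(self):
        fx = make_fixture(FixtureSpec(500, 5, (PlantElement("triple", (25,)),)))
        L, K = 45, 12
        res = multibridging_assemble(all_windows(fx.genome, L), K)
        assert res.status == "unique"
        assert rotations_equal(res.sequence, fx.genome.sequence)
        assert res.diagnostics["resolutions"] >= 1

    def test_unbridged_interleaved_pair_reports_both_spellings(
        self, confusable_fixture
    ):
        fx = confusable_fixture
        sw = make_confusable(fx.genome)
        res = multibridging_assemble(all_windows(fx.genome, 31), 20)
        assert res.status == "ambiguous"
        cands = [res.sequence] + res.alternatives
        assert any(rotations_equal(c, fx.genome.sequence) for c in cands)
        assert any(rotations_equal(c, sw.sequence) for c in cands)

    def test_dominates_debruijn(self):
        # whenever DEBRUIJN succeeds uniquely at K, MULTIBRIDGING does too
        rng = np.random.default_rng(42)
        checked = 0
        for i in range(10):
            g, stats = make_trial_genome(rng, i)
            L, N = harness_point(rng, g, stats)
            K = default_K(stats, "debruijn")
            if K >= L:
                continue
            reads = sample_reads(g, N, L, seed=int(rng.integers(2**31))).sequences()
            db = debruijn_assemble(reads, K)
            if db.status != "unique":
                continue
            mb = multibridging_assemble(reads, K)
            assert mb.status == "unique"
            assert rotations_equal(mb.sequence, db.sequence)
            checked += 1
        assert checked >= 5


class TestConditionalGuarantees:
    """Smoke-scale version of the theorem harness (the full >=500-trial run
    lives in the acceptance suite)."""

    @pytest.mark.parametrize(
        "algorithm", ["greedy", "debruijn", "simplebridging", "multibridging"]
    )
    def test_hypotheses_imply_exact_reconstruction(self, algorithm):
        rng = np.random.default_rng(hash(algorithm) % 2**31)
        certified = 0
        for i in range(14):
            g, stats = make_trial_genome(rng, i)
            L, N = harness_point(rng, g, stats)
            K = default_K(stats, algorithm)
            if K >= L:
                continue
            for _ in range(2):
                rec = run_trial(g, stats, algorithm, K, L, N, int(rng.integers(2**31)))
                if rec.conditions_hold:
                    certified += 1
                    assert rec.outcome == "unique-correct", rec
        assert certified >= 15


class TestInvariances:
    def test_rotation_invariance_of_assembly(self):
        fx = make_fixture(FixtureSpec(300, 3, (PlantElement("pair", (20,)),)))
        g = fx.genome
        res0 = multibridging_assemble(all_windows(g, 35), 12)
        res1 = multibridging_assemble(all_windows(g.rotate(101), 35), 12)
        assert res0.status == res1.status == "unique"
        assert rotations_equal(res0.sequence, res1.sequence)

    def test_kmer_assemblers_ignore_read_order(self):
        g = random_genome(250, 13)
        reads = sample_reads(g, 120, 35, seed=5).sequences()
        shuffled = reads[:]
        random.Random(3).shuffle(shuffled)
        a = multibridging_assemble(reads, 12)
        b = multibridging_assemble(shuffled, 12)
        assert a.status == b.status
        if a.status == "unique":
            assert rotations_equal(a.sequence, b.sequence)
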