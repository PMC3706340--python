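"""Graph engine: construction, condensation confluence, X-node census,
extensions, Eulerian uniqueness, spelling, and GFA round trips."""

import random

import pytest

from debridge.fixtures import FixtureSpec, PlantElement, make_fixture, random_genome
from debridge.genome import rotations_equal
from debridge.sequence_graph import (
    NotEulerianError,
    SequenceGraph,
    build_kmer_graph,
    condense,
    debug_dump,
    eulerian_cycle,
    extend_left,
    extend_right,
    find_x_nodes,
    read_gfa,
    spell,
    write_gfa,
)


def graph_signature(g: SequenceGraph):
    nodes = sorted(g.labels.values())
    edges = sorted(
        (g.labels[s], g.labels[d], w) for s, d, w in g.edges.values()
    )
    return nodes, edges


def all_windows(genome, L):
    return [genome.substr(t, L) for t in range(len(genome))]


class TestBuild:
    def test_single_read_path(self):
        g = build_kmer_graph(["ACGTA"], 2)
        assert sorted(g.labels.values()) == ["AC", "CG", "GT", "TA"]

    def test_edge_count_and_weights(self):
        g = build_kmer_graph(["ACGTA"], 2)
        assert len(g.edges) == 3  # 4 K-mers -> 3 adjacencies
        assert all(w == 1 for _, _, w in g.edges.values())
        assert spell(g, sorted(g.edges)) == "ACGTA"

    def test_duplicate_reads_do_not_change_the_graph(self):
        a = build_kmer_graph(["ACGTACC"], 3)
        b = build_kmer_graph(["ACGTACC", "ACGTACC"], 3)
        assert graph_signature(a) == graph_signature(b)
        assert len(b.threads) == 2

    def test_edges_are_the_spectrum(self):
        gen = random_genome(80, 4)
        K = 7
        g = build_kmer_graph(all_windows(gen, K + 1), K)
        spectrum = {gen.substr(t, K + 1) for t in range(80)}
        edges = {
            g.labels[s] + g.labels[d][-1] for s, d, _ in g.edges.values()
        }
        assert edges == spectrum

    def test_K_not_below_read_length_rejected(self):
        with pytest.raises(ValueError):
            build_kmer_graph(["ACGT"], 4)


class TestCondense:
    def test_path_collapses_to_read(self):
        g = build_kmer_graph(["ACGTAGG"], 2)
        condense(g)
        assert list(g.labels.values()) == ["ACGTAGG"]
        assert g.threads == [[next(iter(g.labels))]]

    def test_repeat_free_cycle_collapses_to_self_loop(self):
        gen = random_genome(60, 8)
        g = build_kmer_graph(all_windows(gen, 13), 12)
        condense(g)
        assert g.n_nodes() == 1 and g.n_edges() == 1
        (eid,) = g.edges
        s, d, w = g.edges[eid]
        assert s == d  # self-loop
        seq = spell(g, [eid], circular=True)
        assert rotations_equal(seq, gen.sequence)

    def test_confluence_under_read_order(self):
        gen = random_genome(150, 5)
        reads = all_windows(gen, 20)
        base = None
        for seed in range(4):
            shuffled = reads[:]
            random.Random(seed).shuffle(shuffled)
            g = build_kmer_graph(shuffled, 9)
            condense(g)
            sig = graph_signature(g)
            base = base or sig
            assert sig == base

    def test_idempotent(self):
        gen = random_genome(120, 6)
        g = build_kmer_graph(all_windows(gen, 18), 8)
        condense(g)
        sig = graph_signature(g)
        condense(g)
        assert graph_signature(g) == sig

    def test_spelled_length_invariant_under_condense(self):
        gen = random_genome(100, 11)
        g_raw = build_kmer_graph(all_windows(gen, 15), 9)
        raw_cycle = eulerian_cycle(g_raw)
        raw_seq = spell(g_raw, raw_cycle.cycle, circular=True)
        g = build_kmer_graph(all_windows(gen, 15), 9)
        condense(g)
        cooked = spell(g, eulerian_cycle(g).cycle, circular=True)
        assert len(raw_seq) == len(cooked) == 100


class TestXNodes:
    def test_simple_cycle_has_none(self):
        gen = random_genome(70, 2)
        g = build_kmer_graph(all_windows(gen, 13), 12)
        condense(g)
        assert find_x_nodes(g) == []

    def test_planted_two_copy_repeat_yields_one_two_x_node(self):
        fx = make_fixture(FixtureSpec(400, 4, (PlantElement("pair", (24,)),)))
        L, K = 40, 12
        g = build_kmer_graph(all_windows(fx.genome, L), K)
        condense(g)
        xs = find_x_nodes(g)
        assert len(xs) == 1
        assert xs[0].is_two_x and xs[0].multiplicity == 2
        assert xs[0].bridged and xs[0].all_bridged  # every window read exists
        assert len(g.labels[xs[0].node]) >= 24

    def test_self_loop_counts_once_per_side(self):
        g = SequenceGraph()
        v = g.add_node("AATAA")
        x, y = g.add_node("CAAT"), g.add_node("TAAC")
        g.add_edge(x, v, 3)
        g.add_edge(v, v, 2)
        g.add_edge(v, y, 3)
        xs = find_x_nodes(g)
        assert [x.node for x in xs] == [v]  # degrees 2/2 with the self-loop


class TestExtensions:
    def _graph(self):
        g = SequenceGraph()
        v = g.add_node("ATTG")
        q = g.add_node("TGCA")
        g.add_edge(v, q, 2)
        return g, v, q

    def test_extend_right_by_one_base(self):
        g, v, q = self._graph()
        assert extend_right(g, v, q) == "ATTGC"

    def test_extend_right_full_overlap_appends_last_base(self):
        g = SequenceGraph()
        v = g.add_node("GATC")
        q = g.add_node("ATCA")
        g.add_edge(v, q, 3)  # a = |q| - 1
        assert extend_right(g, v, q) == "GATC" + "A"

    def test_extend_left_inverse_slicing(self):
        g, v, q = self._graph()
        ext = extend_left(g, v, q)
        assert ext == "T" + "TGCA"
        assert ext[-len(g.labels[q]):] == g.labels[q]

    def test_missing_edge_raises(self):
        g, v, q = self._graph()
        with pytest.raises(ValueError):
            extend_right(g, q, v)


class TestEulerian:
    def test_simple_cycle_unique(self):
        gen = random_genome(50, 3)
        g = build_kmer_graph(all_windows(gen, 12), 11)
        condense(g)
        res = eulerian_cycle(g)
        assert res.unique
        assert rotations_equal(spell(g, res.cycle, circular=True), gen.sequence)

    def test_interleaved_fixture_two_spellings(self, confusable_fixture):
        from debridge.fixtures import make_confusable

        fx = confusable_fixture
        gen = fx.genome
        sw = make_confusable(gen)
        g = build_kmer_graph(all_windows(gen, 21), 20)
        condense(g)
        res = eulerian_cycle(g)
        assert not res.unique
        seqs = {
            spell(g, res.cycle, circular=True),
            spell(g, res.witness, circular=True),
        }
        assert any(rotations_equal(s, gen.sequence) for s in seqs)
        assert any(rotations_equal(s, sw.sequence) for s in seqs)

    def test_nested_pair_stays_unique(self):
        fx = make_fixture(
            FixtureSpec(500, 6, (PlantElement("nested_pair", (25, 30)),))
        )
        g = build_kmer_graph(all_windows(fx.genome, 16), 15)
        condense(g)
        res = eulerian_cycle(g)
        assert res.unique
        assert rotations_equal(
            spell(g, res.cycle, circular=True), fx.genome.sequence
        )

    def test_disconnected_or_unbalanced_rejected(self):
        g = build_kmer_graph(["ACGTT", "GGCAG"], 3)  # two islands, open paths
        with pytest.raises(NotEulerianError):
            eulerian_cycle(g)


class TestGFA:
    def test_round_trip(self, tmp_path):
        gen = random_genome(90, 12)
        g = build_kmer_graph(all_windows(gen, 14), 9)
        condense(g)
        p = tmp_path / "g.gfa"
        write_gfa(g, p)
        g2 = read_gfa(p)
        assert graph_signature(g) == graph_signature(g2)
        text = p.read_text()
        assert text.startswith("H\t") and "\t8M\n" in text

    def test_debug_dump_structure(self):
        g = build_kmer_graph(["ACGTA"], 2)
        d = debug_dump(g)
        assert set(d) == {"nodes", "edges", "threads"}
        assert len(d["edges"]) == 3 and len(d["threads"]) == 1
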