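"""Redundancy removal, end extension, variant enumeration/selection, SNP
collapsing and GFA/FASTA serialization."""

import numpy as np
import pytest

import targetasm as ta

from oracle import count_source_sink_paths


@pytest.fixture(scope="module")
def toy_counts():
    rng = np.random.default_rng(21)
    base = ta.random_sequence(1400, rng)
    hapB = ta.plant_snps(base, list(range(200, 1200, 100)), seed=3)
    reads = ta.simulate_reads(
        [base, hapB],
        ta.SimConfig(seed=5, genome_len=1400, coverage=20, read_len=80,
                     insert_mean=160, insert_sd=5),
    )
    return base, hapB, ta.count_kmers(reads, 21)


class TestRemoveRedundant:
    def _graph(self, seq, k=21, name="g"):
        return ta.AssembledGraph.from_paths([seq], k, origin_target=name)

    def test_contained_graph_removed(self):
        rng = np.random.default_rng(2)
        a = ta.random_sequence(300, rng)
        b = ta.random_sequence(300, rng)
        gA = self._graph(a, name="geneA")
        gAB = self._graph(a + b, name="fusion")
        kept = ta.remove_redundant([gA, gAB], 21)
        assert [g.origin_target for g in kept] == ["fusion"]

    def test_keep_subgraphs_is_identity(self):
        rng = np.random.default_rng(2)
        a = ta.random_sequence(300, rng)
        gA = self._graph(a, name="geneA")
        gAA = self._graph(a, name="copy")
        kept = ta.remove_redundant([gA, gAA], 21, keep_subgraphs=True)
        assert len(kept) == 2

    def test_mutual_containment_keeps_first(self):
        rng = np.random.default_rng(2)
        a = ta.random_sequence(300, rng)
        kept = ta.remove_redundant(
            [self._graph(a, name="first"), self._graph(a, name="second")], 21
        )
        assert [g.origin_target for g in kept] == ["first"]

    def test_disjoint_graphs_survive(self):
        rng = np.random.default_rng(2)
        kept = ta.remove_redundant(
            [
                self._graph(ta.random_sequence(300, rng), name="x"),
                self._graph(ta.random_sequence(300, rng), name="y"),
            ],
            21,
        )
        assert len(kept) == 2


class TestExtendEnds:
    def test_unique_flank_appended(self, gene_fixture):
        fx = gene_fixture
        g = ta.assemble_target(
            ta.Target("hom", "nt", fx.homolog), fx.dbg_p, fx.dbg_s,
            ta.ScoringScheme.nucleotide(), ta.Params(),
        )
        ge = ta.extend_ends(g, fx.dbg_p)
        (seq,) = ge.segments.values()
        assert fx.gene in seq
        (added,) = ge.ext.values()
        assert added[0] > 0 and added[1] > 0

    def test_fork_stops_extension(self):
        rng = np.random.default_rng(6)
        stem = ta.random_sequence(40, rng)
        reads = ta.ReadSet(
            [ta.Read("a", stem + "A" + ta.random_sequence(10, rng)),
             ta.Read("b", stem + "C" + ta.random_sequence(10, rng))]
        )
        dbg = ta.build_dbg(ta.count_kmers(reads, 15), 1)
        g = ta.AssembledGraph({"s1": stem}, [], 15)
        ge = ta.extend_ends(g, dbg)
        assert ge.segments["s1"] == stem  # two successors: unchanged

    def test_circular_context_terminates(self):
        cycle = "ACGTGGCTAATCGGATC"
        seq = cycle * 4
        reads = ta.ReadSet([ta.Read("c", seq)])
        dbg = ta.build_dbg(ta.count_kmers(reads, 9), 1)
        g = ta.AssembledGraph({"s1": seq[:30]}, [], 9)
        ge = ta.extend_ends(g, dbg)  # must not loop forever
        assert len(ge.segments["s1"]) <= len(seq) + len(cycle)


class TestEnumerateVariants:
    def test_bubble_graph_two_paths(self, toy_counts):
        base, hapB, cs = toy_counts
        snp = ta.plant_snps(base, [700], seed=9)
        g = ta.AssembledGraph.from_paths([base, snp], 21, origin_target="bub")
        vs = ta.enumerate_variants(g, cs, ta.Params(), target_length=1400)
        assert {s for s, _ in vs.variants} == {base, snp}

    def test_unphased_sites_multiply_and_rank(self, toy_counts):
        base, hapB, cs = toy_counts
        g = ta.AssembledGraph.from_paths([base, hapB], 21, origin_target="toy")
        vs = ta.enumerate_variants(g, cs, ta.Params(max_variants=2000), target_length=1400)
        assert len(vs.variants) == 1024
        assert not vs.truncated
        sups = [s for _, s in vs.variants]
        assert sups == sorted(sups, reverse=True)
        top2 = ta.enumerate_variants(g, cs, ta.Params(max_variants=2), target_length=1400)
        assert top2.truncated
        assert [s for _, s in top2.variants] == sups[:2]

    def test_enumeration_matches_independent_path_counter(self, toy_counts):
        base, hapB, cs = toy_counts
        g = ta.AssembledGraph.from_paths([base, hapB], 21, origin_target="toy")
        expected = count_source_sink_paths(set(g.segments), g.links)
        vs = ta.enumerate_variants(g, cs, ta.Params(max_variants=5000), target_length=10)
        assert len(vs.variants) == expected

    def test_short_variant_suppressed_by_coverage(self, toy_counts):
        base, _, cs = toy_counts
        frag = base[:560]  # 0.4 of a 1400-length target
        g = ta.AssembledGraph({"s1": frag}, [], 21, origin_target="t")
        assert ta.enumerate_variants(g, cs, ta.Params(), target_length=1400).variants == []
        ok = ta.enumerate_variants(g, cs, ta.Params(target_coverage=0.3), target_length=1400)
        assert len(ok.variants) == 1

    def test_min_hit_len_overrides_coverage(self, toy_counts):
        base, _, cs = toy_counts
        frag = base[:560]
        g = ta.AssembledGraph({"s1": frag}, [], 21, origin_target="t")
        vs = ta.enumerate_variants(
            g, cs, ta.Params(min_hit_len=500), target_length=1400
        )
        assert len(vs.variants) == 1

    def test_extension_excluded_from_length_filter(self, toy_counts):
        base, _, cs = toy_counts
        frag = base[:560]
        g = ta.AssembledGraph({"s1": frag + "A" * 200}, [], 21, origin_target="t")
        g.ext["s1"] = [0, 200]  # flank added by end extension
        vs = ta.enumerate_variants(g, cs, ta.Params(), target_length=1400)
        assert vs.variants == []  # pre-extension length 560 < 700


class TestSelectVariants:
    def test_simple_bubble_two_sequences(self, toy_counts):
        base, _, cs = toy_counts
        snp = ta.plant_snps(base, [700], seed=9)
        g = ta.AssembledGraph.from_paths([base, snp], 21, origin_target="bub")
        sel = ta.select_variants(g, cs)
        assert set(sel) == {base, snp}

    def test_linear_graph_single_sequence(self, toy_counts):
        base, _, cs = toy_counts
        g = ta.AssembledGraph.from_paths([base], 21, origin_target="lin")
        assert ta.select_variants(g, cs) == [base]

    def test_shared_best_path_reported_once(self, toy_counts):
        base, hapB, cs = toy_counts
        g = ta.AssembledGraph.from_paths([base, hapB], 21, origin_target="toy")
        sel = ta.select_variants(g, cs)
        assert len(sel) == len(set(sel))
        assert len(sel) <= len(g.links)


class TestCollapseSnps:
    def test_substitution_bubble_becomes_iupac(self, toy_counts):
        base, _, cs = toy_counts
        snp = ta.plant_snps(base, [700], seed=9)
        g = ta.AssembledGraph.from_paths([base, snp], 21, origin_target="bub")
        gc = ta.collapse_snps(g)
        assert gc.n_segments() == 1
        (seq,) = gc.segments.values()
        alts = {base[700], snp[700]}
        code = {frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
                frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M"}
        assert seq[700] == code[frozenset(alts)]

    def test_indel_bubble_untouched(self):
        rng = np.random.default_rng(10)
        base = ta.random_sequence(400, rng)
        deleted = base[:200] + base[203:]
        g = ta.AssembledGraph.from_paths([base, deleted], 21, origin_target="d")
        gc = ta.collapse_snps(g)
        assert gc.kmer_set(21) == g.kmer_set(21)
        assert gc.n_segments() >= 4  # the bubble survives

    def test_many_snps_reduce_variant_count(self, toy_counts):
        base, hapB, cs = toy_counts
        g = ta.AssembledGraph.from_paths([base, hapB], 21, origin_target="toy")
        before = len(
            ta.enumerate_variants(g, cs, ta.Params(max_variants=2000), target_length=10).variants
        )
        gc = ta.collapse_snps(g)
        after = len(
            ta.enumerate_variants(gc, cs, ta.Params(max_variants=2000), target_length=10).variants
        )
        assert before == 1024 and after < before


class TestSerialization:
    def test_gfa_round_trip(self, toy_counts, tmp_path):
        base, hapB, _ = toy_counts
        g = ta.AssembledGraph.from_paths([base, hapB], 21, origin_target="toy")
        path = tmp_path / "g.gfa"
        ta.write_gfa(g, str(path))
        g2 = ta.read_gfa(str(path))
        assert g2.segments == g.segments
        assert g2.links == g.links
        assert g2.k == g.k
        text = path.read_text()
        assert text.startswith("H\tVN:Z:1.0")
        assert f"\t{g.overlap}M" in text

    def test_single_segment_gfa_shape(self, tmp_path):
        g = ta.AssembledGraph({"s1": "ACGTACGT"}, [], 5)
        path = tmp_path / "one.gfa"
        ta.write_gfa(g, str(path))
        lines = path.read_text().splitlines()
        assert sum(1 for l in lines if l.startswith("S")) == 1
        assert sum(1 for l in lines if l.startswith("L")) == 0

    def test_fasta_wraps_at_80(self, tmp_path):
        p = tmp_path / "v.fa"
        ta.write_fasta([("v1", "A" * 200)], str(p))
        lines = p.read_text().splitlines()
        assert lines[0] == ">v1"
        assert [len(l) for l in lines[1:]] == [80, 80, 40]
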