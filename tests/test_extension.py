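"""Extension engine: candidate classification, strand filtering, secondary
rescue, fork bookkeeping, anchors, density abort and whole-target assembly."""

import numpy as np
import pytest

import targetasm as ta
from targetasm.extension import _filter_candidates
from targetasm.dna import revcomp


def _dbg_from(counts_map, k):
    kc = ta.KmerCounts(k)
    for km, (p, m) in counts_map.items():
        kc.counts[ta.canonical(km)] = [p, m]
    return ta.build_dbg(kc, 1)


class TestClassifyExtension:
    params = ta.Params()

    def test_single_choice(self):
        dbg = _dbg_from({"ACGTA": (20, 20)}, 5)
        kind, bases = ta.classify_extension(dbg, "AACGT", self.params)
        assert (kind, bases) == ("single", ["A"])

    def test_noise_and_strand_filters(self):
        # balanced A at 40 vs plus-only C at 4: C survives the noise cut
        # (4 >= 0.1*40) but dies to the strand-balance rule
        cands = {"A": (20, 20), "C": (4, 0)}
        assert _filter_candidates(cands, self.params) == ["A"]

    def test_noise_cut(self):
        cands = {"A": (20, 20), "C": (1, 1)}
        assert _filter_candidates(cands, self.params) == ["A"]

    def test_fork_order_count_then_lexicographic(self):
        cands = {"G": (15, 15), "A": (14, 16)}
        assert _filter_candidates(cands, self.params) == ["A", "G"]
        cands = {"G": (16, 16), "A": (14, 14)}
        assert _filter_candidates(cands, self.params) == ["G", "A"]

    def test_all_one_strand_is_a_fork(self):
        # no balanced choice exists: the strand rule does not apply
        cands = {"A": (20, 0), "C": (18, 0)}
        assert _filter_candidates(cands, self.params) == ["A", "C"]

    def test_dead_end(self):
        dbg = _dbg_from({"ACGTA": (5, 5)}, 5)
        kind, bases = ta.classify_extension(dbg, "TTTTT", self.params)
        assert (kind, bases) == ("dead_end", [])


class TestSecondaryRescue:
    def test_rescue_candidates_from_path_suffix(self):
        dbg_s = _dbg_from({"CGTAC": (1, 0)}, 5)
        bases = ta.try_secondary_rescue("AACGTA", dbg_s, ta.Params(), "right")
        assert bases == ["C"]

    def test_left_rescue_uses_prefix(self):
        dbg_s = _dbg_from({"GAACG": (1, 0)}, 5)
        bases = ta.try_secondary_rescue("AACGTA", dbg_s, ta.Params(), "left")
        assert bases == ["G"]

    def test_default_min_count_never_triggers_single_case(self, gene_fixture):
        # every primary k-mer has count >= 2 while the threshold is 1, so the
        # single-extension rescue condition can never be met
        fx = gene_fixture
        thr = ta.Params().secondary_kmer_threshold
        assert thr == 1
        assert all(
            fx.counts_p.count(km) > thr for km in fx.dbg_p.kmers
        )

    def test_dip_crossed_with_low_settings_only(self):
        """A coverage dip bridged by single-copy short-overlap reads is crossed
        via the secondary graph at min_count 1 and fragments at min_count 2."""
        rng = np.random.default_rng(8)
        genome = ta.random_sequence(900, rng)
        sim = ta.simulate_reads(
            [genome], ta.SimConfig(seed=9, genome_len=900, coverage=30)
        )
        kept = ta.ReadSet()
        for r in sim:
            s = genome.find(r.sequence)
            if s == -1:
                s = genome.find(revcomp(r.sequence))
            if s == -1 or not (s + 150 > 386 and s < 530):
                kept.add(ta.Read(r.id, r.sequence))
        for st in (236, 296, 356, 416, 476):
            kept.add(ta.Read(f"bridge{st}", genome[st : st + 100]))
        target = ta.Target("g", "nt", ta.mutate_target(genome, 0.9, seed=5))
        results = {}
        for label, pr in (("low", ta.Params().low_coverage()), ("default", ta.Params())):
            dp = ta.build_dbg(ta.count_kmers(kept, 75), pr.min_count)
            ds = ta.build_dbg(ta.count_kmers(kept, 29), pr.min_count)
            g = ta.assemble_target(
                ta.Target("g", "nt", target.sequence), dp, ds,
                ta.ScoringScheme.nucleotide(), pr,
            )
            results[label] = g
        low_lens = sorted(len(s) for s in results["low"].segments.values())
        assert low_lens and low_lens[-1] > 800  # crossed the dip
        assert results["default"].n_segments() >= 2  # fragmented
        assert all(len(s) < 800 for s in results["default"].segments.values())


class TestExtendDirection:
    def test_linear_region_single_path(self, gene_fixture):
        fx = gene_fixture
        target = ta.Target("hom", "nt", fx.homolog)
        scheme = ta.ScoringScheme.nucleotide()
        seeds, _ = ta.find_seeds(fx.dbg_p, target, scheme, ta.Params())
        sd = sorted(seeds, key=lambda s: abs(s.target_pos - 1000))[0]
        res = ta.extend_direction(sd, "right", fx.dbg_p, fx.dbg_s, target, scheme, ta.Params())
        assert not res.aborted
        assert len(res.paths) == 1
        path = res.paths[0]
        # no interior forks; at most a terminal clip mark where the extension
        # left the target and was trimmed back
        assert set(path.fork_positions) <= {len(path.bases)}
        # the assembled bases all lie on the true genome
        assert (sd.seq + path.bases) in fx.genome

    def test_emitted_path_ends_at_best_position(self, gene_fixture):
        """Rescoring an emitted path from scratch lands its optimum exactly at
        the path end (the recorded best scoring position)."""
        fx = gene_fixture
        target = ta.Target("hom", "nt", fx.homolog)
        scheme = ta.ScoringScheme.nucleotide()
        seeds, _ = ta.find_seeds(fx.dbg_p, target, scheme, ta.Params())
        sd = sorted(seeds, key=lambda s: abs(s.target_pos - 800))[0]
        res = ta.extend_direction(sd, "right", fx.dbg_p, fx.dbg_s, target, scheme, ta.Params())
        path = res.paths[0]
        window = target.sequence[sd.target_pos + fx.pk :]
        st = ta.AlignmentState(window, scheme)
        for b in path.bases:
            st.extend(b)
        assert st.best_path_pos == len(path.bases)

    def test_snp_fork_recorded(self):
        rng = np.random.default_rng(14)
        hapA = ta.random_sequence(700, rng)
        hapB = ta.plant_snps(hapA, [350], seed=3)
        reads = ta.simulate_reads(
            [hapA, hapB], ta.SimConfig(seed=6, genome_len=700, coverage=60)
        )
        dp = ta.build_dbg(ta.count_kmers(reads, 75), 2)
        ds = ta.build_dbg(ta.count_kmers(reads, 29), 2)
        target = ta.Target("t", "nt", ta.mutate_target(hapA, 0.92, seed=8))
        scheme = ta.ScoringScheme.nucleotide()
        seeds, _ = ta.find_seeds(dp, target, scheme, ta.Params())
        sd = sorted(
            (s for s in seeds if s.target_pos + 75 < 330),
            key=lambda s: -s.target_pos,
        )[0]
        res = ta.extend_direction(sd, "right", dp, ds, target, scheme, ta.Params())
        assert len(res.paths) == 2
        forks = {p.fork_positions for p in res.paths}
        assert all(len(f) >= 1 for f in forks)
        seqs = {sd.seq + p.bases for p in res.paths}
        assert any(s in hapA for s in seqs)
        assert any(s in hapB for s in seqs)


class TestForkDensity:
    @pytest.mark.parametrize(
        "n_forks,length,expected",
        [(21, 200, True), (20, 200, False), (3, 20, True), (2, 20, False)],
    )
    def test_threshold_is_strict(self, n_forks, length, expected):
        forks = list(range(1, n_forks + 1))
        assert ta.fork_density_abort(forks, length, ta.Params()) is expected

    def test_dense_fixture_aborts_quickly(self):
        rng = np.random.default_rng(32)
        base = ta.random_sequence(600, rng)
        haps = []
        for _ in range(8):
            h = list(base)
            for pos in range(150, 500, 8):
                h[pos] = "ACGT"[rng.integers(0, 4)]
            haps.append("".join(h))
        reads = ta.ReadSet()
        for h in haps:
            for r in ta.tiled_reads(h, 80, 40):
                reads.add(r)
                reads.add(ta.Read(r.id + "b", r.sequence))
        dp = ta.build_dbg(ta.count_kmers(reads, 15), 2)
        target = ta.Target("t", "nt", base)
        scheme = ta.ScoringScheme.nucleotide(word=4)
        seeds, _ = ta.find_seeds(dp, target, scheme, ta.Params())
        sd = [s for s in seeds if s.target_pos < 120][0]
        res = ta.extend_direction(sd, "right", dp, None, target, scheme, ta.Params())
        assert res.aborted


class TestMergeAtAnchor:
    def test_register_and_merge(self):
        anchors = {}
        k = 75
        assert not ta.merge_at_anchor(anchors, "KMER", 10, 500, k)  # registers
        assert anchors == {"KMER": 500}
        assert ta.merge_at_anchor(anchors, "KMER", 3, 500, k)  # same best: merge
        assert not ta.merge_at_anchor(anchors, "KMER", 3, 777, k)  # differs

    def test_distance_bound_is_strict(self):
        anchors = {}
        assert not ta.merge_at_anchor(anchors, "A", 19, 1, 75)  # 19 >= 75/4
        assert anchors == {}
        ta.merge_at_anchor(anchors, "A", 18, 1, 75)
        assert anchors == {"A": 1}


class TestAssembleTarget:
    def test_single_gene_single_segment(self, gene_fixture):
        fx = gene_fixture
        g = ta.assemble_target(
            ta.Target("hom", "nt", fx.homolog), fx.dbg_p, fx.dbg_s,
            ta.ScoringScheme.nucleotide(), ta.Params(),
        )
        assert g.n_segments() == 1
        (seq,) = g.segments.values()
        assert seq in fx.genome
        assert len(seq) > 0.95 * len(fx.gene)

    def test_two_haplotype_bubble_topology(self):
        rng = np.random.default_rng(14)
        hapA = ta.random_sequence(700, rng)
        hapB = ta.plant_snps(hapA, [350], seed=3)
        reads = ta.simulate_reads(
            [hapA, hapB], ta.SimConfig(seed=6, genome_len=700, coverage=60)
        )
        dp = ta.build_dbg(ta.count_kmers(reads, 75), 2)
        ds = ta.build_dbg(ta.count_kmers(reads, 29), 2)
        g = ta.assemble_target(
            ta.Target("t", "nt", ta.mutate_target(hapA, 0.92, seed=8)),
            dp, ds, ta.ScoringScheme.nucleotide(), ta.Params(),
        )
        assert g.n_segments() == 4
        arms = [s for s in g.segments if g.preds(s) and g.succs(s)]
        assert len(arms) == 2
        assert all(len(g.segments[a]) == 2 * 75 - 1 for a in arms)

    def test_zero_seeds_empty_graph(self, gene_fixture):
        rng = np.random.default_rng(99)
        unrelated = ta.Target("x", "nt", ta.random_sequence(500, rng))
        g = ta.assemble_target(
            unrelated, gene_fixture.dbg_p, gene_fixture.dbg_s,
            ta.ScoringScheme.nucleotide(), ta.Params(),
        )
        assert g.is_empty()

    def test_segment_kmers_exist_in_graphs(self, gene_fixture):
        fx = gene_fixture
        g = ta.assemble_target(
            ta.Target("hom", "nt", fx.homolog), fx.dbg_p, fx.dbg_s,
            ta.ScoringScheme.nucleotide(), ta.Params(),
        )
        for seq in g.segments.values():
            for i in range(len(seq) - fx.pk + 1):
                assert seq[i : i + fx.pk] in fx.dbg_p

    def test_deterministic(self, gene_fixture):
        fx = gene_fixture
        make = lambda: ta.assemble_target(
            ta.Target("hom", "nt", fx.homolog), fx.dbg_p, fx.dbg_s,
            ta.ScoringScheme.nucleotide(), ta.Params(),
        )
        g1, g2 = make(), make()
        assert g1.segments == g2.segments and g1.links == g2.links

    def test_no_remaining_seed_inside_segments(self, gene_fixture):
        fx = gene_fixture
        target = ta.Target("hom", "nt", fx.homolog)
        scheme = ta.ScoringScheme.nucleotide()
        seeds, _ = ta.find_seeds(fx.dbg_p, ta.Target("hom", "nt", fx.homolog), scheme, ta.Params())
        g = ta.assemble_target(target, fx.dbg_p, fx.dbg_s, scheme, ta.Params())
        segment_kmers = set()
        for seq in g.segments.values():
            for i in range(len(seq) - fx.pk + 1):
                segment_kmers.add(ta.canonical(seq[i : i + fx.pk]))
        # seed consumption: every seed whose k-mer appears in a segment was used
        consumed = {s.kmer for s in seeds} & segment_kmers
        assert consumed  # the fixture seeds overlap the assembly
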