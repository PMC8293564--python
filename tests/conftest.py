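"""Shared synthetic fixtures.

Expensive simulations are session-scoped so several tests can reuse one
read set; every fixture is fully seeded and deterministic.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

import targetasm as ta


@dataclass
class GeneFixture:
    gene: str
    genome: str
    homolog: str
    reads: ta.ReadSet
    counts_p: ta.KmerCounts
    counts_s: ta.KmerCounts
    dbg_p: ta.DeBruijnGraph
    dbg_s: ta.DeBruijnGraph
    pk: int
    sk: int


def build_gene_fixture(
    gene_len=2000, flank=200, coverage=30, identity=0.85, seed=42, min_count=2
) -> GeneFixture:
    rng = np.random.default_rng(seed)
    gene = ta.random_sequence(gene_len, rng)
    genome = ta.random_sequence(flank, rng) + gene + ta.random_sequence(flank, rng)
    reads = ta.simulate_reads(
        [genome],
        ta.SimConfig(seed=seed + 1, genome_len=len(genome), coverage=coverage,
                     read_len=150, insert_mean=300, insert_sd=10),
    )
    pk, sk = ta.choose_kmer_sizes([150])
    cp = ta.count_kmers(reads, pk)
    cs = ta.count_kmers(reads, sk)
    return GeneFixture(
        gene, genome, ta.mutate_target(gene, identity, seed=seed + 2),
        reads, cp, cs,
        ta.build_dbg(cp, min_count), ta.build_dbg(cs, min_count), pk, sk,
    )


@pytest.fixture(scope="session")
def gene_fixture() -> GeneFixture:
    """2 kb gene in 200 bp flanks, 30x error-free pairs, 85%-identity homolog."""
    return build_gene_fixture()


@dataclass
class HaplotypeFixture:
    hapA: str
    hapB: str
    snps: list
    target: ta.Target
    reads: ta.ReadSet
    counts_s: ta.KmerCounts
    dbg_p: ta.DeBruijnGraph
    dbg_s: ta.DeBruijnGraph
    insert: ta.InsertSizeRange


@pytest.fixture(scope="session")
def haplotype_fixture() -> HaplotypeFixture:
    """Two haplotypes differing at three SNPs spaced within one insert length."""
    rng = np.random.default_rng(5)
    hapA = ta.random_sequence(900, rng)
    snps = [300, 400, 500]
    hapB = ta.plant_snps(hapA, snps, seed=11)
    reads = ta.simulate_reads(
        [hapA, hapB],
        ta.SimConfig(seed=9, genome_len=900, coverage=60, read_len=150,
                     insert_mean=300, insert_sd=10),
    )
    pk, sk = ta.choose_kmer_sizes([150])
    cp = ta.count_kmers(reads, pk)
    cs = ta.count_kmers(reads, sk)
    dbg_p = ta.build_dbg(cp, 2)
    insert = ta.estimate_insert_size(reads, dbg_p, min_joins=10)
    return HaplotypeFixture(
        hapA, hapB, snps,
        ta.Target("hap", "nt", ta.mutate_target(hapA, 0.9, seed=2)),
        reads, cs, dbg_p, ta.build_dbg(cs, 2), insert,
    )


def make_fig1_graph(seed=1, k=6):
    """Hand-built two-fork graph: A,B -> C -> D,E with k-1 overlaps.

    A/B differ at their final exclusive base and D/E at their first, so a
    read from one phased path matches zero bases of the other side's choice.
    """
    rng = np.random.default_rng(seed)
    ov = k - 1
    core = ta.random_sequence(30, rng)
    A = ta.random_sequence(19, rng) + "G" + core[:ov]
    B = ta.random_sequence(19, rng) + "T" + core[:ov]
    D = core[-ov:] + "A" + ta.random_sequence(19, rng)
    E = core[-ov:] + "C" + ta.random_sequence(19, rng)
    graph = ta.AssembledGraph(
        {"A": A, "B": B, "C": core, "D": D, "E": E},
        [("A", "C"), ("B", "C"), ("C", "D"), ("C", "E")],
        k,
    )
    paths = {
        (l, r): graph.path_sequence([l, "C", r])
        for l in ("A", "B")
        for r in ("D", "E")
    }
    return graph, paths
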