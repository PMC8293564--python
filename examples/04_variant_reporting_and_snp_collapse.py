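"""Variant enumeration, support ranking and SNP collapsing on a 10-SNP graph.

Ten unphased SNPs multiply into 2^10 = 1024 source-to-sink paths; reporting
caps at max_variants ranked by secondary-k-mer support, and collapsing SNPs
into IUPAC ambiguity codes reduces the graph to a single segment.
"""

import numpy as np

import targetasm as ta

rng = np.random.default_rng(21)
base = ta.random_sequence(1400, rng)
hapB = ta.plant_snps(base, list(range(200, 1200, 100)), seed=3)
reads = ta.simulate_reads(
    [base, hapB],
    ta.SimConfig(seed=5, genome_len=1400, coverage=20, read_len=80,
                 insert_mean=160, insert_sd=5),
)
counts_s = ta.count_kmers(reads, 21)

graph = ta.AssembledGraph.from_paths([base, hapB], 21, origin_target="toy")
print(f"graph: {graph.n_segments()} segments, {len(graph.links)} links")

full = ta.enumerate_variants(graph, counts_s, ta.Params(max_variants=2000),
                             target_length=1400)
print(f"all variants: {len(full.variants)} (2^10 phase combinations)")

capped = ta.enumerate_variants(graph, counts_s, ta.Params(), target_length=1400)
print(f"reported at default cap: {len(capped.variants)} "
      f"(truncated={capped.truncated}, ranked by support)")

selected = ta.select_variants(graph, counts_s)
print(f"per-link best paths: {len(selected)} sequences")

collapsed = ta.collapse_snps(graph)
after = ta.enumerate_variants(collapsed, counts_s, ta.Params(max_variants=2000),
                              target_length=1400)
seq = after.variants[0][0]
ambiguous = sum(1 for c in seq if c not in "ACGT")
print(f"after SNP collapse: {len(after.variants)} variant with "
      f"{ambiguous} IUPAC ambiguity positions")
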