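"""End-to-end pipeline: reads -> graphs -> per-target assembly -> filtering ->
redundancy removal -> reporting."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .config import Params
from .extension import AssembledGraph, assemble_target
from .graphfilter import filter_graph
from .output import (
    VariantSet,
    collapse_snps,
    enumerate_variants,
    extend_ends,
    remove_redundant,
    select_variants,
    write_fasta,
    write_gfa,
)
from .reads import (
    InsertSizeRange,
    build_dbg,
    choose_kmer_sizes,
    count_kmers,
    estimate_insert_size,
    load_reads,
)
from .targets import ScoringScheme, Target, load_targets

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one run needs; mirrors the command-line surface."""

    reads: List[str]
    targets: str
    mode: str = "nt"  # "nt" | "aa"
    gfa: Optional[str] = None
    all_variants: Optional[str] = None
    selected_variants: Optional[str] = None
    paired: Optional[bool] = None  # default: paired iff two read files
    interleaved: bool = False
    kmer: Optional[int] = None
    secondary_kmer: Optional[int] = None
    genetic_code: Optional[int] = None
    params: Params = field(default_factory=Params)
    scheme_overrides: Dict[str, int] = field(default_factory=dict)
    cores: int = 1  # accepted for interface parity; execution is single-threaded

    def __post_init__(self):
        if self.mode not in ("nt", "aa"):
            raise ValueError("mode must be 'nt' or 'aa'")
        if self.mode == "aa" and self.genetic_code is None:
            raise ValueError("protein mode requires a genetic_code")
        if self.mode == "aa":
            for name, k in (("kmer", self.kmer), ("secondary_kmer", self.secondary_kmer)):
                if k is not None and k % 3 != 0:
                    raise ValueError(f"{name}={k}: protein-mode k-mer sizes must be multiples of 3")


@dataclass
class RunSummary:
    primary_k: int
    secondary_k: int
    insert: Optional[InsertSizeRange]
    graphs: List[AssembledGraph]
    variant_sets: List[VariantSet]
    selected: List[Tuple[str, List[str]]]
    outputs: List[str]


def _build_scheme(config: RunConfig) -> ScoringScheme:
    if config.mode == "nt":
        return ScoringScheme.nucleotide(**config.scheme_overrides)
    return ScoringScheme.protein(
        genetic_code=config.genetic_code, **config.scheme_overrides
    )


def run(config: RunConfig) -> RunSummary:
    params = config.params
    paired = config.paired
    if paired is None:
        paired = len(config.reads) == 2 or config.interleaved
    reads = load_reads(config.reads, paired=paired, interleaved=config.interleaved)
    lengths = [len(r.sequence) for r in reads]
    if config.kmer is not None and config.secondary_kmer is not None:
        pk, sk = config.kmer, config.secondary_kmer
    else:
        pk, sk = choose_kmer_sizes(lengths, protein_mode=(config.mode == "aa"))
        if config.kmer is not None:
            pk = config.kmer
        if config.secondary_kmer is not None:
            sk = config.secondary_kmer
    logger.info("k-mer sizes: primary %d, secondary %d", pk, sk)

    counts_p = count_kmers(reads, pk)
    counts_s = count_kmers(reads, sk)
    dbg_p = build_dbg(counts_p, params.min_count)
    dbg_s = build_dbg(counts_s, params.min_count)
    logger.info("primary DBG: %d k-mers; secondary DBG: %d k-mers", len(dbg_p), len(dbg_s))

    insert = None
    if reads.pairs():
        insert = estimate_insert_size(
            reads, dbg_p, cap=params.insert_cap, min_joins=params.min_insert_joins
        )
        logger.info(
            "insert size range [%d, %d] from %d joins",
            insert.min_len, insert.max_len, insert.samples,
        )

    scheme = _build_scheme(config)
    targets = load_targets(config.targets, config.mode)
    graphs: List[AssembledGraph] = []
    target_by_id: Dict[str, Target] = {}
    for tgt in targets:
        target_by_id[tgt.id] = tgt
        g = assemble_target(tgt, dbg_p, dbg_s, scheme, params)
        logger.info(
            "target %s: %d segments, %d links", tgt.id, g.n_segments(), len(g.links)
        )
        graphs.append(g)

    graphs = remove_redundant(graphs, sk, params.keep_subgraphs)
    graphs = [filter_graph(g, reads, insert, params) for g in graphs]
    graphs = remove_redundant(graphs, sk, params.keep_subgraphs)
    if params.collapse_snps:
        graphs = [collapse_snps(g) for g in graphs]
    if params.extend_ends:
        graphs = [extend_ends(g, dbg_p) for g in graphs]

    variant_sets: List[VariantSet] = []
    selected: List[Tuple[str, List[str]]] = []
    for g in graphs:
        tgt = target_by_id[g.origin_target]
        vs = enumerate_variants(
            g, counts_s, params,
            target_length=len(tgt), target_is_protein=(config.mode == "aa"),
        )
        variant_sets.append(vs)
        selected.append((g.origin_target, select_variants(g, counts_s, params)))
        logger.info(
            "target %s: %d variants reported%s",
            g.origin_target, len(vs.variants), " (truncated)" if vs.truncated else "",
        )

    outputs: List[str] = []
    if config.gfa:
        write_gfa(graphs, config.gfa)
        outputs.append(config.gfa)
    if config.all_variants:
        records = []
        for vs in variant_sets:
            for i, (seq, sup) in enumerate(vs.variants):
                records.append((f"{vs.graph_id}|v{i + 1}|support={sup}", seq))
        write_fasta(records, config.all_variants)
        outputs.append(config.all_variants)
    if config.selected_variants:
        records = []
        for tid, seqs in selected:
            for i, seq in enumerate(seqs):
                records.append((f"{tid}|sel{i + 1}", seq))
        write_fasta(records, config.selected_variants)
        outputs.append(config.selected_variants)
    return RunSummary(pk, sk, insert, graphs, variant_sets, selected, outputs)


def run_nucleotide(config: RunConfig) -> RunSummary:
    """Assemble with nucleotide targets."""
    if config.mode != "nt":
        raise ValueError("run_nucleotide requires mode 'nt'")
    return run(config)


def run_protein(config: RunConfig) -> RunSummary:
    """Assemble with protein targets (translated alignment)."""
    if config.mode != "aa":
        raise ValueError("run_protein requires mode 'aa'")
    return run(config)
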