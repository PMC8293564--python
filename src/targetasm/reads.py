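"""Read I/O, k-mer counting, de Bruijn graph construction and insert-size estimation.

Reads are held in memory as plain records; k-mers are counted canonically with
separate per-strand tallies because downstream extension filtering compares the
counts observed on the two strands to spot strand-specific systematic errors.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO

from .dna import BASES, canonical, iter_kmers, revcomp


@dataclass
class Read:
    """One (possibly N-split) sequencing read.

    ``mate_index`` is 0/1 for the two mates of a pair and ``None`` for
    unpaired reads; paired mates share a ``pair_id``.
    """

    id: str
    sequence: str
    mate_index: Optional[int] = None
    pair_id: Optional[str] = None


class ReadSet:
    """Container for reads with convenient access to complete pairs."""

    def __init__(self, reads: Iterable[Read] = ()):
        self.reads: List[Read] = list(reads)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def add(self, read: Read) -> None:
        self.reads.append(read)

    def sequences(self) -> List[str]:
        return [r.sequence for r in self.reads]

    def max_length(self) -> int:
        if not self.reads:
            raise ValueError("empty read set")
        return max(len(r.sequence) for r in self.reads)

    def pairs(self) -> List[Tuple[Read, Read]]:
        """All complete (mate 0, mate 1) pairs; incomplete pairs are skipped."""
        by_pair: Dict[str, Dict[int, Read]] = {}
        order: List[str] = []
        for r in self.reads:
            if r.pair_id is None or r.mate_index is None:
                continue
            if r.pair_id not in by_pair:
                by_pair[r.pair_id] = {}
                order.append(r.pair_id)
            by_pair[r.pair_id][r.mate_index] = r
        return [
            (by_pair[p][0], by_pair[p][1])
            for p in order
            if 0 in by_pair[p] and 1 in by_pair[p]
        ]


def _open_maybe_gzip(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(path: str) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    if name.endswith((".fa", ".fasta", ".fna", ".ffn")):
        return "fasta"
    with _open_maybe_gzip(path) as fh:
        first = fh.read(1)
    if first == "@":
        return "fastq"
    if first == ">":
        return "fasta"
    raise ValueError(f"cannot determine FASTA/FASTQ format of {path}")


def _parse_records(path: str) -> List[Tuple[str, str]]:
    fmt = _sniff_format(path)
    with _open_maybe_gzip(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, fmt)]


def _split_at_n(seq: str) -> List[str]:
    return [part for part in seq.replace("N", " ").split() if part]


def _emit(out: ReadSet, rid: str, seq: str, mate: Optional[int], pair: Optional[str]) -> None:
    """Split a record at N runs; sub-reads keep pairing only if the whole read survived."""
    parts = _split_at_n(seq)
    if len(parts) == 1 and parts[0] == seq:
        out.add(Read(rid, seq, mate, pair))
        return
    for i, part in enumerate(parts):
        out.add(Read(f"{rid}.{i}", part, None, None))


def load_reads(paths: Sequence[str], paired: bool = False, interleaved: bool = False) -> ReadSet:
    """Load FASTA/FASTQ reads (optionally gzipped).

    In paired mode either two files (mate 0 / mate 1, equal record counts) or
    one interleaved file are accepted.  Records containing N are split at N
    runs into unpaired sub-reads.
    """
    if not paths:
        raise ValueError("no read files given")
    out = ReadSet()
    if not paired:
        for path in paths:
            for rid, seq in _parse_records(path):
                _emit(out, rid, seq, None, None)
    elif interleaved or len(paths) == 1:
        if len(paths) != 1:
            raise ValueError("interleaved pairs require exactly one file")
        recs = _parse_records(paths[0])
        if len(recs) % 2 != 0:
            raise ValueError(f"odd record count in interleaved file {paths[0]}")
        for i in range(0, len(recs), 2):
            pid = f"{paths[0]}#{i // 2}"
            _emit(out, recs[i][0], recs[i][1], 0, pid)
            _emit(out, recs[i + 1][0], recs[i + 1][1], 1, pid)
    else:
        if len(paths) != 2:
            raise ValueError("paired mode expects two files or one interleaved file")
        recs0 = _parse_records(paths[0])
        recs1 = _parse_records(paths[1])
        if len(recs0) != len(recs1):
            raise ValueError(
                f"mismatched pair counts: {paths[0]} has {len(recs0)} records, "
                f"{paths[1]} has {len(recs1)}"
            )
        for i, ((id0, s0), (id1, s1)) in enumerate(zip(recs0, recs1)):
            pid = f"p{i}"
            _emit(out, id0, s0, 0, pid)
            _emit(out, id1, s1, 1, pid)
    if not out.reads:
        raise ValueError(f"no reads found in {', '.join(map(str, paths))}")
    return out


def _largest_odd_at_most(bound: int, multiple_of_three: bool = False) -> int:
    k = bound
    while k > 0:
        if k % 2 == 1 and (not multiple_of_three or k % 3 == 0):
            return k
        k -= 1
    return 0


def choose_kmer_sizes(read_lengths: Sequence[int], protein_mode: bool = False) -> Tuple[int, int]:
    """Automatic (primary, secondary) k-mer sizes from read lengths.

    Primary k is the largest odd integer at most half the read length;
    secondary k the larger of 21 and the largest odd integer at most a fifth
    of it.  In protein mode both must additionally be multiples of three.
    The representative length is the maximum observed read length.
    """
    if not read_lengths:
        raise ValueError("no read lengths")
    length = max(read_lengths)
    primary = _largest_odd_at_most(length // 2, protein_mode)
    secondary = max(21, _largest_odd_at_most(length // 5, protein_mode))
    if primary < 21:
        raise ValueError(
            f"automatic k-mer size detection fails for read length {length} "
            f"(primary k-mer {primary} < 21); supply k-mer sizes explicitly"
        )
    return primary, secondary


class KmerCounts:
    """Canonical k-mer -> (plus-strand count, minus-strand count) for fixed k.

    An occurrence counts to the plus strand when the k-mer as read equals its
    canonical form (palindromic ties count to plus), to minus otherwise.
    """

    def __init__(self, k: int):
        self.k = k
        self.counts: Dict[str, List[int]] = {}

    def add_occurrence(self, kmer: str) -> None:
        can = canonical(kmer)
        entry = self.counts.setdefault(can, [0, 0])
        if kmer == can:
            entry[0] += 1
        else:
            entry[1] += 1

    def get(self, kmer: str) -> Tuple[int, int]:
        """(plus, minus) counts looked up through the canonical form."""
        entry = self.counts.get(canonical(kmer))
        return (entry[0], entry[1]) if entry else (0, 0)

    def count(self, kmer: str) -> int:
        """Total read count L = plus + minus."""
        p, m = self.get(kmer)
        return p + m

    def __len__(self) -> int:
        return len(self.counts)

    def total_occurrences(self) -> int:
        return sum(p + m for p, m in self.counts.values())


def count_kmers(reads: ReadSet, k: int) -> KmerCounts:
    """Count canonical k-mers over all reads with per-strand attribution."""
    if not any(len(r.sequence) >= k for r in reads):
        raise ValueError(f"k={k} exceeds every read length")
    kc = KmerCounts(k)
    for r in reads:
        for kmer in iter_kmers(r.sequence, k):
            kc.add_occurrence(kmer)
    return kc


class DeBruijnGraph:
    """k-mers with read count >= min_count, queried strand-agnostically.

    Base-extension queries take an *oriented* k-mer (the orientation the path
    is being assembled in) and return surviving single-base extensions with
    the stored per-strand counts of the new k-mer.
    """

    def __init__(self, counts: KmerCounts, min_count: int):
        if min_count < 1:
            raise ValueError("min_count must be >= 1")
        self.k = counts.k
        self.min_count = min_count
        self.counts = counts
        self.kmers = {
            km for km, (p, m) in ((km, c) for km, c in counts.counts.items())
            if p + m >= min_count
        }

    def __contains__(self, kmer: str) -> bool:
        return canonical(kmer) in self.kmers

    def __len__(self) -> int:
        return len(self.kmers)

    def successors(self, kmer: str) -> Dict[str, Tuple[int, int]]:
        """base -> (plus, minus) counts of kmer[1:] + base present in the graph."""
        out: Dict[str, Tuple[int, int]] = {}
        suffix = kmer[1:]
        for b in BASES:
            nk = suffix + b
            if nk in self:
                out[b] = self.counts.get(nk)
        return out

    def predecessors(self, kmer: str) -> Dict[str, Tuple[int, int]]:
        """base -> (plus, minus) counts of base + kmer[:-1] present in the graph."""
        out: Dict[str, Tuple[int, int]] = {}
        prefix = kmer[:-1]
        for b in BASES:
            nk = b + prefix
            if nk in self:
                out[b] = self.counts.get(nk)
        return out

    def extensions(self, kmer: str, direction: str) -> Dict[str, Tuple[int, int]]:
        if direction == "right":
            return self.successors(kmer)
        if direction == "left":
            return self.predecessors(kmer)
        raise ValueError(f"unknown direction {direction!r}")


def build_dbg(counts: KmerCounts, min_count: int) -> DeBruijnGraph:
    """Graph of exactly the k-mers whose total count reaches ``min_count``."""
    return DeBruijnGraph(counts, min_count)


@dataclass
class InsertSizeRange:
    """Insert-size bounds derived from de-novo mate joining through the graph."""

    min_len: int
    max_len: int
    samples: int = 0

    def __post_init__(self):
        if not (0 < self.min_len <= self.max_len):
            raise ValueError(f"invalid insert range [{self.min_len}, {self.max_len}]")

    def __contains__(self, length: int) -> bool:
        return self.min_len <= length <= self.max_len


def _join_pair(m0: str, m1: str, graph: DeBruijnGraph, cap: int) -> Optional[int]:
    """Walk right from mate 0 through unambiguous graph extensions until the
    reverse complement of mate 1 forms the suffix; return the joined length."""
    k = graph.k
    target = revcomp(m1)
    if len(m0) < k or len(m1) < k:
        return None
    seq = m0
    if seq[-k:] not in graph:
        return None
    while len(seq) <= cap:
        if len(seq) >= len(target) and seq.endswith(target) and len(seq) >= len(m0):
            return len(seq)
        succ = graph.successors(seq[-k:])
        if len(succ) != 1:
            return None
        seq += next(iter(succ))
    return None


def estimate_insert_size(
    reads: ReadSet,
    graph: DeBruijnGraph,
    cap: int = 1000,
    min_joins: int = 100,
) -> InsertSizeRange:
    """Estimate the insert-size range by joining mates through the graph.

    Each pair is walked from the end of mate 0 by single-choice extensions
    for at most ``cap`` bases; the range reported is the 1st-99th percentile
    of joined lengths.  With fewer than ``min_joins`` successful joins a
    conservative fallback range [read_len, 2*cap] is returned with a warning.
    """
    joined: List[int] = []
    for r0, r1 in reads.pairs():
        length = _join_pair(r0.sequence, r1.sequence, graph, cap)
        if length is not None:
            joined.append(length)
    if len(joined) < max(1, min_joins):
        read_len = reads.max_length()
        warnings.warn(
            f"only {len(joined)} mate pairs joined (need {min_joins}); "
            f"falling back to insert range [{read_len}, {2 * cap}]"
        )
        return InsertSizeRange(read_len, 2 * cap, samples=len(joined))
    lo = int(np.floor(np.percentile(joined, 1)))
    hi = int(np.ceil(np.percentile(joined, 99)))
    return InsertSizeRange(lo, hi, samples=len(joined))
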