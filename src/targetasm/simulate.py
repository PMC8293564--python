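"""Synthetic fixture generator: targets, homologs, haplotypes and Illumina-like
paired reads with controllable substitution errors, strand-biased errors and
carryover contaminants.

The generator emulates the read properties the assembler is built around:
fixed-length paired reads, normally distributed inserts, substitution-only
errors, optional systematic plus-strand-only errors at one locus (to exercise
the strand-balance extension filter) and a configurable fraction of pairs
drawn from an unrelated sequence.  It does not model quality-score decay,
indel errors, GC bias or PCR duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .dna import BASES, revcomp
from .reads import Read, ReadSet
from .targets import translate

_OTHER = {b: [c for c in BASES if c != b] for b in BASES}


@dataclass
class SimConfig:
    """Study conditions for one simulated read set."""

    seed: int = 0
    genome_len: int = 2000
    n_haplotypes: int = 1
    snp_rate: float = 0.0
    target_identity: float = 0.85
    coverage: float = 30.0
    read_len: int = 150
    insert_mean: int = 300
    insert_sd: float = 10.0
    error_rate: float = 0.0
    strand_biased_error: bool = False
    strand_bias_locus: Optional[int] = None
    strand_bias_rate: float = 0.1
    contaminant_fraction: float = 0.0

    def __post_init__(self):
        for name in ("snp_rate", "target_identity", "error_rate",
                     "strand_bias_rate", "contaminant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def mutate_target(sequence: str, identity: float, seed=0) -> str:
    """A homolog at the requested identity: substitutions placed uniformly.

    The number of substituted positions is round((1 - identity) * length);
    every substitution changes the base.
    """
    rng = _rng(seed)
    n_sub = int(round((1.0 - identity) * len(sequence)))
    positions = rng.choice(len(sequence), size=n_sub, replace=False)
    seq = list(sequence)
    for p in positions:
        seq[p] = _OTHER[seq[p]][rng.integers(0, 3)]
    return "".join(seq)


def mutate_protein_target(cds: str, identity: float, seed=0, genetic_code: int = 1) -> str:
    """Protein homolog: mutate the CDS at the nucleotide level to the given
    identity and report the translation.

    Substitutions that would create an internal stop codon are redrawn at
    the same position (or skipped when every alternative stops), so the
    realized identity can be marginally above the request.
    """
    rng = _rng(seed)
    n_sub = int(round((1.0 - identity) * len(cds)))
    positions = rng.choice(len(cds), size=n_sub, replace=False)
    seq = list(cds)
    last_codon_start = (len(cds) // 3 - 1) * 3
    for p in positions:
        alts = list(_OTHER[seq[p]])
        rng.shuffle(alts)
        start = (p // 3) * 3
        for alt in alts:
            codon = seq[start : start + 3]
            codon[p - start] = alt
            if start == last_codon_start or translate("".join(codon), genetic_code) != "*":
                seq[p] = alt
                break
    prot = translate("".join(seq), genetic_code)
    return prot[:-1] if prot.endswith("*") else prot


def plant_snps(sequence: str, positions: Sequence[int], seed=0) -> str:
    """Second haplotype: substitute the base at each given position."""
    rng = _rng(seed)
    seq = list(sequence)
    for p in positions:
        seq[p] = _OTHER[seq[p]][rng.integers(0, 3)]
    return "".join(seq)


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = _OTHER[chars[i]][rng.integers(0, 3)]
    return "".join(chars)


def simulate_reads(haplotypes: Sequence[str], config: SimConfig) -> ReadSet:
    """Paired reads from one or more haplotypes under the given conditions.

    The pair count is round(genome_len * coverage / (2 * read_len)); insert
    lengths are Normal(insert_mean, insert_sd) truncated to at least one read
    length; mate 0 reports the plus strand of the fragment, mate 1 the
    reverse complement of its other end.  A strand-biased error substitutes a
    fixed base at ``strand_bias_locus`` in a fraction of the mates observing
    the locus on the plus strand only.
    """
    rng = np.random.default_rng(config.seed)
    n_pairs = int(round(config.genome_len * config.coverage / (2 * config.read_len)))
    out = ReadSet()
    locus = config.strand_bias_locus
    if config.strand_biased_error and locus is None:
        locus = config.genome_len // 2
    bias_alt: Optional[str] = None
    if config.strand_biased_error:
        ref_base = haplotypes[0][locus]
        bias_alt = _OTHER[ref_base][0]
    n_cont = int(round(config.contaminant_fraction * n_pairs))
    contaminant = (
        random_sequence(max(config.genome_len, 2 * config.read_len + 1), rng)
        if n_cont else ""
    )
    for i in range(n_pairs):
        if i < n_pairs - n_cont:
            hap = haplotypes[int(rng.integers(0, len(haplotypes)))]
            is_cont = False
        else:
            hap = contaminant
            is_cont = True
        insert = int(round(rng.normal(config.insert_mean, config.insert_sd)))
        insert = max(config.read_len, min(insert, len(hap)))
        start = int(rng.integers(0, len(hap) - insert + 1))
        frag = hap[start : start + insert]
        m0 = frag[: config.read_len]
        m1 = revcomp(frag[-config.read_len :])
        m0 = _apply_errors(m0, rng, config.error_rate)
        m1 = _apply_errors(m1, rng, config.error_rate)
        if (
            bias_alt is not None
            and not is_cont
            and start <= locus < start + len(m0)
            and rng.random() < config.strand_bias_rate
        ):
            # plus-strand observation only: the error goes into mate 0 alone
            j = locus - start
            m0 = m0[:j] + bias_alt + m0[j + 1 :]
        pid = f"p{i}"
        out.add(Read(f"r{i}/1", m0, 0, pid))
        out.add(Read(f"r{i}/2", m1, 1, pid))
    return out


def tiled_reads(
    sequence: str, read_len: int, step: int, skip: Sequence[int] = ()
) -> ReadSet:
    """Deterministic unpaired tiling of a sequence, optionally dropping tiles.

    Useful for coverage-dip fixtures: the overlap between consecutive tiles
    is read_len - step, so k-mers longer than the overlap plus one are absent
    across tile junctions.
    """
    out = ReadSet()
    idx = 0
    for start in range(0, len(sequence) - read_len + 1, step):
        if idx not in skip:
            out.add(Read(f"t{idx}", sequence[start : start + read_len]))
        idx += 1
    return out


def write_fastq_pairs(reads: ReadSet, path0: str, path1: str) -> None:
    """Write complete pairs as two FASTQ files with constant quality."""
    with open(path0, "w") as f0, open(path1, "w") as f1:
        for r0, r1 in reads.pairs():
            f0.write(f"@{r0.id}\n{r0.sequence}\n+\n{'I' * len(r0.sequence)}\n")
            f1.write(f"@{r1.id}\n{r1.sequence}\n+\n{'I' * len(r1.sequence)}\n")


def write_fasta_reads(reads: ReadSet, path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.sequence}\n")
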