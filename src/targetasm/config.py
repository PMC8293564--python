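"""Shared assembly parameters.

One flat parameter block mirrors the command-line surface of the tool; each
field is consumed by the stage named in its comment.  The "low-coverage"
preset changes min_count and aligned_count to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional


@dataclass
class Params:
    # graph construction
    min_count: int = 2

    # seeding
    fraction: float = 0.05           # per-position seed count fraction vs max
    kmer_complexity: int = 2000      # seeds per position before hard-masking
    protect_reference_ends: bool = False
    end_protect_nt: int = 100        # bp from a target end that suspends the
    end_protect_aa: int = 34         # extensibility check (nt / aa coordinates)

    # extension
    extension_fraction: float = 0.1  # noise threshold vs max extension count
    strand_fraction: float = 0.1     # minor-strand share below which a choice
                                     # is "predominantly one strand"
    secondary_kmer_threshold: int = 1
    buf_length: int = 200
    max_fork_density: float = 0.1
    branch_budget: int = 10000       # per-seed guard beyond fork density

    # read/pair filtering
    aligned_count: int = 2
    not_aligned_count: int = 3
    not_aligned_len: int = 10
    max_path: int = 1000
    rollback_factor: int = 15

    # reporting
    target_coverage: float = 0.5
    min_hit_len: Optional[int] = None
    max_variants: int = 1000
    extend_ends: bool = False
    keep_subgraphs: bool = False
    collapse_snps: bool = False

    # insert-size estimation
    insert_cap: int = 1000
    min_insert_joins: int = 100

    @property
    def not_aligned_half(self) -> int:
        """Y = floor(not_aligned_len / 2)."""
        return self.not_aligned_len // 2

    def low_coverage(self) -> "Params":
        """Preset for low-coverage read sets: min_count 1, aligned_count 1."""
        return replace(self, min_count=1, aligned_count=1)
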