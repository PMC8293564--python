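"""Small DNA helpers shared across the package."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement.

    Both strands of a duplex share one canonical record; ties (palindromes,
    which only occur for even k) resolve to the k-mer itself.
    """
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


def iter_kmers(seq: str, k: int):
    """Yield every k-long window of ``seq`` that is free of N."""
    n = len(seq)
    if n < k:
        return
    # scan once for N so the common (N-free) case is a fast slice loop
    if "N" in seq:
        last_n = -1
        for i, c in enumerate(seq):
            if c == "N":
                last_n = i
            if i >= k - 1 and last_n <= i - k:
                yield seq[i - k + 1 : i + 1]
    else:
        for i in range(n - k + 1):
            yield seq[i : i + k]
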