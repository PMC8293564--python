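"""Target sequences, scoring schemes, translation, and incremental path alignment.

The aligner grows a banded affine-gap dynamic-programming frontier one path
symbol at a time (one base for nucleotide targets, one translated residue for
protein targets) and reports after every symbol whether the alignment score
improved, stayed within the drop-off of the best score, or fell far enough
below it that the path must be clipped back to the best scoring position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .dna import revcomp

NEG = -(1 << 30)

_NT_ALPHABET = set("ACGTN")
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZU")


def _load_blosum62() -> Dict[str, Dict[str, int]]:
    arr = substitution_matrices.load("BLOSUM62")
    alpha = arr.alphabet
    return {a: {b: int(arr[a, b]) for b in alpha} for a in alpha}


BLOSUM62: Dict[str, Dict[str, int]] = _load_blosum62()


@dataclass
class Target:
    """One nucleotide or protein target with a mutable hard mask."""

    id: str
    alphabet: str  # "nt" | "aa"
    sequence: str
    mask: List[bool] = field(default_factory=list)

    def __post_init__(self):
        if not self.mask:
            self.mask = [False] * len(self.sequence)
        if len(self.mask) != len(self.sequence):
            raise ValueError("mask length must equal sequence length")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mask_char(self) -> str:
        return "N" if self.alphabet == "nt" else "X"

    def masked_sequence(self) -> str:
        """Sequence with hard-masked positions rendered as N (nt) or X (aa)."""
        if not any(self.mask):
            return self.sequence
        mc = self.mask_char
        return "".join(mc if m else c for c, m in zip(self.sequence, self.mask))

    def apply_mask(self, start: int, length: int) -> None:
        for i in range(max(0, start), min(len(self.mask), start + length)):
            self.mask[i] = True

    def is_masked(self, start: int, length: int) -> bool:
        return any(self.mask[max(0, start) : start + length])


def load_targets(path: str, alphabet: str) -> List[Target]:
    """Parse a FASTA file of targets in file order; duplicate ids are an error."""
    if alphabet not in ("nt", "aa"):
        raise ValueError("alphabet must be 'nt' or 'aa'")
    from Bio import SeqIO

    targets: List[Target] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate target id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if alphabet == "aa":
            seq = seq.rstrip("*")
            if "*" in seq:
                raise ValueError(f"internal stop '*' in protein target {rec.id!r}")
            bad = set(seq) - _AA_ALPHABET
        else:
            bad = set(seq) - _NT_ALPHABET
        if bad:
            raise ValueError(f"illegal characters {sorted(bad)} in target {rec.id!r}")
        if not seq:
            raise ValueError(f"empty target sequence {rec.id!r}")
        mask = [c == ("N" if alphabet == "nt" else "X") for c in seq]
        targets.append(Target(rec.id, alphabet, seq, mask))
    if not targets:
        raise ValueError(f"no targets found in {path}")
    return targets


@dataclass
class ScoringScheme:
    """Alignment parameters for one mode.

    Nucleotide mode uses match ``reward`` and mismatch ``penalty`` (stored
    positive); protein mode uses BLOSUM62 in integer half-bit units.  A gap
    of length L costs gap_open + L * gap_extend.  ``word`` is the exact-match
    word length (in bases) used by seeding.
    """

    mode: str  # "nt" | "aa"
    reward: int = 1
    penalty: int = 2
    gap_open: int = 5
    gap_extend: int = 2
    drop_off: int = 25
    word: int = 8
    matrix: Optional[Dict[str, Dict[str, int]]] = None
    frameshift_open: int = 30
    allow_frameshifts: bool = False
    genetic_code: int = 1

    @classmethod
    def nucleotide(cls, **kw) -> "ScoringScheme":
        return cls(mode="nt", **kw)

    @classmethod
    def protein(cls, genetic_code: int = 1, **kw) -> "ScoringScheme":
        defaults = dict(
            mode="aa",
            gap_open=11,
            gap_extend=1,
            drop_off=50,
            word=12,
            matrix=BLOSUM62,
            genetic_code=genetic_code,
        )
        defaults.update(kw)
        return cls(**defaults)

    def __post_init__(self):
        if self.mode not in ("nt", "aa"):
            raise ValueError("mode must be 'nt' or 'aa'")
        if self.mode == "aa" and self.matrix is None:
            self.matrix = BLOSUM62
        if self.allow_frameshifts:
            raise NotImplementedError("frameshift-tolerant protein alignment is not implemented")
        if min(self.reward, self.penalty, self.gap_open, self.gap_extend, self.drop_off) <= 0:
            raise ValueError("scores and penalties must be positive")

    def score(self, q: str, t: str) -> int:
        """Substitution score of path symbol q against target symbol t."""
        if self.mode == "nt":
            if q == "N" or t == "N":
                return -self.penalty
            return self.reward if q == t else -self.penalty
        row = self.matrix.get(q)
        if row is None or t not in row:
            return -4  # unknown symbol: worst BLOSUM62 substitution
        return row[t]

    @property
    def band(self) -> int:
        """Half-width of the DP band; drop-off bounds attainable gap offsets."""
        return self.drop_off // self.gap_extend + 2


_CODON_CACHE: Dict[int, Dict[str, str]] = {}


def _codon_table(genetic_code: int) -> Dict[str, str]:
    table = _CODON_CACHE.get(genetic_code)
    if table is None:
        ct = CodonTable.unambiguous_dna_by_id[genetic_code]
        table = dict(ct.forward_table)
        for stop in ct.stop_codons:
            table[stop] = "*"
        _CODON_CACHE[genetic_code] = table
    return table


def translate(nt: str, genetic_code: int = 1) -> str:
    """Translate a DNA string under an NCBI genetic-code table; stops become '*'."""
    if len(nt) % 3 != 0:
        raise ValueError(f"length {len(nt)} is not a multiple of 3")
    if not nt:
        return ""
    if "N" in nt:
        raise ValueError("cannot translate sequence containing N")
    table = _codon_table(genetic_code)
    return "".join(table[nt[i : i + 3]] for i in range(0, len(nt), 3))


def self_score(fragment: str, matrix: Optional[Dict[str, Dict[str, int]]] = None) -> int:
    """Score of a protein fragment aligned to itself (sum of diagonal entries)."""
    if not fragment:
        raise ValueError("empty fragment")
    mat = matrix or BLOSUM62
    return sum(mat[c][c] for c in fragment)


class ExtensionAligner:
    """Incremental banded affine-gap DP of a growing query against a fixed window.

    The query is anchored at the window start (the target coordinate right
    after the seed); the alignment may end at any window position.  After each
    appended symbol the frontier row is advanced; ``current_score`` is the
    best cell of that row and ``best_score``/``best_qpos`` track the running
    optimum over all rows.
    """

    __slots__ = (
        "window", "scheme", "band", "j", "M", "Ix", "Iy",
        "best_score", "best_qpos", "best_tpos", "current_score",
    )

    def __init__(self, window: str, scheme: ScoringScheme):
        self.window = window
        self.scheme = scheme
        self.band = scheme.band
        m = min(len(window), self.band)
        go, ge = scheme.gap_open, scheme.gap_extend
        self.j = 0
        # row arrays index target coordinate i in [ilo(j), ihi(j)]
        self.M = [0] + [NEG] * m
        self.Ix = [NEG] * (m + 1)
        self.Iy = [NEG] + [-(go + i * ge) for i in range(1, m + 1)]
        self.best_score = 0
        self.best_qpos: Optional[int] = None  # query symbols at the best row
        self.best_tpos: Optional[int] = None  # window coordinate of the best cell
        self.current_score = 0

    def _bounds(self, j: int) -> Tuple[int, int]:
        return max(0, j - self.band), min(len(self.window), j + self.band)

    def copy(self) -> "ExtensionAligner":
        new = object.__new__(ExtensionAligner)
        new.window = self.window
        new.scheme = self.scheme
        new.band = self.band
        new.j = self.j
        new.M = self.M[:]
        new.Ix = self.Ix[:]
        new.Iy = self.Iy[:]
        new.best_score = self.best_score
        new.best_qpos = self.best_qpos
        new.best_tpos = self.best_tpos
        new.current_score = self.current_score
        return new

    def extend(self, symbol: str) -> str:
        """Advance one query symbol; returns 'improved', 'within_dropoff' or 'clip'."""
        sc = self.scheme
        go_ge = sc.gap_open + sc.gap_extend
        ge = sc.gap_extend
        pilo, _ = self._bounds(self.j)
        self.j += 1
        ilo, ihi = self._bounds(self.j)
        width = ihi - ilo + 1
        nM = [NEG] * width
        nIx = [NEG] * width
        nIy = [NEG] * width
        pM, pIx, pIy = self.M, self.Ix, self.Iy

        def prev(arr: List[int], i: int) -> int:
            idx = i - pilo
            if 0 <= idx < len(arr):
                return arr[idx]
            return NEG

        win = self.window
        for i in range(ilo, ihi + 1):
            x = i - ilo
            if i >= 1:
                diag = max(prev(pM, i - 1), prev(pIx, i - 1), prev(pIy, i - 1))
                if diag > NEG // 2:
                    nM[x] = diag + sc.score(symbol, win[i - 1])
            up_m, up_x = prev(pM, i), prev(pIx, i)
            cand = max(
                up_m - go_ge if up_m > NEG // 2 else NEG,
                up_x - ge if up_x > NEG // 2 else NEG,
            )
            nIx[x] = cand
            if x >= 1:
                left_m, left_y = nM[x - 1], nIy[x - 1]
                nIy[x] = max(
                    left_m - go_ge if left_m > NEG // 2 else NEG,
                    left_y - ge if left_y > NEG // 2 else NEG,
                )
        self.M, self.Ix, self.Iy = nM, nIx, nIy
        cur = NEG
        cur_i = None
        for x in range(width):
            cell = max(nM[x], nIx[x], nIy[x])
            if cell > cur:
                cur = cell
                cur_i = ilo + x
        self.current_score = cur
        if cur > self.best_score:
            self.best_score = cur
            self.best_qpos = self.j
            self.best_tpos = cur_i
            return "improved"
        if self.best_score - cur <= sc.drop_off:
            return "within_dropoff"
        return "clip"


class AlignmentState:
    """Path-alignment state: wraps the aligner and, in protein mode, a codon buffer.

    ``best_path_pos`` is reported in path bases.  For protein targets bases
    are buffered three at a time and the DP advances one residue per codon;
    ``reverse_codons`` handles leftward extension where bases arrive in
    right-to-left order.
    """

    def __init__(self, window: str, scheme: ScoringScheme, reverse_codons: bool = False):
        self.scheme = scheme
        self.aligner = ExtensionAligner(window, scheme)
        self.protein = scheme.mode == "aa"
        self.reverse_codons = reverse_codons
        self.codon_buffer = ""

    def copy(self) -> "AlignmentState":
        new = object.__new__(AlignmentState)
        new.scheme = self.scheme
        new.aligner = self.aligner.copy()
        new.protein = self.protein
        new.reverse_codons = self.reverse_codons
        new.codon_buffer = self.codon_buffer
        return new

    @property
    def best_score(self) -> int:
        return self.aligner.best_score

    @property
    def current_score(self) -> int:
        return self.aligner.current_score

    @property
    def best_target_pos(self) -> Optional[int]:
        return self.aligner.best_tpos

    @property
    def best_path_pos(self) -> Optional[int]:
        """Best scoring position in path bases (None while unknown)."""
        q = self.aligner.best_qpos
        if q is None:
            return None
        return q * 3 if self.protein else q

    def extend(self, base: str) -> str:
        if not self.protein:
            return self.aligner.extend(base)
        self.codon_buffer += base
        if len(self.codon_buffer) < 3:
            return "within_dropoff"
        codon = self.codon_buffer[::-1] if self.reverse_codons else self.codon_buffer
        self.codon_buffer = ""
        try:
            residue = translate(codon, self.scheme.genetic_code)
        except ValueError:
            residue = "X"
        return self.aligner.extend(residue)


def extend_alignment(state: AlignmentState, new_base: str) -> Tuple[AlignmentState, str]:
    """Functional wrapper: advance a copy of ``state`` by one base."""
    new = state.copy()
    verdict = new.extend(new_base)
    return new, verdict
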