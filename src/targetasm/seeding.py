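"""Seed k-mer discovery: word-hash candidate location, good-alignment tests,
per-position count filtering, and hard-masking of hyper-repetitive positions.

A graph k-mer becomes a seed only when it good-aligns at exactly one target
position, is extensible in the graph on both sides, has read count above one,
and is not drowned out (or crowded out) by other k-mers at the same position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .config import Params
from .dna import revcomp
from .reads import DeBruijnGraph
from .targets import ScoringScheme, Target, self_score, translate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Seed:
    """An anchoring k-mer: canonical form, oriented (target-strand) sequence,
    unique target position, orientation and read count."""

    kmer: str          # canonical form (graph key)
    seq: str           # oriented so that seq aligns the target forward
    target_pos: int    # 0-based; nt coordinate for nt targets, residue for aa
    orientation: str   # "forward" | "reverse"
    count: int


def good_alignment_nt(
    S: str, target: Target, p: int, scheme: ScoringScheme, orientation: str = "forward"
) -> bool:
    """Nucleotide good-alignment test of k-mer S at target position p.

    The word rule demands an exact match of the last ``word`` bases (forward)
    or, for the reverse orientation, the first ``word`` bases of the reverse
    complement; the rest of the k-mer must reach M > min(k-1, V) Hamming
    matches where V = floor(k/10) + k*penalty/(reward+penalty).
    """
    k = len(S)
    if p < 0 or p + k > len(target):
        return False
    if target.is_masked(p, k):
        return False
    R = target.sequence[p : p + k]
    s = S if orientation == "forward" else revcomp(S)
    w = scheme.word
    if orientation == "forward":
        if s[k - w :] != R[k - w :]:
            return False
    else:
        if s[:w] != R[:w]:
            return False
    matches = sum(1 for a, b in zip(s, R) if a == b)
    V = k // 10 + k * scheme.penalty / (scheme.reward + scheme.penalty)
    return matches > min(k - 1, V)


def good_alignment_prot(
    S: str, target: Target, p: int, scheme: ScoringScheme, orientation: str = "forward"
) -> bool:
    """Protein good-alignment test of nucleotide k-mer S at residue position p.

    Requires an exact match of word/3 residues at the appropriate end of the
    translation and a gap-free BLOSUM62 score above 0.75 of the target
    fragment's self-score.
    """
    k = len(S)
    if k % 3 != 0:
        raise ValueError("protein-mode k-mer length must be a multiple of 3")
    kaa = k // 3
    if p < 0 or p + kaa > len(target):
        return False
    if target.is_masked(p, kaa):
        return False
    R = target.sequence[p : p + kaa]
    s = S if orientation == "forward" else revcomp(S)
    try:
        T = translate(s, scheme.genetic_code)
    except ValueError:
        return False
    waa = scheme.word // 3
    if orientation == "forward":
        if T[kaa - waa :] != R[kaa - waa :]:
            return False
    else:
        if T[:waa] != R[:waa]:
            return False
    mat = scheme.matrix
    r_align = sum(mat.get(R[i], {}).get(T[i], -4) for i in range(kaa))
    return r_align > 0.75 * self_score(R, mat)


def _word_index(target: Target, k: int, scheme: ScoringScheme) -> Dict[str, List[Tuple[int, str]]]:
    """Map word-key -> [(position, orientation)] for every unmasked window.

    For nt targets both orientations key off the last ``word`` bases of the
    stored k-mer (forward: last word of the window; reverse: revcomp of the
    first word), matching a hash built over k-mer suffixes.
    """
    idx: Dict[str, List[Tuple[int, str]]] = {}
    w = scheme.word
    seq = target.sequence
    if target.alphabet == "nt":
        span = k
        for p in range(len(seq) - span + 1):
            if target.is_masked(p, span):
                continue
            fwd_key = seq[p + k - w : p + k]
            idx.setdefault(fwd_key, []).append((p, "forward"))
            rev_key = revcomp(seq[p : p + w])
            idx.setdefault(rev_key, []).append((p, "reverse"))
    else:
        kaa, waa = k // 3, w // 3
        for p in range(len(seq) - kaa + 1):
            if target.is_masked(p, kaa):
                continue
            idx.setdefault("F" + seq[p + kaa - waa : p + kaa], []).append((p, "forward"))
            idx.setdefault("R" + seq[p : p + waa], []).append((p, "reverse"))
    return idx


def _candidate_alignments(
    kmer: str, idx, target: Target, scheme: ScoringScheme
) -> List[Tuple[int, str]]:
    """All (position, orientation) where the canonical k-mer good-aligns."""
    hits: List[Tuple[int, str]] = []
    if target.alphabet == "nt":
        w = scheme.word
        for p, orient in idx.get(kmer[-w:], ()):
            if good_alignment_nt(kmer, target, p, scheme, orient):
                hits.append((p, orient))
    else:
        waa = scheme.word // 3
        try:
            t_fwd = translate(kmer, scheme.genetic_code)
            t_rev = translate(revcomp(kmer), scheme.genetic_code)
        except ValueError:
            return hits
        for p, orient in idx.get("F" + t_fwd[-waa:], ()):
            if orient == "forward" and good_alignment_prot(kmer, target, p, scheme, orient):
                hits.append((p, orient))
        for p, orient in idx.get("R" + t_rev[:waa], ()):
            if orient == "reverse" and good_alignment_prot(kmer, target, p, scheme, orient):
                hits.append((p, orient))
    return hits


class _Extensibility:
    """Memoized existential DFS: can an oriented k-mer grow ``need`` bases?"""

    def __init__(self, dbg: DeBruijnGraph, need: int):
        self.dbg = dbg
        self.need = need
        self.cache: Dict[Tuple[str, str], bool] = {}

    def check(self, kmer: str, direction: str) -> bool:
        if self.need <= 0:
            return True
        key = (kmer, direction)
        hit = self.cache.get(key)
        if hit is not None:
            return hit
        ok = self._dfs(kmer, direction, self.need, {kmer})
        self.cache[key] = ok
        return ok

    def _dfs(self, kmer: str, direction: str, remaining: int, on_path: set) -> bool:
        if remaining <= 0:
            return True
        full = self.cache.get((kmer, direction))
        if full:  # known to extend the full distance from here
            return True
        for b in self.dbg.extensions(kmer, direction):
            nk = kmer[1:] + b if direction == "right" else b + kmer[:-1]
            if nk in on_path:
                # a cycle can supply unlimited length
                return True
            on_path.add(nk)
            if self._dfs(nk, direction, remaining - 1, on_path):
                on_path.discard(nk)
                return True
            on_path.discard(nk)
        return False


def find_seeds(
    dbg: DeBruijnGraph,
    target: Target,
    scheme: ScoringScheme,
    params: Optional[Params] = None,
) -> Tuple[List[Seed], Target]:
    """All seed k-mers for a target, plus the target with any new hard masks.

    Positions crowded by ``kmer_complexity`` or more distinct qualifying
    k-mers lose all their seeds and have the k-length window starting there
    hard-masked.
    """
    params = params or Params()
    k = dbg.k
    protein = target.alphabet == "aa"
    idx = _word_index(target, k, scheme)
    # each seed must admit a 100-base extension beyond the k-mer on each side
    ext = _Extensibility(dbg, 100)
    kaa = k // 3 if protein else None
    tlen = len(target)
    end_protect = params.end_protect_aa if protein else params.end_protect_nt
    span = kaa if protein else k

    by_pos: Dict[int, List[Seed]] = {}
    for kmer in sorted(dbg.kmers):
        hits = _candidate_alignments(kmer, idx, target, scheme)
        if len(hits) != 1:
            if len(hits) > 1:
                logger.debug("k-mer %s good-aligns at %d positions; not a seed", kmer, len(hits))
            continue
        p, orient = hits[0]
        count = dbg.counts.count(kmer)
        if count <= 1:
            continue
        oriented = kmer if orient == "forward" else revcomp(kmer)
        # extensibility on each side, possibly suspended near target ends
        left_protected = params.protect_reference_ends and p < end_protect
        right_protected = (
            params.protect_reference_ends and (tlen - (p + span)) < end_protect
        )
        if not left_protected and not ext.check(oriented, "left"):
            continue
        if not right_protected and not ext.check(oriented, "right"):
            continue
        by_pos.setdefault(p, []).append(Seed(kmer, oriented, p, orient, count))

    seeds: List[Seed] = []
    for p in sorted(by_pos):
        group = by_pos[p]
        n_max = max(s.count for s in group)
        group = [s for s in group if s.count >= n_max * params.fraction]
        if len(group) >= params.kmer_complexity:
            target.apply_mask(p, span)
            logger.info(
                "target %s position %d: %d seed k-mers >= kmer_complexity; window hard-masked",
                target.id, p, len(group),
            )
            continue
        seeds.extend(sorted(group, key=lambda s: (s.seq,)))
    return seeds, target
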