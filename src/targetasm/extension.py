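"""Core assembler: grow alignment-guided extensions from seeds through the
primary de Bruijn graph with fork bookkeeping, strand-balance filtering,
drop-off clipping, secondary-graph rescue across coverage dips, anchor
merging of convergent branches and repetitive-region aborts; merge all
accepted paths for one target into a compressed assembled graph.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .config import Params
from .dna import canonical, iter_kmers, revcomp
from .reads import DeBruijnGraph
from .seeding import Seed, find_seeds
from .targets import AlignmentState, ScoringScheme, Target

logger = logging.getLogger(__name__)


def _filter_candidates(
    cands: Dict[str, Tuple[int, int]], params: Params
) -> List[str]:
    """Apply noise and strand-balance filters; order by count desc, then base.

    Choices with total count below extension_fraction of the maximum are
    noise.  If more than one choice survives and at least one has balanced
    strand counts, choices seen predominantly on one strand are dropped.
    """
    if not cands:
        return []
    totals = {b: p + m for b, (p, m) in cands.items()}
    mx = max(totals.values())
    kept = [b for b in cands if totals[b] >= mx * params.extension_fraction]
    if len(kept) > 1:
        def balanced(b: str) -> bool:
            p, m = cands[b]
            t = p + m
            return p > 0 and m > 0 and min(p, m) >= params.strand_fraction * t

        if any(balanced(b) for b in kept):
            kept = [b for b in kept if balanced(b)]
    return sorted(kept, key=lambda b: (-totals[b], b))


def _step_kmer(kmer: str, base: str, direction: str) -> str:
    return kmer[1:] + base if direction == "right" else base + kmer[:-1]


def classify_extension(
    dbg_primary: DeBruijnGraph,
    kmer: str,
    params: Params,
    direction: str = "right",
) -> Tuple[str, List[str]]:
    """Classify the extension of an oriented k-mer in the primary graph.

    Returns ('dead_end', []), ('single', [base]) or ('fork', bases) with
    fork branches ordered maximum-count-first, ties lexicographic.
    """
    kept = _filter_candidates(dbg_primary.extensions(kmer, direction), params)
    if not kept:
        return "dead_end", []
    if len(kept) == 1:
        return "single", kept
    return "fork", kept


def try_secondary_rescue(
    path_seq: str,
    dbg_secondary: DeBruijnGraph,
    params: Params,
    direction: str = "right",
) -> List[str]:
    """Candidate bases from the secondary graph at the path's terminal
    (secondary_k - 1)-mer; the caller reverts to the primary k afterwards."""
    sk = dbg_secondary.k
    if len(path_seq) < sk - 1:
        return []
    cands: Dict[str, Tuple[int, int]] = {}
    if direction == "right":
        ctx = path_seq[-(sk - 1):]
        for b in "ACGT":
            nk = ctx + b
            if nk in dbg_secondary:
                cands[b] = dbg_secondary.counts.get(nk)
    else:
        ctx = path_seq[: sk - 1]
        for b in "ACGT":
            nk = b + ctx
            if nk in dbg_secondary:
                cands[b] = dbg_secondary.counts.get(nk)
    return _filter_candidates(cands, params)


@dataclass(frozen=True)
class DirectionalPath:
    """One finalized extension: bases in extension order (leftward order for
    left extensions), fork positions (1-based base indices, clip points
    included) and whether the branch ended by merging into an anchor."""

    bases: str
    fork_positions: Tuple[int, ...]
    merged: bool = False


@dataclass
class DirectionalResult:
    paths: List[DirectionalPath] = field(default_factory=list)
    aborted: bool = False


def fork_density_abort(fork_positions: Sequence[int], length: int, params: Params) -> bool:
    """True when the trailing-window fork density strictly exceeds the limit.

    The window is buf_length, or the whole path when shorter.
    """
    if length <= 0:
        return False
    window = min(length, params.buf_length)
    count = sum(1 for f in fork_positions if f > length - window)
    return count / window > params.max_fork_density


class _Extender:
    """Depth-first branch exploration for one seed and one direction."""

    def __init__(
        self,
        seed: Seed,
        direction: str,
        dbg_primary: DeBruijnGraph,
        dbg_secondary: Optional[DeBruijnGraph],
        target: Target,
        scheme: ScoringScheme,
        params: Params,
    ):
        self.seed = seed
        self.direction = direction
        self.dbg_p = dbg_primary
        self.dbg_s = dbg_secondary
        self.target = target
        self.scheme = scheme
        self.params = params
        self.k = dbg_primary.k
        self.protein = target.alphabet == "aa"
        self.anchors: Dict[str, int] = {}
        self.result = DirectionalResult()
        self._seen: Set[str] = set()
        self.budget = params.branch_budget

    # -- window ---------------------------------------------------------
    def _window(self) -> str:
        masked = self.target.masked_sequence()
        p = self.seed.target_pos
        span = self.k // 3 if self.protein else self.k
        if self.direction == "right":
            return masked[p + span :]
        return masked[:p][::-1]

    # -- sequence bookkeeping -------------------------------------------
    def _full_seq(self, bases: List[str]) -> str:
        if self.direction == "right":
            return self.seed.seq + "".join(bases)
        return "".join(reversed(bases)) + self.seed.seq

    # -- candidate generation -------------------------------------------
    def _primary_candidates(self, kmer: str) -> List[str]:
        return _filter_candidates(
            self.dbg_p.extensions(kmer, self.direction), self.params
        )

    def _secondary_candidates(self, bases: List[str]) -> List[str]:
        if self.dbg_s is None:
            return []
        return try_secondary_rescue(
            self._full_seq(bases), self.dbg_s, self.params, self.direction
        )

    def _lookahead_ok(self, kmer: str, bases_with_step: str) -> bool:
        """Double-step rule: the new k-mer must itself admit a continuation."""
        if self._primary_candidates(kmer):
            return True
        if self.dbg_s is None:
            return False
        return bool(
            try_secondary_rescue(bases_with_step, self.dbg_s, self.params, self.direction)
        )

    def _candidates(self, kmer: str, bases: List[str]) -> List[str]:
        cands = self._primary_candidates(kmer)
        if not cands:
            cands = self._secondary_candidates(bases)
        elif len(cands) == 1:
            nk = _step_kmer(kmer, cands[0], self.direction)
            if self.dbg_p.counts.count(nk) <= self.params.secondary_kmer_threshold:
                extra = [
                    b for b in self._secondary_candidates(bases) if b != cands[0]
                ]
                cands = cands + extra
        # double-step: keep a base only if the resulting k-mer can continue
        kept = []
        for b in cands:
            nk = _step_kmer(kmer, b, self.direction)
            if self.direction == "right":
                stepped = self._full_seq(bases) + b
            else:
                stepped = b + self._full_seq(bases)
            if self._lookahead_ok(nk, stepped):
                kept.append(b)
        return kept

    # -- finalization ---------------------------------------------------
    def _finalize(self, bases: List[str], state: AlignmentState,
                  forks: List[int], clip_mark: bool, merged: bool = False) -> None:
        best = state.best_path_pos
        if best is None:
            return  # no extension possible in this direction
        if merged:
            # keep everything up to the merge k-mer so the branch reconnects
            kept = bases[:]
            fp = list(forks)
        else:
            kept = bases[:best]
            fp = [f for f in forks if f <= best]
            if clip_mark and best >= 1 and best not in fp:
                fp.append(best)
        path = DirectionalPath("".join(kept), tuple(sorted(fp)), merged)
        if path.bases and path.bases not in self._seen:
            self._seen.add(path.bases)
            self.result.paths.append(path)

    # -- main loop ------------------------------------------------------
    def run(self) -> DirectionalResult:
        start_state = AlignmentState(
            self._window(), self.scheme,
            reverse_codons=(self.protein and self.direction == "left"),
        )
        stack: List[Tuple[List[str], str, AlignmentState, List[int], Optional[str]]] = [
            ([], self.seed.seq, start_state, [], None)
        ]
        while stack:
            bases, cur, state, forks, forced = stack.pop()
            alive = True
            while alive:
                if forced is not None:
                    b, forced = forced, None
                else:
                    self.budget -= 1
                    if self.budget < 0:
                        logger.warning("branch budget exhausted for seed at %d",
                                       self.seed.target_pos)
                        self._finalize(bases, state, forks, clip_mark=False)
                        return self.result
                    cands = self._candidates(cur, bases)
                    if not cands:
                        self._finalize(bases, state, forks, clip_mark=False)
                        alive = False
                        continue
                    if len(cands) > 1:
                        pos = len(bases) + 1
                        forks.append(pos)
                        if fork_density_abort(forks, pos, self.params):
                            logger.info(
                                "fork density abort for seed at target pos %d",
                                self.seed.target_pos,
                            )
                            self.result.aborted = True
                            return self.result
                        for alt in reversed(cands[1:]):
                            stack.append(
                                (bases[:], cur, state.copy(), forks[:], alt)
                            )
                    b = cands[0]
                # take the step
                cur = _step_kmer(cur, b, self.direction)
                verdict = state.extend(b)
                bases.append(b)
                if verdict == "clip":
                    best = state.best_path_pos or 0
                    self._finalize(bases, state, forks, clip_mark=True)
                    # clip stored branch points beyond the best scoring position
                    stack = [it for it in stack if len(it[0]) + 1 <= best]
                    alive = False
                    continue
                # anchor merging of convergent branches
                best = state.best_path_pos
                if best is not None:
                    anchor_t = self.anchors.get(cur)
                    if anchor_t is not None:
                        if anchor_t == state.best_target_pos:
                            self._finalize(bases, state, forks,
                                           clip_mark=False, merged=True)
                            alive = False
                            continue
                    elif len(bases) - best < self.k / 4:
                        self.anchors[cur] = state.best_target_pos
        return self.result


def extend_direction(
    seed: Seed,
    direction: str,
    dbg_primary: DeBruijnGraph,
    dbg_secondary: Optional[DeBruijnGraph],
    target: Target,
    scheme: ScoringScheme,
    params: Optional[Params] = None,
) -> DirectionalResult:
    """All clipped extension paths of one seed in one direction."""
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    return _Extender(
        seed, direction, dbg_primary, dbg_secondary, target, scheme, params or Params()
    ).run()


def merge_at_anchor(
    anchors: Dict[str, int], new_kmer: str, best_path_dist: Optional[int],
    best_target_pos: Optional[int], k: int,
) -> bool:
    """Anchor rule in isolation: registers (new_kmer -> best target position)
    when the distance past the best position is under k/4, and reports True
    when an existing anchor with the same best position is hit (merge)."""
    if best_target_pos is None or best_path_dist is None:
        return False
    existing = anchors.get(new_kmer)
    if existing is not None:
        return existing == best_target_pos
    if best_path_dist < k / 4:
        anchors[new_kmer] = best_target_pos
    return False


class AssembledGraph:
    """GFA-shaped assembly graph: segments plus oriented links with k-1 overlap.

    Segment ids are deterministic; all links are forward-forward because
    every path is assembled in target orientation.
    """

    def __init__(
        self,
        segments: Dict[str, str],
        links: Iterable[Tuple[str, str]],
        k: int,
        origin_target: Optional[str] = None,
        fork_kmers: Iterable[str] = (),
    ):
        self.segments = dict(segments)
        self.links = sorted(set(links))
        self.k = k
        self.origin_target = origin_target
        self.fork_kmers: FrozenSet[str] = frozenset(fork_kmers)
        self.ext: Dict[str, List[int]] = {}  # extend_ends bookkeeping per segment
        self._index()

    def _index(self) -> None:
        self._succ: Dict[str, List[str]] = defaultdict(list)
        self._pred: Dict[str, List[str]] = defaultdict(list)
        for f, t in self.links:
            self._succ[f].append(t)
            self._pred[t].append(f)

    @property
    def overlap(self) -> int:
        return self.k - 1

    def succs(self, sid: str) -> List[str]:
        return self._succ.get(sid, [])

    def preds(self, sid: str) -> List[str]:
        return self._pred.get(sid, [])

    def n_segments(self) -> int:
        return len(self.segments)

    def is_empty(self) -> bool:
        return not self.segments

    def copy(self) -> "AssembledGraph":
        g = AssembledGraph(
            dict(self.segments), list(self.links), self.k,
            self.origin_target, self.fork_kmers,
        )
        g.ext = {k: v[:] for k, v in self.ext.items()}
        return g

    def kmer_set(self, k: int) -> Set[str]:
        """Canonical k-mers of all segments at word size ``k``."""
        out: Set[str] = set()
        for seq in self.segments.values():
            for w in iter_kmers(seq, k):
                out.add(canonical(w))
        return out

    def path_sequence(self, path: Sequence[str]) -> str:
        """Concatenate a segment path honouring the k-1 overlaps."""
        if not path:
            return ""
        seq = self.segments[path[0]]
        for sid in path[1:]:
            seq += self.segments[sid][self.overlap :]
        return seq

    @classmethod
    def from_paths(
        cls,
        paths: Iterable[str],
        k: int,
        origin_target: Optional[str] = None,
        fork_kmers: Iterable[str] = (),
    ) -> "AssembledGraph":
        """Union the k-mer chains of full path sequences and compress unitigs."""
        nodes: Set[str] = set()
        edges: Set[Tuple[str, str]] = set()
        for seq in paths:
            prev = None
            for i in range(len(seq) - k + 1):
                node = seq[i : i + k]
                nodes.add(node)
                if prev is not None:
                    edges.add((prev, node))
                prev = node
        succ: Dict[str, List[str]] = defaultdict(list)
        pred: Dict[str, List[str]] = defaultdict(list)
        for a, b in edges:
            succ[a].append(b)
            pred[b].append(a)

        def is_start(n: str) -> bool:
            ps = pred.get(n, [])
            if len(ps) != 1:
                return True
            return len(succ.get(ps[0], [])) != 1

        visited: Set[str] = set()
        unitigs: List[List[str]] = []
        for n in sorted(nodes):
            if n in visited or not is_start(n):
                continue
            chain = [n]
            visited.add(n)
            cur = n
            while True:
                ss = succ.get(cur, [])
                if len(ss) != 1:
                    break
                nxt = ss[0]
                if len(pred.get(nxt, [])) != 1 or is_start(nxt) or nxt in visited:
                    break
                chain.append(nxt)
                visited.add(nxt)
                cur = nxt
            unitigs.append(chain)
        # leftover nodes belong to perfect cycles
        for n in sorted(nodes):
            if n in visited:
                continue
            chain = [n]
            visited.add(n)
            cur = n
            while True:
                ss = succ.get(cur, [])
                if len(ss) != 1 or ss[0] in visited:
                    break
                chain.append(ss[0])
                visited.add(ss[0])
                cur = ss[0]
            unitigs.append(chain)

        unitigs.sort(key=lambda ch: ch[0])
        start_of: Dict[str, str] = {}
        segments: Dict[str, str] = {}
        ends: Dict[str, str] = {}
        for i, chain in enumerate(unitigs):
            sid = f"s{i + 1}"
            seq = chain[0] + "".join(n[-1] for n in chain[1:])
            segments[sid] = seq
            start_of[chain[0]] = sid
            ends[sid] = chain[-1]
        links = []
        for sid, last in ends.items():
            for nxt in succ.get(last, []):
                links.append((sid, start_of[nxt]))
        return cls(segments, links, k, origin_target, fork_kmers)


def assemble_target(
    target: Target,
    dbg_primary: DeBruijnGraph,
    dbg_secondary: Optional[DeBruijnGraph],
    scheme: ScoringScheme,
    params: Optional[Params] = None,
) -> AssembledGraph:
    """Seed, extend and merge: the assembled graph for one target.

    Seeds are processed in target order; every k-mer traversed by an accepted
    path consumes the matching unused seed.  Paths of all seeds are merged by
    k-mer chain union and compressed into unitig segments.
    """
    params = params or Params()
    seeds, target = find_seeds(dbg_primary, target, scheme, params)
    pool: Dict[str, Seed] = {}
    for s in seeds:
        pool.setdefault(s.kmer, s)
    order = sorted(seeds, key=lambda s: (s.target_pos, s.seq))
    k = dbg_primary.k
    all_paths: List[str] = []
    fork_kmers: Set[str] = set()
    for sd in order:
        if sd.kmer not in pool:
            continue
        del pool[sd.kmer]
        right = extend_direction(sd, "right", dbg_primary, dbg_secondary,
                                 target, scheme, params)
        left = extend_direction(sd, "left", dbg_primary, dbg_secondary,
                                target, scheme, params)
        seqs: List[str] = []
        for p in right.paths:
            seq = sd.seq + p.bases
            seqs.append(seq)
            for f in p.fork_positions:
                fork_kmers.add(seq[f : f + k])
        for p in left.paths:
            seq = p.bases[::-1] + sd.seq
            seqs.append(seq)
            n = len(p.bases)
            for f in p.fork_positions:
                fork_kmers.add(seq[n - f : n - f + k])
        if not right.paths and not left.paths:
            seqs = [sd.seq]
        all_paths.extend(seqs)
        for seq in seqs:
            for w in iter_kmers(seq, k):
                pool.pop(canonical(w), None)
    if not all_paths:
        return AssembledGraph({}, [], k, origin_target=target.id)
    return AssembledGraph.from_paths(
        all_paths, k, origin_target=target.id, fork_kmers=fork_kmers
    )
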