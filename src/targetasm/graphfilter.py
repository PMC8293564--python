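"""Remove assembled-graph connections unsupported by reads and read pairs.

A middle segment C flanked by a fork on each side defines candidate paths
(left choice)-C-(right choice).  Reads containing C confirm a path when their
mismatch-free outward extension covers at least Y bases on both flanks, and
contradict it when one flank is covered, the other gets zero bases, and at
least 2Y unaligned read bases were available.  Pairs apply the same rule with
one mate per fork and the fork separation inside the insert range.  A path
with enough contradiction and too little confirmation is removed by
duplicating C; if segment count inflates past the rollback factor the whole
pass is undone.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .config import Params
from .dna import revcomp
from .extension import AssembledGraph
from .reads import InsertSizeRange, ReadSet

logger = logging.getLogger(__name__)

_ANCHOR = 12  # exact-match anchor length for read placement


@dataclass
class SupportCounts:
    confirm: int = 0
    contradict: int = 0

    def __iadd__(self, other: "SupportCounts") -> "SupportCounts":
        self.confirm += other.confirm
        self.contradict += other.contradict
        return self


@dataclass
class ForkContext:
    """Fig.-1-shaped context: middle segment C with >=2 choices on each side."""

    middle: str
    left_choices: List[str]
    right_choices: List[str]


@dataclass
class CandidatePath:
    """One left-C-right combination expanded to plain sequence.

    ``variants`` are (P, jl, jr) tuples: the expanded sequence and the
    positions of the left and right fork junctions within it (C spans
    P[jl:jr]).  Several variants exist when the flank context itself forks.
    """

    left: str
    right: str
    variants: List[Tuple[str, int, int]]


def _side_contexts(
    graph: AssembledGraph, first: str, side: str, need: int, limit: int
) -> List[str]:
    """Exclusive flank sequences starting from neighbour segment ``first``.

    Walks outward (left: toward predecessors, right: toward successors)
    collecting up to ``need`` exclusive bases per context; forks multiply
    contexts up to ``limit``.
    """
    ov = graph.overlap
    results: List[str] = []
    # item: (sequence built so far, segment to expand next)
    if side == "left":
        start_seq = graph.segments[first][: len(graph.segments[first]) - ov]
    else:
        start_seq = graph.segments[first][ov:]
    stack: List[Tuple[str, str]] = [(start_seq, first)]
    while stack and len(results) < limit:
        seq, sid = stack.pop()
        if len(seq) >= need:
            results.append(seq[-need:] if side == "left" else seq[:need])
            continue
        nxt = graph.preds(sid) if side == "left" else graph.succs(sid)
        if not nxt:
            results.append(seq)
            continue
        for nb in sorted(nxt, reverse=True):
            nseq = graph.segments[nb]
            if side == "left":
                ext = nseq[: len(nseq) - ov]
                stack.append((ext + seq, nb))
            else:
                stack.append((seq + nseq[ov:], nb))
    return sorted(set(results))


def build_candidate_paths(
    graph: AssembledGraph,
    ctx: ForkContext,
    need: int,
    params: Params,
) -> List[CandidatePath]:
    """Expand every left-C-right combination to sequences, shrinking the
    expansion length if the number of sequences would exceed max_path."""
    c_seq = graph.segments[ctx.middle]
    while True:
        lefts = {
            a: _side_contexts(graph, a, "left", need, params.max_path)
            for a in ctx.left_choices
        }
        rights = {
            d: _side_contexts(graph, d, "right", need, params.max_path)
            for d in ctx.right_choices
        }
        n_seq = sum(
            len(lefts[a]) * len(rights[d])
            for a in ctx.left_choices
            for d in ctx.right_choices
        )
        if n_seq <= params.max_path or need <= 2 * params.not_aligned_half:
            break
        need //= 2
    out: List[CandidatePath] = []
    for a in ctx.left_choices:
        for d in ctx.right_choices:
            variants = []
            for ls, rs in itertools.product(lefts[a], rights[d]):
                variants.append((ls + c_seq + rs, len(ls), len(ls) + len(c_seq)))
            out.append(CandidatePath(a, d, variants))
    return out


def _extend_match(read: str, q: int, P: str, jl: int, jr: int) -> Tuple[int, int, int, int]:
    """Mismatch-free outward extension of the C occurrence at read offset q.

    Returns (left aligned, right aligned, left available, right available)
    where aligned counts are matching bases beyond each junction and
    available counts are the read bases that could have matched.
    """
    c_len = jr - jl
    a = 0
    while q - 1 - a >= 0 and jl - 1 - a >= 0 and read[q - 1 - a] == P[jl - 1 - a]:
        a += 1
    d = 0
    while (
        q + c_len + d < len(read)
        and jr + d < len(P)
        and read[q + c_len + d] == P[jr + d]
    ):
        d += 1
    return a, d, q, len(read) - q - c_len


def support_by_reads(
    path: CandidatePath, c_seq: str, reads: Sequence[str], Y: int
) -> SupportCounts:
    """Confirm/contradict counts from single reads containing segment C."""
    counts = SupportCounts()
    for seq in reads:
        best_confirm = False
        best_contradict = False
        for rs in (seq, revcomp(seq)):
            start = rs.find(c_seq)
            while start != -1:
                a_best = d_best = 0
                avail_l = avail_r = 0
                for P, jl, jr in path.variants:
                    a, d, al, ar = _extend_match(rs, start, P, jl, jr)
                    a_best = max(a_best, a)
                    d_best = max(d_best, d)
                    avail_l, avail_r = al, ar
                if a_best >= Y and d_best >= Y:
                    best_confirm = True
                elif (a_best >= Y and d_best == 0 and avail_r >= 2 * Y) or (
                    d_best >= Y and a_best == 0 and avail_l >= 2 * Y
                ):
                    best_contradict = True
                start = rs.find(c_seq, start + 1)
            if best_confirm:
                break
        if best_confirm:
            counts.confirm += 1
        elif best_contradict:
            counts.contradict += 1
    return counts


def _placements(read: str, P: str) -> List[Tuple[int, int]]:
    """Anchored exact placements of ``read`` on ``P``.

    Each placement is (start, run) where ``run`` is the length of the
    maximal mismatch-free stretch from the anchored end.  Prefix-anchored
    placements extend rightward; suffix-anchored ones are reported with the
    implied start (possibly with unmatched prefix bases).
    """
    out: List[Tuple[int, int]] = []
    if len(read) < _ANCHOR:
        return out
    anchor = read[:_ANCHOR]
    o = P.find(anchor)
    while o != -1:
        run = _ANCHOR
        while o + run < len(P) and run < len(read) and P[o + run] == read[run]:
            run += 1
        out.append((o, run))
        o = P.find(anchor, o + 1)
    return out


def _placements_suffix(read: str, P: str) -> List[Tuple[int, int]]:
    """Suffix-anchored placements: (match_start_in_P, run) extending leftward."""
    out: List[Tuple[int, int]] = []
    if len(read) < _ANCHOR:
        return out
    anchor = read[-_ANCHOR:]
    o = P.find(anchor)
    while o != -1:
        end = o + _ANCHOR  # one past the anchored suffix in P
        run = _ANCHOR
        ri = len(read) - _ANCHOR - 1
        pi = o - 1
        while ri >= 0 and pi >= 0 and read[ri] == P[pi]:
            run += 1
            ri -= 1
            pi -= 1
        out.append((end - run, run))
        o = P.find(anchor, o + 1)
    return out


def _mate_vs_junction(read: str, P: str, j: int, Y: int) -> Tuple[bool, bool, List[int], List[int]]:
    """Judge one mate against one junction at P position j.

    Returns (confirms, contradicts, confirm starts, contradict starts) where
    starts are the placement start coordinates used for the distance check.
    """
    confirms: List[int] = []
    contradicts: List[int] = []
    for o, run in _placements(read, P):
        if o <= j - Y and o + run >= j + Y:
            confirms.append(o)
        elif o + run == j and o + len(read) - j >= 2 * Y:
            # approached the junction from the left and matched nothing beyond
            contradicts.append(o)
    for s, run in _placements_suffix(read, P):
        e = s + run
        if s <= j - Y and e >= j + Y:
            confirms.append(e - len(read))
        elif s == j and j - (e - len(read)) >= 2 * Y:
            contradicts.append(e - len(read))
    return bool(confirms), bool(contradicts), confirms, contradicts


def support_by_pairs(
    path: CandidatePath,
    pairs: Sequence[Tuple[str, str]],
    insert: InsertSizeRange,
    Y: int,
) -> SupportCounts:
    """Confirm/contradict counts from mate pairs straddling the two forks."""
    counts = SupportCounts()
    for m0, m1 in pairs:
        pair_confirm = False
        pair_contradict = False
        for left_read, right_read in ((m0, revcomp(m1)), (m1, revcomp(m0))):
            for P, jl, jr in path.variants:
                lc, lx, lc_pos, lx_pos = _mate_vs_junction(left_read, P, jl, Y)
                rc, rx, rc_pos, rx_pos = _mate_vs_junction(right_read, P, jr, Y)

                def in_range(ls: int, rs: int) -> bool:
                    frag = rs + len(right_read) - ls
                    return ls <= rs and frag in insert

                if lc and rc and any(
                    in_range(ls, rs) for ls in lc_pos for rs in rc_pos
                ):
                    pair_confirm = True
                if lc and rx and any(
                    in_range(ls, rs) for ls in lc_pos for rs in rx_pos
                ):
                    pair_contradict = True
                if rc and lx and any(
                    in_range(ls, rs) for ls in lx_pos for rs in rc_pos
                ):
                    pair_contradict = True
            if pair_confirm:
                break
        if pair_confirm:
            counts.confirm += 1
        elif pair_contradict:
            counts.contradict += 1
    return counts


def find_fork_contexts(graph: AssembledGraph) -> List[ForkContext]:
    """Middle segments with at least two choices on both ends, sorted by id."""
    out = []
    for sid in sorted(graph.segments):
        preds = sorted(graph.preds(sid))
        succs = sorted(graph.succs(sid))
        if len(preds) >= 2 and len(succs) >= 2:
            out.append(ForkContext(sid, preds, succs))
    return out


def filter_graph(
    graph: AssembledGraph,
    reads: ReadSet,
    insert: Optional[InsertSizeRange],
    params: Optional[Params] = None,
) -> AssembledGraph:
    """Remove left-C-right combinations that reads and pairs contradict.

    A combination is removed when contradict >= not_aligned_count and
    confirm < aligned_count; removal duplicates C per surviving combination
    group.  If the segment count inflates beyond rollback_factor times the
    initial count the pass is rolled back and the input graph returned.
    """
    params = params or Params()
    Y = params.not_aligned_half
    if Y <= 0 or graph.is_empty():
        return graph
    initial_n = graph.n_segments()
    g = graph.copy()
    read_seqs = reads.sequences()
    read_len = max((len(s) for s in read_seqs), default=0)
    pair_seqs = [(a.sequence, b.sequence) for a, b in reads.pairs()]
    need = max(read_len, insert.max_len if insert is not None else 0)

    processed: Set[str] = set()
    changed = True
    while changed:
        changed = False
        for ctx in find_fork_contexts(g):
            if ctx.middle in processed:
                continue
            processed.add(ctx.middle)
            c_seq = g.segments[ctx.middle]
            cands = build_candidate_paths(g, ctx, need, params)
            allowed: Dict[str, Set[str]] = {a: set() for a in ctx.left_choices}
            any_removed = False
            for cand in cands:
                sup = support_by_reads(cand, c_seq, read_seqs, Y)
                if pair_seqs and insert is not None:
                    sup += support_by_pairs(cand, pair_seqs, insert, Y)
                remove = (
                    sup.contradict >= params.not_aligned_count
                    and sup.confirm < params.aligned_count
                )
                logger.debug(
                    "path %s-%s-%s confirm=%d contradict=%d removed=%s",
                    cand.left, ctx.middle, cand.right,
                    sup.confirm, sup.contradict, remove,
                )
                if remove:
                    any_removed = True
                else:
                    allowed[cand.left].add(cand.right)
            if not any_removed:
                continue
            _split_middle(g, ctx, allowed)
            changed = True
            break  # topology changed; recompute contexts
    if g.n_segments() > params.rollback_factor * initial_n:
        logger.warning(
            "filtering inflated segments %d -> %d (> %dx); rolling back",
            initial_n, g.n_segments(), params.rollback_factor,
        )
        return graph
    return g


def _split_middle(
    g: AssembledGraph, ctx: ForkContext, allowed: Dict[str, Set[str]]
) -> None:
    """Duplicate the middle segment per group of left choices sharing the
    same surviving right-choice set; drop combinations with nothing left."""
    groups: Dict[frozenset, List[str]] = {}
    for a in ctx.left_choices:
        if allowed[a]:
            groups.setdefault(frozenset(allowed[a]), []).append(a)
    new_links = [
        (f, t) for (f, t) in g.links
        if f != ctx.middle and t != ctx.middle
    ]
    c_seq = g.segments.pop(ctx.middle)
    for i, key in enumerate(sorted(groups, key=lambda s: sorted(s))):
        sid = ctx.middle if i == 0 else f"{ctx.middle}.{i}"
        g.segments[sid] = c_seq
        for a in sorted(groups[key]):
            new_links.append((a, sid))
        for d in sorted(key):
            new_links.append((sid, d))
    g.links = sorted(set(new_links))
    g._index()
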