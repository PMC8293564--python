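"""Reporting: cross-target redundancy removal, end extension, variant
enumeration/ranking/selection, SNP collapsing to IUPAC codes, and GFA/FASTA
serialization."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .config import Params
from .dna import canonical, iter_kmers
from .extension import AssembledGraph
from .reads import DeBruijnGraph, KmerCounts

logger = logging.getLogger(__name__)


@dataclass
class VariantSet:
    """Ranked assembled sequences for one graph.

    ``variants`` are (sequence, support) sorted by descending support with
    lexicographic tie-break; support is the sum of secondary-k-mer read
    counts over all windows of the sequence.
    """

    graph_id: str
    variants: List[Tuple[str, int]] = field(default_factory=list)
    truncated: bool = False

    def sequences(self) -> List[str]:
        return [s for s, _ in self.variants]


def remove_redundant(
    graphs: Sequence[AssembledGraph], secondary_k: int, keep_subgraphs: bool = False
) -> List[AssembledGraph]:
    """Drop graphs whose full secondary-k-mer set is contained in another's.

    Mutual containment (identical sets) keeps the earliest graph by target
    order.  With keep_subgraphs set this is the identity.
    """
    if keep_subgraphs or len(graphs) <= 1:
        return list(graphs)
    sets = [g.kmer_set(secondary_k) for g in graphs]
    kept: List[AssembledGraph] = []
    for i, g in enumerate(graphs):
        redundant = False
        for j in range(len(graphs)):
            if i == j:
                continue
            if sets[i] <= sets[j] and (sets[i] != sets[j] or j < i):
                redundant = True
                logger.info(
                    "graph %s redundant with %s at k=%d",
                    g.origin_target, graphs[j].origin_target, secondary_k,
                )
                break
        if not redundant:
            kept.append(g)
    return kept


def extend_ends(graph: AssembledGraph, dbg_primary: DeBruijnGraph) -> AssembledGraph:
    """Extend terminal segment ends through strictly unambiguous graph walks.

    Each end with no link walks single-successor (single-predecessor) steps
    in the primary graph until a fork, dead end or k-mer revisit; the added
    lengths are recorded per segment for pre-extension length accounting.
    """
    g = graph.copy()
    k = g.k
    for sid in sorted(g.segments):
        added = g.ext.setdefault(sid, [0, 0])
        if not g.succs(sid):
            seq = g.segments[sid]
            seen = set(seq[i : i + k] for i in range(len(seq) - k + 1))
            while True:
                cur = seq[-k:]
                succ = dbg_primary.successors(cur)
                if len(succ) != 1:
                    break
                b = next(iter(succ))
                nk = cur[1:] + b
                if nk in seen:
                    break
                seen.add(nk)
                seq += b
                added[1] += 1
            g.segments[sid] = seq
        if not g.preds(sid):
            seq = g.segments[sid]
            seen = set(seq[i : i + k] for i in range(len(seq) - k + 1))
            while True:
                cur = seq[:k]
                pred = dbg_primary.predecessors(cur)
                if len(pred) != 1:
                    break
                b = next(iter(pred))
                nk = b + cur[:-1]
                if nk in seen:
                    break
                seen.add(nk)
                seq = b + seq
                added[0] += 1
            g.segments[sid] = seq
    return g


def _enumerate_paths(graph: AssembledGraph, cap: int) -> Tuple[List[List[str]], bool]:
    """Source-to-sink segment paths, each link used at most once per path.

    Returns (paths, hit_cap).  Graphs that are pure cycles start from the
    smallest segment id.
    """
    if graph.is_empty():
        return [], False
    sources = [s for s in sorted(graph.segments) if not graph.preds(s)]
    if not sources:
        sources = [min(graph.segments)]
    paths: List[List[str]] = []
    hit_cap = False
    for src in sources:
        stack: List[Tuple[List[str], frozenset]] = [([src], frozenset())]
        while stack:
            path, used = stack.pop()
            if len(paths) >= cap:
                hit_cap = True
                return paths, hit_cap
            nxt = [
                t for t in sorted(graph.succs(path[-1]), reverse=True)
                if (path[-1], t) not in used
            ]
            if not nxt:
                paths.append(path)
                continue
            for t in nxt:
                stack.append((path + [t], used | {(path[-1], t)}))
    return paths, hit_cap


def _path_support(seq: str, counts_secondary: KmerCounts) -> int:
    k2 = counts_secondary.k
    return sum(counts_secondary.count(w) for w in iter_kmers(seq, k2))


def _effective_length(graph: AssembledGraph, path: List[str], seq_len: int) -> int:
    """Path length minus flank bases appended by extend_ends on its terminal
    segments (the reporting filter uses pre-extension coordinates)."""
    length = seq_len
    if path:
        length -= graph.ext.get(path[0], [0, 0])[0]
        length -= graph.ext.get(path[-1], [0, 0])[1]
    return length


def enumerate_variants(
    graph: AssembledGraph,
    counts_secondary: KmerCounts,
    params: Optional[Params] = None,
    target_length: Optional[int] = None,
    target_is_protein: bool = False,
) -> VariantSet:
    """All source-to-sink variants of a graph, length-filtered and ranked.

    Variants shorter than target_coverage x target length (or min_hit_len
    when set) are suppressed; beyond max_variants only the top-supported
    variants are kept and the set is flagged truncated.
    """
    params = params or Params()
    cap = max(4 * params.max_variants, 4096) + 1
    paths, hit_cap = _enumerate_paths(graph, cap)
    entries: List[Tuple[str, int]] = []
    seen: Set[str] = set()
    for path in paths:
        seq = graph.path_sequence(path)
        eff = _effective_length(graph, path, len(seq))
        if params.min_hit_len is not None:
            if eff < params.min_hit_len:
                continue
        elif target_length is not None:
            # protein target lengths are in residues; variants are nucleotide
            span = target_length * 3 if target_is_protein else target_length
            if eff < params.target_coverage * span:
                continue
        if seq in seen:
            continue
        seen.add(seq)
        entries.append((seq, _path_support(seq, counts_secondary)))
    entries.sort(key=lambda e: (-e[1], e[0]))
    truncated = hit_cap or len(entries) > params.max_variants
    if len(entries) > params.max_variants:
        entries = entries[: params.max_variants]
    return VariantSet(graph.origin_target or "", entries, truncated)


def select_variants(
    graph: AssembledGraph, counts_secondary: KmerCounts, params: Optional[Params] = None
) -> List[str]:
    """The best supported source-to-sink sequence for each link, deduplicated.

    A graph with a single segment and no links reports that segment.
    """
    params = params or Params()
    cap = max(4 * params.max_variants, 4096) + 1
    paths, _ = _enumerate_paths(graph, cap)
    if not graph.links:
        return sorted(graph.segments.values())
    scored = []
    for path in paths:
        seq = graph.path_sequence(path)
        links = set(zip(path, path[1:]))
        scored.append((seq, _path_support(seq, counts_secondary), links))
    best: Dict[Tuple[str, str], Tuple[int, str]] = {}
    for seq, sup, links in scored:
        for link in links:
            cur = best.get(link)
            if cur is None or (sup, _neg(seq)) > (cur[0], _neg(cur[1])):
                best[link] = (sup, seq)
    out = sorted({seq for _, seq in best.values()})
    return out


def _neg(seq: str):
    # lexicographically smaller sequences win support ties
    return tuple(-ord(c) for c in seq)


_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


def collapse_snps(graph: AssembledGraph) -> AssembledGraph:
    """Merge substitution-only simple bubbles into IUPAC-ambiguity segments.

    A simple bubble is one source u, >=2 equal-length single-in/single-out
    branch segments, one sink w; indel bubbles (unequal lengths) are left
    untouched.  Resulting linear chains are recompressed.
    """
    g = graph.copy()
    changed = True
    while changed:
        changed = False
        for u in sorted(g.segments):
            branches = g.succs(u)
            if len(branches) < 2:
                continue
            ws = {tuple(g.succs(b)) for b in branches}
            if len(ws) != 1:
                continue
            w_tuple = ws.pop()
            if len(w_tuple) != 1:
                continue
            w = w_tuple[0]
            if any(len(g.preds(b)) != 1 for b in branches):
                continue
            if sorted(g.preds(w)) != sorted(branches):
                continue
            lengths = {len(g.segments[b]) for b in branches}
            if len(lengths) != 1:
                continue  # indel bubble: untouched
            seqs = [g.segments[b] for b in sorted(branches)]
            merged = "".join(
                _IUPAC.get(frozenset(chars), "N") if len(set(chars)) > 1 else chars[0]
                for chars in zip(*seqs)
            )
            keep = sorted(branches)[0]
            drop = set(sorted(branches)[1:])
            for b in drop:
                del g.segments[b]
            g.segments[keep] = merged
            g.links = sorted(
                {
                    (f, t) for (f, t) in g.links
                    if f not in drop and t not in drop
                }
                | {(u, keep), (keep, w)}
            )
            g._index()
            changed = True
            break
    return _recompress(g)


def _recompress(g: AssembledGraph) -> AssembledGraph:
    """Merge strictly linear segment chains left over after bubble collapse."""
    changed = True
    while changed:
        changed = False
        for u in sorted(g.segments):
            ss = g.succs(u)
            if len(ss) != 1:
                continue
            v = ss[0]
            if v == u or len(g.preds(v)) != 1:
                continue
            g.segments[u] = g.segments[u] + g.segments[v][g.overlap :]
            new_links = [(f, t) for (f, t) in g.links if (f, t) != (u, v)]
            new_links = [
                (u if f == v else f, u if t == v else t) for (f, t) in new_links
            ]
            del g.segments[v]
            g.links = sorted(set(new_links))
            g._index()
            changed = True
            break
    return g


def write_gfa(graphs, path: str) -> None:
    """Write one or more assembled graphs as GFA 1.0.

    Segment names are prefixed per graph when several graphs share the file;
    the k-mer size travels in a private tag on the header.
    """
    if isinstance(graphs, AssembledGraph):
        graphs = [graphs]
    with open(path, "w") as fh:
        k = graphs[0].k if graphs else 0
        fh.write(f"H\tVN:Z:1.0\tpk:i:{k}\n")
        multi = len(graphs) > 1
        for gi, g in enumerate(graphs):
            prefix = f"g{gi + 1}." if multi else ""
            for sid in sorted(g.segments):
                fh.write(f"S\t{prefix}{sid}\t{g.segments[sid]}\n")
            for f, t in g.links:
                fh.write(f"L\t{prefix}{f}\t+\t{prefix}{t}\t+\t{g.overlap}M\n")


def read_gfa(path: str) -> AssembledGraph:
    """Parse a (single-graph) GFA 1.0 file written by :func:`write_gfa`."""
    segments: Dict[str, str] = {}
    links: List[Tuple[str, str]] = []
    k = None
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "H":
                for tag in fields[1:]:
                    if tag.startswith("pk:i:"):
                        k = int(tag[5:])
            elif fields[0] == "S":
                segments[fields[1]] = fields[2]
            elif fields[0] == "L":
                links.append((fields[1], fields[3]))
                if k is None:
                    k = int(fields[5].rstrip("M")) + 1
    if k is None:
        k = min((len(s) for s in segments.values()), default=1)
    return AssembledGraph(segments, links, k)


def write_fasta(records: Iterable[Tuple[str, str]], path: str, width: int = 80) -> None:
    """Write (id, sequence) records as FASTA with fixed line width."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
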