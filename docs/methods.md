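# Methods

This note records the model, the tunable parameters, the synthetic data the
package is validated on, and the choices made where the design was genuinely
open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and assumptions

The assembler is built for Illumina-like data: fixed-length reads
(~100–250 bp), short inserts, a very low indel error rate, substitution
errors that can be strand-systematic, and possible low-level carryover
contamination.  Its core assumption is that the region of interest is
homologous to a user-supplied target — a nucleotide sequence or a protein —
at roughly ≥75% identity, so that enough seed k-mers pass the
good-alignment tests to anchor assembly.  The reads, not the target, supply
every reported base: the target bounds the search and scores candidate
paths, and a drop-off rule trims each path back to its best-scoring
position so assemblies stay co-terminal with the homologous region.

Two graphs are kept.  The primary graph (large k) gives specificity; the
secondary graph (small k) exists solely to bridge short coverage dips where
no read spans a primary-k window, reverting to the primary k immediately
afterwards.  With the default `min_count` 2 and `secondary_kmer_threshold`
1 the single-extension rescue case is provably idle (every primary k-mer
already has count ≥ 2); it activates under the low-coverage preset
(`min_count` 1, `aligned_count` 1).

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `min_count` | 2 | count | k-mer admission to both graphs |
| `word` | 8 nt / 12 nt (4 aa) | bases | exact-match seed word |
| `fraction` | 0.05 | — | per-position seed count floor vs the maximum N |
| `kmer_complexity` | 2000 | count | seeds per position before hard-masking |
| reward/penalty | 1 / 2 | score | nucleotide match/mismatch |
| gap open/extend | 5 / 2 (nt), 11 / 1 (aa) | score | affine gap costs (BLAST-family values; the production defaults are not published) |
| `drop_off` | 25 (nt), 50 (aa half-bits) | score | clip threshold below the best score |
| `extension_fraction` | 0.1 | — | extension-noise cut vs max choice count |
| strand balance | 0.1 | — | minor-strand share separating "balanced" from "predominantly one strand" (the original states the intent, not a cutoff) |
| `secondary_kmer_threshold` | 1 | count | single-extension rescue trigger |
| `buf_length` / `max_fork_density` | 200 bp / 0.1 | — | fork-density abort window and limit |
| `aligned_count` / `not_aligned_count` / `not_aligned_len` | 2 / 3 / 10 | counts, bp | fork filtering thresholds; Y = `not_aligned_len`/2 |
| `max_path` | 1000 | count | fork-context expansion budget |
| rollback factor | 15× | — | segment inflation bound before undoing a filter pass |
| `target_coverage` / `min_hit_len` | 0.5 / unset | — | variant length reporting filter (pre-end-extension length) |
| `max_variants` | 1000 | count | reported variants per graph, ranked by secondary-k-mer support |

Automatic k sizes: primary = largest odd ≤ len/2, secondary = max(21,
largest odd ≤ len/5), both multiples of 3 in protein mode, with the maximum
observed read length as the representative length; selection fails below
primary k = 21 and the user must supply sizes.

## Numerical and algorithmic choices

**Alignment.**  The incremental aligner advances a banded affine-gap DP one
path symbol (base or translated residue) per step, anchored at the target
coordinate following the seed; band half-width is `drop_off`/`gap_extend` + 2,
which covers every offset reachable within the drop-off.  Integer
arithmetic throughout; protein scores are BLOSUM62 half-bits.  An exact
from-scratch banded DP serves as the test oracle.  Stop codons score as the
BLOSUM62 `*` column (−4 against any residue) and do not terminate the path;
frameshift-tolerant alignment is declared in the scoring scheme but not
implemented (no default enables it).  Left extensions reuse the rightward
machinery on reversed sequences, with codons reassembled in genomic order.

**Seed extensibility** demands an existential 100-base extension beyond the
k-mer on each side (memoized DFS; cycles count as unbounded length).  This
length is load-bearing: k-mers created by a duplicated strand-biased error
can chain at most ~(read length − k) k-mers and cannot reconnect to the
reference on both sides, so the 100-base requirement excludes error-derived
seeds that a shallower check admits.  With `protect_reference_ends` the
check is suspended on a side nearer than 100 bp (nt) or 34 aa (protein) to
a target end, which restores seeds at transcript termini.

**Clipping and dead ends.**  Paths clipped by drop-off are trimmed to the
best scoring position, the clip point is marked as a fork for filtering,
and pending branches beyond the best position are discarded.  Dead-ended
paths are also trimmed to their best position, so default assemblies do not
run into non-homologous flank; flank recovery is the explicit job of
`extend_ends`.  Paths whose best position never rose above score 0
contribute nothing.

**Anchors.**  A branch registers an anchor at a new k-mer when fewer than
k/4 bases separate it from the branch's best position; a second branch
reaching the same k-mer with the same best position (compared in target
coordinates — the only frame shared between branches) merges and stops.
Merged branches keep their full base run so the merge point stays
connected.

**Fork-density abort** uses the trailing `buf_length` window, or the whole
path when shorter, with a strict inequality; paths already finalized for
the seed are kept and exploration stops.  A per-seed branch budget (10,000)
guards pathologies the density rule misses.

**Graph shape.**  All paths are assembled in target orientation, unioned as
k-mer chains and compressed into unitig segments with k−1 overlaps; segment
ids are assigned in sorted-sequence order, so identical inputs yield
byte-identical graphs.

**Filtering.**  Read and pair evidence are accumulated into a single
confirm count and a single contradict count per candidate path (the same
formula governs both).  Fork-context flanks are expanded up to the read
length (pairs: the insert maximum), halving the expansion when the number
of context sequences would exceed `max_path`.  Reads are matched on both
strands; placements are anchored on a 12-base exact prefix or suffix and
extended mismatch-free, which is exact for the substitution-only regime the
filter addresses.  Pair orientation is innie with the fragment length
inside the estimated insert range, inclusive.  Removal duplicates the
middle segment per group of left choices sharing a surviving right-choice
set; a pass that inflates the segment count beyond 15× is rolled back
wholesale.

**Insert size** is estimated by walking mate 0 forward through
single-choice graph extensions until the reverse complement of mate 1 forms
the suffix (cap 1000 bp); the range is the 1st–99th percentile of joined
lengths — a robust substitute for the unpublished estimator of the original
— with a fallback of [read length, 2×cap] under 100 joins.

**Variant enumeration** traverses each link at most once per path (so
cycles terminate), filters lengths in pre-end-extension coordinates
(protein target lengths × 3), ranks by the sum of secondary-k-mer read
counts with lexicographic tie-break, and caps enumeration at
max(4·`max_variants`, 4096) paths before truncation — exhaustive
enumeration of astronomically many paths is deliberately out of scope, and
the per-link best-path selection exists for exactly that regime.  SNP
collapsing merges substitution-only simple bubbles of equal arm length into
IUPAC codes and recompresses; indel bubbles are untouched.

## What the simulator emulates — and what it does not

`simulate` produces fixed-length innie pairs with Normal-truncated inserts,
uniform fragment starts, substitution-only errors, an optional systematic
substitution injected only into plus-strand observations of one locus (to
exercise the strand-balance filter), contaminant pairs from an unrelated
random sequence, and homolog targets at a requested identity (protein
homologs repair substitutions that would create internal stops).
Deterministic read tilings support coverage-dip and repeat fixtures.

It does **not** model quality-score structure, indel errors, GC-coverage
bias, PCR duplicates, adapter read-through or chimeric fragments.  Passing
tests therefore demonstrate the algorithmic contracts — seeding, guided
extension, strand filtering, rescue, pair phasing, reporting — on clean
substitution-dominated data; they do not certify behavior under indel-rich
or heavily biased real libraries.  Fixture scales (genes of 0.6–2 kb,
coverage 20–60×, read length 80–150 bp) were chosen as the smallest sizes
at which every mechanism is exercised with comfortable statistical margin.

## Known limitations

- Frameshift-aware protein alignment is not implemented.
- Quality values are ignored; trimming is N-splitting only.
- Single-threaded; `--cores` is accepted for interface parity only.
- Simple bubbles (one fork per side) are judged by graph counts alone — the
  read/pair filter only tests paths between two forks, per its design.
- The SNP collapse handles simple substitution bubbles, not nested ones.
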