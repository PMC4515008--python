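# Methods

## Problem and model

Draft genome assemblies represent unresolved sequence inside scaffolds as
runs of `N` of estimated length ("gaps"). Much of that sequence is
recoverable from the raw whole-genome shotgun reads: the reads cover the
gap, they just were not assembled into it. `nclose` closes such gaps by
local assembly between the gap's flanks.

The read set is represented as an **implicit de Bruijn graph**: the nodes
are the *solid* k-mers — canonical k-mers observed at least `threshold`
times — and an edge exists between two k-mers when they overlap by k−1
bases. Neither nodes nor edges are stored explicitly; membership lives in
a **cascading Bloom filter** (one plain Bloom level per unit of
multiplicity threshold; an occurrence is promoted into level *i*+1 only if
the k-mer is already present in levels 1..*i*; a k-mer is solid when
present in all levels). The filter has one-sided error: no false
negatives, and a false-positive probability of about
`fill_ratio ** num_hashes` per level. At the default threshold of 2,
singleton k-mers — overwhelmingly sequencing errors at ordinary coverage —
never enter the graph.

A gap is closed in three steps:

1. **Discovery.** Every maximal N-run with at least `min_flank` (`-L`,
   default 100) clean A/C/G/T bases on *both* sides becomes a work item;
   the adjacent `min_flank` bases are its flanks. Terminal runs and runs
   crowded by neighbouring Ns or ambiguity codes are skipped.
2. **Connection.** On each flank the first solid *anchor* k-mer is sought
   scanning inward from the gap edge (bases inward of the anchor are
   trimmed and later replaced — the assembler may have erred near the gap
   edge). A depth-limited, bidirectional, breadth-first search then
   enumerates **all** distinct k-mer paths between the anchors: two
   frontiers expand alternately one level at a time, every partial path is
   registered at its end node, and halves are joined whenever an expansion
   lands on a node the opposite side has reached. A path never revisits a
   stranded k-mer (cycle guard; an inverted repeat — same canonical k-mer,
   opposite strand — may be traversed). A unique path is reported as-is;
   2..`P` equal-length paths are merged column-wise, disagreeing columns
   getting IUPAC ambiguity codes; anything else fails the gap. The output
   is all-or-none: no partial fills.
3. **Update.** Successful products (kept flanks + interior) are spliced
   over the window [gap − left flank, gap + right flank), processing gaps
   from 3′ to 5′ per scaffold so that coordinate shifts from length
   changes never invalidate pending closures. Length disagreements between
   the N-run and its replacement are deliberately ignored — written gap
   lengths are estimates.

The whole procedure is swept over a list of k values (largest first by
default: large k resolves repeats, small k tolerates low coverage), with
one Bloom filter resident at a time and **subtractive** bookkeeping: a gap
closed at one k is never re-attempted at a later k.

## Parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `k_list` | — | k-mer sizes swept, attempted in order; every k ≤ `min_flank` |
| `min_flank` (`-L`) | 100 bp | clean flank length required and extracted per side |
| `threshold` | 2 | k-mer multiplicity for solidity (= Bloom cascade depth) |
| `max_paths` (`-P`) | 2 | most distinct complete paths accepted for a consensus |
| `max_branches` (`-B`) | 1000 | live partial paths allowed, summed over both frontiers |
| `max_frag` (`-F`) | 1000 bp | cap on the full replacement product length |
| `max_flank_scan` | whole flank | how far inward an anchor may sit |
| `bloom_bytes` (`-b`) | 32 MB | total filter memory, split equally over levels |
| `num_hashes` | 4 | hash functions per Bloom level |
| `seed` | 0 | hash seed recorded in the filter; fixes all randomness |

## Numerical and design choices

- **Canonical k-mers.** Strand-neutral identity is the lexicographic
  minimum of a k-mer and its reverse complement. The filter realizes this
  with a strand-symmetric hash: each strand of a window receives a 64-bit
  polynomial rolling hash (computed for all windows of a sequence at once
  with wrapping prefix-sum arithmetic), the pair is symmetrized with
  `min`, and a murmur-style finalizer keyed by the seed produces the
  `(h1, h2)` pair consumed by double hashing (`h1 + i*h2`). Collisions of
  the 64-bit hash are indistinguishable from, and dominated by, Bloom
  false positives.
- **Cascade batching.** Occurrences are inserted in vectorized batches;
  for a k-mer currently present in the first *c* levels with *m*
  occurrences in the batch, the final state (levels 1..min(threshold,
  c+m)) equals one-at-a-time insertion, so batching does not change
  semantics.
- **Consensus scope.** Only equal-length alternate paths are merged;
  column-wise IUPAC merging is ill-defined across an indel, so
  unequal-length path sets fail the gap (reported as `too_many_paths` —
  ambiguity beyond what a consensus can express).
- **Branch budget.** `max_branches` counts live partial paths summed over
  both frontiers, and exceeding it aborts the entire gap (fail-closed),
  consistent with all-or-none output.
- **Product cap.** `max_frag` bounds kept-flanks-plus-interior; the
  interior depth limit is derived as `F − |left kept| − |right kept| + k`.
- **Tie-breaks.** Neighbor expansion and candidate bases are always in
  A<C<G<T order; enumerated paths are deduplicated by spelling and sorted;
  with a fixed seed two runs are byte-identical.
- **Degenerate inputs.** `start == goal` yields the zero-length interior
  (overlapping flanks); flanks shorter than k give `no_anchor`; a k above
  `min_flank` is a configuration error before any work; an overloaded
  filter (estimated top-level FPR > 5 %) warns rather than fails.
- **Overlapping windows.** Two closures whose replacement windows overlap
  are resolved right-most-wins at apply time, mirroring the 3′→5′ rule;
  the dropped closure is counted and logged.
- **Coordinates.** 0-based half-open everywhere; file outputs state this
  in a header comment.

## Synthetic data

The generator produces what the method consumes, at desk scale:

- an i.i.d. reference at a chosen GC content, optionally with planted
  exact repeats (`repeat_spec`), the repeat intervals being reported so
  gaps can avoid them (default) or be forced inside them;
- paired-end reads at a stated fold-coverage (pair count
  `ceil(coverage·G / 2·read_len)`), Gaussian fragment lengths clamped at
  `read_len`, read 2 reverse-complemented, i.i.d. substitutions that
  always change the base (no indel errors: the multiplicity filter, which
  the fixtures exercise, acts on substitution-dominated short-read error
  profiles);
- a gapped draft whose N-run lengths may deliberately misstate the masked
  lengths (`gap_size_error`, fixed fraction or per-gap uniform range),
  with per-gap ground truth in draft coordinates.

Each operation draws from an RNG stream derived from `(seed, operation)`,
so outputs are individually reproducible.

What the fixtures do **not** model: indel and platform-specific error
profiles, coverage bias, heterozygosity beyond hand-built two-haplotype
fixtures, and repeat families more complex than exact copies. Passing
tests therefore demonstrate the algorithmic contracts (exact recovery,
error filtering, consensus, conservation, determinism), not performance
on real libraries.

## Evaluation conventions

A gap is a maximal N-run; ambiguity codes are not N. Closure is assessed
by re-locating each original gap's flanks in the filled assembly (exact
search from a moving cursor, then scaffold-wide) and inspecting the bases
between them; gaps whose flanks cannot be anchored are counted
unassessable. Similarity of an inserted sequence to truth is
`100 · matches / |query|` under a global alignment with unit scoring
(match 1, mismatch and indel 0), where a query IUPAC code matches any
base in its set — consensus codes are not penalized. Exact match means
some IUPAC-consistent resolution of the query equals the truth. A
similarity threshold (e.g. 95 %) can annotate report summaries but never
filters rows. The aligner is Biopython's `PairwiseAligner` with a custom
IUPAC-compatibility matrix.

## Problem sizes used in the checks

The end-to-end checks run on a 100 kbp genome with 20 planted gaps of
50–500 bp (written lengths off by up to ±20 %), 2×100 bp reads at 50×
(clean) or 60× with 1 % substitutions, sweeping k = 90…40 in steps of 10
with `-P 10 -B 1000 -F 700`. The search is cross-checked against an
exhaustive depth-first enumeration over an exact k-mer set on 2–5 kbp
genomes, 100 random flank pairs. These sizes exercise every code path —
coverage thresholds, k-sweep hand-off, consensus, subtraction — while a
full run of the suite stays in the minutes range on one CPU.

## Known limitations

- Unequal-length alternate paths are never merged, so a heterozygous
  indel inside a gap leaves it open.
- The bidirectional search enumerates paths explicitly; pathological
  tangles are cut by the branch budget rather than traversed cleverly.
- The assessment's flank re-location uses exact string search; if a
  closure rewrote flank bases (trim > 0 with a disagreeing read set), that
  gap is reported unassessable rather than fuzzily matched.
- The Bloom filter identifies k-mers by a 64-bit strand-neutral hash;
  adversarial inputs could collide deliberately, which is irrelevant for
  sequencing data but makes the filter unsuitable as a general-purpose
  exact set.
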