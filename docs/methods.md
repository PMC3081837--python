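# Methods

## Distance model

The unit of divergence is the **mismatch-only distance**: the number of
alignment columns in which both sequences carry a determined nucleotide
(A, C, G or T) and the nucleotides differ. Columns with a gap on either
side and columns containing N or any IUPAC ambiguity symbol contribute
nothing; ambiguity columns do, however, count toward the overlap fraction
when ungapped, since the bases are present even if unresolved. The
rationale is that substitutions track evolutionary divergence while indels
in amplicon data are dominated by sequencing artefacts — in particular
pyrosequencing homopolymer-run length miscalls — and by alignment
ambiguity. This distance is not a metric (the triangle inequality can
fail); nothing in the pipeline relies on it being one.

Alignments are optimal **global** alignments under an affine-gap scheme
(Gotoh three-state dynamic programme, numba-compiled). Among co-optimal
alignments the traceback is deterministic — diagonal over up over left at
every tie, and match-state over gap states when closing a gap — so a given
input always yields the identical alignment and distance.

### Scoring defaults and why they are linear

Default scoring: match +1, mismatch −1, gap open −2, gap **extend −2**
(i.e. linear gap costs, expressed through the affine machinery; any affine
scheme with match > mismatch can be configured). The linear default is a
correctness choice, not a tuning: when extension is cheaper than opening,
k ≥ 3 nearby single-base gaps can be bundled into one long gap plus
compensating mismatches at *equal* score (2k versus k+1+2m at
m=(k−1)/2), and the deterministic traceback may then report mismatches for
divergence that is purely indel. With equal open and extend costs, any
alignment that trades a gap pair for a mismatch is strictly worse, so
indel-only divergence scores distance exactly 0, while a substitution is
still always cheaper as a mismatch (−1) than as an insertion-deletion pair
(−4) and is therefore always counted. No integer scheme can make *mixed*
insertion/deletion slips in adjacent homopolymer runs invisible without
also hiding substitutions (it would require mismatch < 2·gap_open and
mismatch > 2·gap_open simultaneously); see the generator notes below.

The overlap fraction divides the gap-free column count by the length of
the **shorter** sequence, so an exact fragment of a longer read has
overlap 1.0 — consistent with the preclustering semantics. Pairs below the
minimum overlap (default 0.90) are simply never linked, at any cutoff.

## Preclustering

Exact-subsequence dereplication is greedy and deterministic: sequences are
processed longest-first (ties by smaller id) and each joins the first
existing group whose representative contains it as an exact substring,
else founds a new group. A fragment contained in two non-nested parents
joins the parent that comes first in this fixed order; resolving
containment *by assignment* (rather than by linkage) is a deliberate
choice and the reason the brute-force equivalence below is stated for
fragment-free data. Only forward-strand containment is tested — amplicons
from one PCR product share orientation — and reverse-complement merging is
out of scope.

## Candidate screening

The pigeonhole argument: if two sequences of length ≥ L differ by at most
c substitutions, splitting either into c+1 blocks leaves at least one
block untouched, so they share an exact word of length ⌊L/(c+1)⌋. The
k-mer screen with word size at or below that bound therefore returns a
superset of all pairs within the largest requested cutoff, for
substitution-only divergence. The default word size is min(14, bound) —
a megablast-like seed length, safe for ≥ 200-base amplicons at cutoffs
≤ 13; an explicitly requested word above the bound is refused. Pairs
diverged mainly by long indels can in principle evade any word screen;
`all_pairs` mode is the guaranteed, quadratic fallback. The permissive
"gathering" identity parameter of a BLAST-based screen is retained in the
configuration for provenance but the word screen is strictly more
permissive than any sensible value of it.

## Clustering

Single linkage at cutoff t = connected components (union–find) of the
graph with edges d ≤ t. Distances are computed once, for the largest
requested cutoff, and reused for every smaller one; requesting a cutoff
above the computed maximum is an error rather than a silent undercount.
Pairs absent from the distance store (failed screen or overlap) stay
unlinked forever — clustering is a pure function of the store. Cutoff 0
merges zero-distance sequences (identical reads, exact fragments, and
indel-only variants), which is what makes the distinct-sequence count at
cutoff 0 meaningful. MOTU names `{t}bp_MOTU{NNNN}` are assigned in
decreasing expanded-size order with ties broken by smallest member id;
together with order-independent components this makes the entire output
invariant under permutation of the input.

Two-tier analysis (for datasets whose unique-sequence count exceeds what
one distance matrix can hold): each batch is clustered at t1; each
first-tier MOTU contributes its longest member (ties by smallest id) and
its original-sequence count; the pooled representatives are clustered at
t2 ≥ t1. Only representatives and counts cross the tier boundary; full
membership remains recoverable by joining the per-batch stores.

## Annotation

Each MOTU is represented by its longest member (ties by smallest id),
aligned exhaustively against the reference database. Identity = matching
columns / gap-free columns of the global alignment. Hits are ranked by
score, then identity, then reference id; at most `top_n` (default 10, the
conventional short-list) hits with identity ≥ `min_identity` are kept.
The default acceptance cutoff is 0.70: annotation is based on the most
similar existing sequences, not exact matches, so MOTU from taxa absent
from the reference can still be placed at family or phylum level; a
stricter cutoff is appropriate when the reference is known to be dense.
Lineages store all ranked ancestors from genus to kingdom (genus, family,
order, class, phylum, kingdom), skipping unranked nodes. Rank summaries
count each MOTU once via its rank-1 hit; MOTU without hits, or whose best
hit lacks the requested rank, are tallied as "unassigned". No
lowest-common-ancestor consensus is computed — per-hit lineages only.

## Synthetic communities

The generator emulates a trimmed amplicon survey with known truth:

| parameter | default | meaning |
|---|---|---|
| n_species | 8 | species references, rejection-sampled ≥ min_separation apart |
| seq_length | 600 b | typical barcode amplicon length |
| reads_per_species | 10 | uniform (a per-species tuple gives skewed abundance) |
| within_substitutions | 2 | max substitutions per read (~0.3% of 600 b) |
| homopolymer_indel_rate | 0.002/run | ~1 slip per 600-base read (~450 runs) |
| fragment_fraction | 0.1 | share of reads emitted as exact 5'/3' fragments ≥ 60% |
| min_separation | 30 | ≥ 5% between-species divergence |

Read 0 of each species is emitted error-free — the modal amplicon — so
every same-species read lies within `within_substitutions` mismatches of
it and single linkage recovers species through this star whenever
min_separation > 2·within_substitutions (the configuration refuses
parameters violating this). Slippage indels are applied per maximal
homopolymer run with one slip *direction per read* (all affected runs
lengthen, or all shorten): mixed +1/−1 slips in adjacent runs would make a
one-mismatch ungapped alignment optimal (e.g. AAATTT → AAAATT) and is the
one configuration no scoring can hide, so the generator models directional
polymerase slippage instead. Consequences worth knowing: the *pairwise*
within-species bound 2·within_substitutions is exact only for
substitution-only communities (two sibling reads slipping in opposite
directions can add a spurious mismatch or two), and a substitution that
extends a run which then slips away is genuinely indistinguishable from a
single deletion, so a read's realized distance to its reference can be
slightly *below* its substitution count.

What the generator does not model: chimeras (kept out so truth tables are
exact), quality scores, flowgram-level 454 noise, reverse-complement
reads, and abundance-correlated error. Passing tests therefore demonstrate
algorithmic correctness under a clean error model, not robustness to every
artefact of real surveys.

## Verification set-up and problem sizes

The test suite checks each stage against an independent oracle: exhaustive
alignment-path enumeration and Bio.Align.PairwiseAligner scores for the
dynamic programme, a quadratic containment oracle for preclustering,
networkx connected components for clustering, parent-pointer walks for
lineages, and brute-force all-pairs pipelines for screening and end-to-end
equivalence. End-to-end checks run on communities of 48–80 reads of
600 bases (20 communities for the oracle-equivalence check, 10 seeds for
parameter recovery over cutoffs 2–27, 8 for indel robustness), sizes at
which the brute-force oracle itself is exact and fast. The
oracle-equivalence communities carry substitutions and slips but no
fragments, because containment-by-assignment (precluster) and
containment-by-linkage (naive oracle) legitimately differ at sub-maximal
cutoffs when a fragment excludes a substitution site. Parameter-recovery
communities use min_separation 32 so the guaranteed recovery window
(cross-read distance > 27) covers the whole tested cutoff range.
`scripts/acceptance.py` re-runs scaled versions of all of these from a
single seed and reports each rate or violation count.

## Known limitations

* New sequences cannot be added incrementally; clustering is a pure
  function of the full input.
* The k-mer screen's superset guarantee covers substitution divergence
  only; indel-heavy pairs need `all_pairs` mode.
* Exact distance equality with other NW implementations is not promised on
  pairs with co-optimal alignments of differing mismatch count; only this
  package's tie-break is deterministic.
* Reverse-complement reads are neither merged nor detected.
* The embedded store keeps one clustering per file; re-running replaces it.
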