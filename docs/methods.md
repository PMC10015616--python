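# Methods

## Index

The evidence base is a multi-string BWT over the short reads. Reads are
uppercased and split at N runs; every resulting ACGT fragment is indexed in
both orientations, each string terminated by a sentinel that sorts before
A. One backward search therefore returns strand-agnostic support, with no
per-query double lookup and no special-casing of palindromic k-mers.
Because patterns never contain the sentinel, a shared sentinel symbol with
position-based tie-breaking in the suffix sort gives exactly the same
counts as per-string sentinels.

Construction is sort-based: numpy prefix doubling over the concatenated
text, with initial ranks packing eight 3-bit symbols so doubling starts at
depth 8. This is O(n log n) sorts and exact; at the tens-of-megabases scale
this package targets (a 100 kb genome at 100× coverage is ~20 Mbp of
indexed text) it builds in well under a minute. Scaling to gigabase read
sets would need an external BWT builder and is out of scope.

Rank queries use exclusive occurrence checkpoints every 64 BWT positions
plus an in-block scan, compiled with numba; the C array and checkpoints
are exact integers, so every count is exact. A fixed-depth cache maps all
4^q q-mers (default q = `cache_size` = 8) to their suffix-array intervals,
so a k-mer query starts from the cached interval of its length-q suffix
and performs only k − q backward steps. The cache is an accelerator only:
counts with and without it are identical (tested), and it is rebuilt on
load rather than serialized.

The on-disk format is run-length encoded: magic + string count + run
count, then run symbols (uint8) and run lengths (uint32). The loader
validates magic and exact file length, so truncation is an error, not
silent corruption. Saving is byte-deterministic given read order.

## Correction model

For each draft fragment and each k the per-position k-mer count profile is
thresholded at `t = max(min_count, ceil(min_frac × median of non-zero
counts))`. The median ignores zero-count positions so that long error
regions (which contribute zeros) cannot drag the relative component to
zero; with `min_frac = 0` the threshold is exactly `min_count`. The
threshold is recomputed per fragment per pass, so it adapts to coverage
and, in repeat arrays, to copy number.

Repair regions are maximal runs of below-threshold k-mer positions.
Working in k-mer space rather than base space matters for deletions: a
single deleted base yields only k − 1 consecutive weak k-mers (fewer
inside a homopolymer, where the first and last windows of the run remain
genuine genome k-mers), so the flanking solid k-mers still cover every
base and a base-coverage rule would never flag the site. A base-space view
(`segment_solid_weak`) is still exported for inspection and reporting.
Weak runs separated by fewer than k solid positions are merged — such a
short solid stretch cannot hold a trustworthy anchor between two repairs,
and merging lets nearby errors be rebuilt in one bridge.

Bridging is depth-first search over single-base right extensions of the
current k-suffix, keeping extensions whose k-mer meets the threshold, in
fixed A<C<G<T order (deterministic output). A path succeeds when its
k-suffix equals the right anchor. Only `branch_factor` is exposed as a
tunable; the remaining budgets are package constants:
extension length cap `2 × (span + k)` where span is the anchor-to-anchor
base distance, and node budget `branch_factor × cap`. Exceeding either
sets the `truncated` flag. Among candidates, minimum edit distance to the
replaced draft segment wins, ties broken by shorter length then
lexicographic order; a best candidate farther than the segment length is
rejected outright (guards pathological rewrites). Candidates are validated
by construction: every k-mer of an accepted replacement meets the pass
threshold.

Head and tail regions have a single anchor and use one-sided extension
(leftward extension runs in reverse-complement space). Paths are emitted
at exactly the target flank length, at the cap `ceil(1.25 × target)`, and
at dead ends. Acceptance is deliberately conservative: the candidate must
reach at least the target length and differ from the draft flank by at
most half its length. The reason is the coverage ramp of linear genomes —
near a contig end, fragment sampling gives the terminal k-mers counts near
zero, so the truth path dead-ends below threshold and an unconstrained
rule would truncate correct sequence; with the rule, ends with genuinely
reconstructable errors are fixed and mere coverage deserts are left
untouched. The same rule prevents a repeat-adjacent flank from being
overwritten by repeat consensus in default mode.

Passes run once per k in ascending order, each pass consuming the previous
output; the index never changes (it derives from the short reads only).
Contigs are split at N runs, the runs are preserved verbatim, and
lowercase or non-ACGTN symbols are normalized (uppercase; odd symbols to
N). Replacements apply right-to-left so earlier coordinates stay valid.

## Evaluation

Residual errors come from a unit-cost global alignment (edlib, exact
banded Myers) with columns classified from the extended CIGAR:
`edit_distance = mismatches + insertions + deletions`, rates per 100 kbp
of reference, combined rate = mismatch rate + indel rate. Among co-optimal
alignments edlib's traceback is deterministic but the mismatch/indel split
is not canonical; the edit distance itself is unique, and the test suite
checks it against an independently written Wagner–Fischer DP. Replicate
sets are compared by the sum over all unordered pairs of edit distances.
Multi-contig assemblies are matched per contig (by name when names agree,
else greedily by smallest distance); no rotation normalization is applied,
so circular replicons should be rotated to a common start upstream.

## Synthetic data

The generator emulates the study conditions rather than any specific
simulator: 100× coverage of 150 bp paired reads from fragments of
400 ± 50 bp (normal, clipped), mate 2 reverse-complemented, read count
chosen so realized coverage matches the request to rounding; short-read
errors are substitutions only (quality strings are constant placeholders —
the polisher never reads qualities) and default to zero, matching the
error-free-read conditions used by the acceptance checks. Draft errors
default to a combined 365 × 10⁻⁵ per base split 65.9 mismatch / 119.8
insertion / 179.7 deletion per 100 kbp — indel-dominated, as long-read
consensus errors are. The insertion/deletion split (40/60) and the
homopolymer multiplier (5× indel propensity inside runs ≥ 3 bp,
renormalized so genome-wide rates stay as requested; inserted bases inside
runs duplicate the run base) are package constants standing in for
consensus-caller bias, for which no published number is used. At most one
event is placed per truth position, and the manifest replays to the draft
exactly, so scoring against ground truth is exact.

What the generator does *not* model: read quality profiles, GC-coverage
bias, chimeras/adapters, structural draft errors, diploidy. Passing tests
therefore demonstrate correctness of the algorithmic chain under clean,
indel-dominated error structure — not performance on real sequencing
artifacts.

The repeat-rescue scenario builds a 30-copy tandem array (unit 500 bp)
between unique 500 bp flanks, with exactly one copy carrying one variant
base. With 100× reads the variant k-mers have ~1/29 of the array-median
support, below `0.1 × median`, so default parameters overwrite the variant
with repeat consensus while `min_frac = 0` retains it — reproducing the
rationale for the eukaryote preset in a minimal construction.

The long-read sampler (gamma-like lengths, clipped-normal identities,
25/25/50 sub/ins/del split) is a demo utility only; no correctness claim
depends on it.

## Problem sizes and numerical choices

Acceptance-level checks use 50 kb (identity, determinism) and 100 kb ×
3 replicates (error reduction) genomes at 100× coverage, and a 16 kb
repeat-array genome for the rescue contrast — sizes at which the full
pipeline, including three independent index builds, completes in a few
minutes on one CPU while every condition (coverage, read geometry, error
rates) matches the study profile. Counts and thresholds are exact
integers; the only floating-point steps are the median and the `ceil`,
where `ceil` guarantees the relative component never rounds below its
intent. All randomness flows through numpy `default_rng` with explicit
seeds; DFS order, right-to-left application, and stable sorts make every
output byte-deterministic given (inputs, parameters, seed).

## Known limitations

* Suffix-array construction is in-memory; gigabase-scale read sets are out
  of scope (reading an external run-length BWT is a possible extension).
* The conservative end rule leaves contig-end errors uncorrected when
  coverage ramps down (linear sampling); circular or end-reinforced read
  sets do not have this limitation.
* `min_frac` interacts with mixed-copy-number fragments through a single
  per-fragment median; a windowed median would adapt better within
  fragments that are part unique, part repeat.
* Evaluation assumes collinear assemblies; no misassembly detection.
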