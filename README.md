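# fmpolish

Hybrid polishing of draft long-read assemblies with accurate short reads,
built on an FM-index of a multi-string Burrows–Wheeler transform.

Long-read (e.g. nanopore) assemblies reach excellent contiguity but their
consensus still carries residual errors — dominated by small indels,
especially in homopolymers. `fmpolish` removes them using an independent,
highly accurate short-read set: every k-mer of the draft is counted in an
FM-index built from the short reads, poorly supported ("weak") stretches
are located, and each weak stretch is reassembled by a bounded
depth-first search through the implicit de Bruijn graph of the reads,
anchored on the nearest well-supported ("solid") k-mers. The package is
aimed at anyone finishing microbial or small eukaryotic genome assemblies,
and at method developers who want a polishing pipeline whose every stage —
simulation, indexing, correction, evaluation — is seeded and testable.

## Method

Let `C(x)` be the number of occurrences of k-mer `x` among the short-read
fragments and their reverse complements, obtained by FM-index backward
search (so one query is strand-agnostic). For a draft fragment the
per-position count profile is thresholded at

```
t = max(min_count, ceil(min_frac * median{C > 0}))
```

A k-mer is *solid* if `C >= t`, else *weak*. Maximal runs of weak k-mers
become repair regions; the flanking solid k-mers are the anchors. A repair
candidate is a path `a_L -> ... -> a_R` of single-base extensions in which
every intermediate k-mer is solid; search is depth-first in fixed A<C<G<T
order with a node budget of `branch_factor x max_length`. Among the
candidates, the one closest in edit distance to the draft segment wins.
One sweep runs per k in an ascending list; small k resolves dense errors,
large k resolves repeats. Contig ends, which have only one anchor, are
rebuilt by single-sided extension under a conservative acceptance rule.

Defaults are `k = 21, 59`, `min_count = 5`, `min_frac = 0.1`,
`branch_factor = 4`, `cache_size = 8`. In repeat-rich genomes the median
count is inflated by multi-copy k-mers, so a genuinely distinct variant
within one repeat copy can fall below `min_frac x median` and be
"corrected" away; the **eukaryote preset** (`k = 21, 59, 80`,
`min_frac = 0`) disables the relative component for exactly that case.

Evaluation follows the matching convention: residual errors are the
columns of a unit-cost global alignment against the reference
(`edit distance = mismatches + insertions + deletions`), reported per
100 kbp; replicate assemblies without a reference are compared by the sum
of pairwise edit distances.

## Worked example

Simulate a 50 kb genome with 100× error-free paired short reads and an
indel-dominated draft, then index, polish, and evaluate:

```sh
fmpolish simulate --genome-len 50000 --coverage 100 --seed 11 -o sim
fmpolish build-index sim/reads_1.fq sim/reads_2.fq -o reads.fmx
fmpolish polish -i reads.fmx -a sim/draft.fa -o polished.fa
fmpolish eval --asm sim/draft.fa   --ref sim/truth.fa
fmpolish eval --asm polished.fa    --ref sim/truth.fa
```

which prints (abridged):

```
wrote truth (50000 bp), 33334 reads, draft with 194 injected errors -> sim
indexed 66668 strings (10066868 BWT symbols) -> reads.fmx
[fmpolish polish pass] bases_changed=194 k=21 regions_bridged=168 regions_failed=2 regions_found=170
[fmpolish polish pass] bases_changed=0   k=59 regions_bridged=0   regions_failed=2 regions_found=2

mismatches  insertions  deletions  ...  rate_combined_per_100kbp
26          71          97         ...  388.0     # draft vs truth
0           0           0          ...  0.0       # polished vs truth
```

The draft carried 194 errors (combined 388 per 100 kbp, indels
dominating); the first pass (k = 21) bridged 168 of 170 repair regions and
changed 194 bases; the polished assembly is identical to the truth. The
two "failed" regions are the contig ends, where read coverage ramps down
and the conservative end rule leaves the (error-free) sequence untouched.

The same pipeline is available as a scikit-learn style estimator:

```python
from fmpolish import Polisher
polished = Polisher(eukaryote=True).fit(short_reads).transform(contigs)
```

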