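# Methods

## Model and scoring

`nbtax` is a multinomial naive Bayes classifier over k-mer features. A
species class y_i is the pooled raw k-mer count table of all its training
genomes, f(x_j | y_i), together with its total T_i and a genome tally.
Class-conditional probabilities use Laplace (add-one) smoothing over the
complete alphabet of 4^k possible k-mers,

    P(x_j | y_i) = (f(x_j | y_i) + 1) / (T_i + 4^k),

which both defines a proper distribution (it sums to 1 over all 4^k keys,
verified exhaustively for k ≤ 6) and guarantees a finite log-probability
for k-mers the class never saw. Reads are scored in natural-log space,
L(x | y_i) = Σ_j log P(x_j | y_i); the class prior is uniform and the
posterior denominator class-independent, so prediction is the plain argmax
of L. An optional log-sum-exp normalization is available for users who want
posterior-shaped numbers, but it never changes the argmax.

Two scoring modes exist because the lineage of k-mer naive Bayes
classifiers is ambiguous about feature multiplicity. The default, `unique`,
sums over the *distinct* k-mers of a read; `multiplicity` weights each
k-mer by its occurrence count. For short reads with mostly unique k-mers
the two rarely disagree; the default is documented, not claimed to be the
only defensible choice. Ties in the argmax break to the smallest taxid, a
pure determinism device. Every read receives a label; rejecting
low-confidence reads as "unclassified" is deliberately out of scope.

## Incremental training

Savefiles store raw integer counts, not probabilities; smoothing is applied
at query time. This is the load-bearing design decision: class updates are
integer addition, so training incrementally — in any partition of the
genome set, in any order — produces savefiles byte-identical to batch
training. Adding a new species creates one new file; updating a species
rewrites one file; merging species A into B (mirroring an NCBI taxa merge)
adds A's counts into B's file and deletes A's. No operation reads any other
class, which is what keeps update cost proportional to the new data rather
than to the database. Class deletion is provided as the trivial complement.
Removing a *single genome* from a class is unsupported: it would require
per-genome count retention.

The savefile format is plain text — a `#` header (taxid, k, canonical flag,
genome tally, total) followed by `kmer<TAB>count` lines sorted by k-mer —
chosen for byte-determinism (two saves of equal models are identical files,
which makes the incremental-equals-batch claim testable with a hash) and
diff-ability. A `store.json` manifest records k, canonical flag, format
version and the class index, and is cross-checked against the directory on
open. Totals are validated on load so truncation is detected.

## k-mer counting

Counting is a sliding window over maximal A/C/G/T runs: windows containing
any other character (IUPAC ambiguity codes, gaps) are skipped rather than
erroring, since reference genomes routinely contain Ns. Input case is
ignored. k is capped at 31 so that a 2-bit packed implementation fits a
64-bit word; the contract is string-keyed regardless. Strand handling
defaults to non-canonical counting (each window counted as read); a
canonical mode collapsing each k-mer with its reverse complement is exposed
as a flag, with the read simulator's strand flag as its counterpart.
Pre-computed counts can be imported in both Jellyfish text-dump dialects.

## Batch scheduling

Classification of large read sets is memory-capped: reads accumulate
greedily in input order until the next read would exceed the cap (counted
as sequence bytes; any constant factor cancels in behaviour), a read larger
than the cap forms a singleton batch with a warning, and a fixed
reads-per-batch override is mutually exclusive with the cap. Per batch,
each class savefile is loaded exactly once and scored across all resident
reads; worker threads take classes concurrently and the reduction iterates
classes in sorted-taxid order. Scheduling is therefore semantically inert:
scores are bit-equal for every thread count and batching, which the tests
assert rather than assume.

## Taxonomy

The NCBI dump dialect (`\t|\t`-delimited nodes.dmp / names.dmp /
merged.dmp) is parsed directly; names are restricted to class "scientific
name"; trees are validated for cycles and dangling parents on load.
Rank trace-back walks the parent chain to the first node of the requested
rank; rank-sparse lineages yield "unresolved" at that rank and evaluation
skips such reads there, reporting the tally. delnodes.dmp is ignored:
deleted taxa simply fail lookup. Only the six ranks species–phylum are used
downstream, though the tree stores all ranks verbatim.

## Evaluation design

Cross-validation splits *genomes*, not reads, into balanced random folds
(sizes differ by at most one; the seed is a required, logged parameter), so
held-out reads come from strains never trained on and a species whose
genomes all fall in the test fold is unknown to the model. A read is
"known" iff its true species has at least one training genome;
unknown-species reads are necessarily wrong at species rank but are scored
normally at higher ranks, where the mislabelled species may still share the
right genus. At each rank a read is correct iff predicted and true species
trace to the same resolvable ancestor.

The snapshot experiment assigns each genome to the calendar year of its
release date (a genome belongs only to its latest release year), updates
the store with one year's cohort at a time, and re-classifies a fixed
held-out read set after each update. After every year a scratch store is
batch-trained on all genomes seen so far and compared byte-for-byte with
the incremental store — the strongest form of the no-accuracy-loss claim —
and genome-processing counters expose the cost asymmetry (incremental
touches each genome once; scratch-per-year re-processes the full history).

Abundance profiles tally predictions at a rank into fractions; taxa under a
threshold (default 5%) can be pooled into "Others: New" / "Others: Old"
bins by whether they entered the reference in the latest division, mass
conserved exactly. Drift between model versions is Bray-Curtis
dissimilarity, BC = Σ|p−q| / Σ(p+q), computed over *all* taxon labels (the
binned presentation is never the input) on relative abundances; the
unresolved fraction is excluded, as the comparison is between taxon
compositions. On unit-sum profiles BC is half the L1 distance, so counts
versus fractions give identical values when both profiles share a read
total.

## Synthetic corpus

The generator emulates the study conditions at desk scale: a full
six-rank taxonomy written in the exact NCBI dump dialect; one random
ancestral sequence per genus; species as copies of the genus ancestor with
independent per-base substitutions at `species_divergence` (default 0.10);
strains as copies of their species at `strain_divergence` (default 0.01) —
so strains cluster within species and congeneric species resemble each
other more than cross-genus pairs; release years attached round-robin; and
error-free fixed-length reads (default 100 per genome, 150 bp, forward
strand) cut at uniform random positions. Defaults are 2 phyla × 2 genera ×
3 species × 2 strains with 20 kb genomes and k = 8: small enough that a
full experiment runs in seconds, large enough that k = 8 separates species
cleanly while k = 2 demonstrably underfits.

What the generator does *not* emulate bounds what green tests show about
real data: there are no sequencing errors or indels, no shared gene content
across genera (cross-genus similarity is at the random-background level,
unlike real conserved proteins), no community abundance structure, and no
strain-count skew between species — the representation bias that pulls
real classifiers toward over-sequenced species. Perfect recovery on the
synthetic corpus therefore validates the machinery (exact incremental
updates, correct scoring and trace-back), not real-corpus accuracy
figures, which depend on database scale and composition.

## Numerical and degenerate-input choices

Natural log throughout (the base only shifts scores uniformly). A read
with no valid k-mer scores 0 for every class and falls to the
smallest-taxid tie-break. Empty year cohorts are no-op updates. Updating
with an empty genome set leaves the store bytes untouched. Mass-conservation
checks use 1e−12; smoothing normalization 1e−9; oracle score comparisons
1e−12. Problem sizes in the test suite and acceptance script (24 genomes,
1000–1200 read test sets, 20 update partitions) were chosen as the smallest
corpus on which every contract is exercised with clear margins.
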