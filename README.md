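# nbtax

An incrementally updatable naive Bayes k-mer classifier for taxonomic
assignment of metagenomic reads.

Reference databases of complete bacterial genomes grow by thousands of
genomes per year, and a classifier trained statically must be rebuilt from
the entire corpus every time new genomes arrive. `nbtax` avoids that: each
species class is a savefile of raw k-mer counts, so absorbing a new genome,
adding a brand-new species, or folding one species into another after a
taxonomic merge is integer addition on the affected files only — provably
*byte-identical* to retraining from scratch, with no access to previously
processed data. The package bundles the classifier with the evaluation
machinery used to study database growth: genome-level cross-validation with
known/unknown read accounting, taxonomy trace-back accuracy at six ranks,
yearly snapshot experiments, and abundance-profile drift measured by
Bray-Curtis dissimilarity.

## The model

Each species class y_i stores raw counts f(x_j | y_i) of every k-mer x_j
seen in its training genomes. Query-time probabilities use Laplace (add-one)
smoothing over the full alphabet of K = 4^k possible k-mers:

    P(x_j | y_i) = (f(x_j | y_i) + 1) / (T_i + 4^k),   T_i = Σ_j f(x_j | y_i)

A read **x** is scored per class by the log-likelihood over its distinct
k-mers,

    L(x | y_i) = Σ_j log P(x_j | y_i)

with a uniform class prior, and labelled with the argmax over classes
(ties to the smallest taxid; every read receives a species label). Accuracy
at genus through phylum is computed by tracing the predicted and true
species to their ancestors at that rank in the NCBI taxonomy.

Because smoothing happens at query time and savefiles hold integers,
incremental and batch training coincide exactly — not approximately — for
any partition and order of updates, and batching/multi-threading during
classification are pure scheduling with bit-identical results.

## Worked example

`examples/01_train_and_classify.py` simulates a 12-species corpus with two
strains per species, trains on the first strain of every species at k = 8
and classifies 1200 error-free 150 bp reads from the held-out strains:

```
trained 12 species classes (k=8) from 12 genomes
classified 1200 held-out strain reads
  species  accuracy: 1.000
  genus    accuracy: 1.000
  ...
  phylum   accuracy: 1.000
```

Every read from an unseen strain is assigned to its correct species; the
higher ranks follow by trace-back and can only be at least as accurate.
`examples/02_incremental_updates.py` shows the incremental-equals-batch
identity (`byte-identical: True` over arbitrary update waves), and
`examples/03_profile_drift.py` replays database growth over four yearly
snapshots:

```
2016: fraction_known=0.33  species_accuracy=0.33
2017: fraction_known=0.67  species_accuracy=0.67
2018: fraction_known=1.00  species_accuracy=1.00
2019: fraction_known=1.00  species_accuracy=1.00
Bray-Curtis 2016&2017: 0.304
Bray-Curtis 2017&2018: 0.250
Bray-Curtis 2018&2019: 0.000
```

Overall accuracy tracks the fraction of reads whose species the model has
seen, and the predicted genus composition of a fixed read set stops moving
(Bray-Curtis → 0) once all species are represented and later updates add
only strain-level refinement.

A `nbtax` console command wraps the same functionality for shell use
(`simulate`, `train`, `update`, `merge`, `classify`, `profile`,
`evaluate`), with `-t` threads, `-m` memory-capped read batching and `-n`
fixed-size batching; see `examples/04_command_line.sh`.

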