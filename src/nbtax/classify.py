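"""Read scoring, argmax labelling, and memory-capped batch scheduling.

A read x is scored against every species class y_i by the log-likelihood

    L(x | y_i) = sum_j log P(x_j | y_i)

over the read's k-mers (by default each *distinct* k-mer contributes once;
a multiplicity mode weighting each occurrence is available). The prior is
uniform and dropped, and the posterior denominator is class-independent, so
the predicted label is simply the argmax of L; ties break to the smallest
taxid. Every read receives a label — there is no "unclassified" call.

Large read sets are processed in batches so that the reads resident in
memory never exceed a user cap (or a fixed per-batch read count); each class
savefile is loaded at most once per batch. Batching and multi-threading are
pure scheduling: predictions are bit-identical for every choice of thread
count and batch boundaries.
"""

from __future__ import annotations

import math
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from scipy.special import logsumexp

from .kmers import KmerCountTable, SpecMismatchError, iter_kmers
from .model import ClassModel, ModelError, ModelStore

__all__ = [
    "ReadRecord",
    "Prediction",
    "score_read",
    "classify_read",
    "plan_batches",
    "classify_batchwise",
    "posterior_probabilities",
    "read_fasta_reads",
    "write_predictions_tsv",
    "read_predictions_tsv",
]

MODES = ("unique", "multiplicity")


@dataclass
class ReadRecord:
    """One query read; ``byte_size`` is what batch planning accounts for."""

    read_id: str
    sequence: str

    @property
    def byte_size(self) -> int:
        return len(self.sequence)


@dataclass
class Prediction:
    read_id: str
    predicted_species: int
    log_likelihood: float
    scores: Optional[dict[int, float]] = field(default=None, repr=False)


def _read_kmer_list(sequence: str, spec, mode: str) -> list[str]:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    kmers = iter_kmers(sequence, spec)
    return sorted(set(kmers)) if mode == "unique" else list(kmers)


def score_read(
    model: ClassModel, read_kmers: KmerCountTable, mode: str = "unique"
) -> float:
    """Log-likelihood of a read's k-mer table under one class.

    unique mode: each distinct k-mer contributes log P once;
    multiplicity mode: each k-mer contributes its occurrence count times.
    """
    if read_kmers.spec != model.spec:
        raise SpecMismatchError(
            f"read spec {read_kmers.spec} != model spec {model.spec}"
        )
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    log_denom = model.log_denominator()
    counts = model.counts
    score = 0.0
    n_terms = 0
    for kmer, c in read_kmers.counts.items():
        weight = 1 if mode == "unique" else c
        score += weight * math.log(counts[kmer] + 1)
        n_terms += weight
    return score - n_terms * log_denom


def _score_class_over_batch(
    model: ClassModel, kmer_lists: Sequence[list[str]]
) -> np.ndarray:
    """Score every read of a batch against one class.

    Uses the decomposition L = sum log(f+1) - n_terms * log(T + 4**k); a
    k-mer the class never saw contributes log(1) = 0 to the first sum.
    """
    log_denom = model.log_denominator()
    lut = {kmer: math.log(c + 1) for kmer, c in model.counts.counts.items()}
    get = lut.get
    out = np.empty(len(kmer_lists), dtype=np.float64)
    for i, kmers in enumerate(kmer_lists):
        out[i] = math.fsum(get(x, 0.0) for x in kmers) - len(kmers) * log_denom
    return out


def classify_read(
    store: ModelStore, read: ReadRecord, mode: str = "unique"
) -> Prediction:
    """Score one read against every class in the store and take the argmax."""
    predictions = classify_batchwise(store, [read], mode=mode)
    return predictions[0]


def plan_batches(
    reads: Sequence[ReadRecord],
    memory_cap_bytes: Optional[int] = None,
    n_per_batch: Optional[int] = None,
) -> list[list[int]]:
    """Partition read indices into batches under exactly one of two limits.

    With ``memory_cap_bytes``, reads accumulate greedily in input order
    until the next read would exceed the cap; a single read larger than the
    cap forms a singleton batch (with a warning). With ``n_per_batch``,
    fixed-size chunks. Concatenating the batches reproduces input order.
    """
    if (memory_cap_bytes is None) == (n_per_batch is None):
        raise ValueError("give exactly one of memory_cap_bytes or n_per_batch")
    if not reads:
        return []
    if n_per_batch is not None:
        if n_per_batch <= 0:
            raise ValueError(f"n_per_batch must be positive, got {n_per_batch}")
        return [
            list(range(i, min(i + n_per_batch, len(reads))))
            for i in range(0, len(reads), n_per_batch)
        ]
    if memory_cap_bytes <= 0:
        raise ValueError(f"memory cap must be positive, got {memory_cap_bytes}")
    batches: list[list[int]] = []
    current: list[int] = []
    used = 0
    for i, read in enumerate(reads):
        size = read.byte_size
        if size > memory_cap_bytes and not current:
            warnings.warn(
                f"read {read.read_id!r} ({size} B) exceeds the memory cap "
                f"({memory_cap_bytes} B); forming a singleton batch",
                stacklevel=2,
            )
            batches.append([i])
            continue
        if current and used + size > memory_cap_bytes:
            batches.append(current)
            current, used = [], 0
        if size > memory_cap_bytes:
            warnings.warn(
                f"read {read.read_id!r} ({size} B) exceeds the memory cap "
                f"({memory_cap_bytes} B); forming a singleton batch",
                stacklevel=2,
            )
            batches.append([i])
            continue
        current.append(i)
        used += size
    if current:
        batches.append(current)
    return batches


def classify_batchwise(
    store: ModelStore,
    reads: Sequence[ReadRecord],
    threads: int = 1,
    memory_cap_bytes: Optional[int] = None,
    n_per_batch: Optional[int] = None,
    mode: str = "unique",
    keep_scores: bool = False,
) -> list[Prediction]:
    """Classify a read set batch-by-batch against every class in the store.

    Per batch, each class savefile is loaded exactly once and scored over
    all resident reads; after all classes are seen, each read's argmax label
    (ties to the smallest taxid) is emitted and the batch is released.
    ``threads`` workers score classes concurrently; the reduction iterates
    classes in sorted-taxid order, so results are independent of thread
    count and batching.
    """
    if threads < 1:
        raise ValueError(f"threads must be >= 1, got {threads}")
    class_ids = store.index
    if not class_ids:
        raise ModelError(f"{store.root}: cannot classify against an empty store")
    if not reads:
        return []
    ids = [r.read_id for r in reads]
    if len(set(ids)) != len(ids):
        raise ValueError("read_id values must be unique within a batch run")
    if memory_cap_bytes is None and n_per_batch is None:
        batches = [list(range(len(reads)))]
    else:
        batches = plan_batches(
            reads, memory_cap_bytes=memory_cap_bytes, n_per_batch=n_per_batch
        )

    predictions: list[Optional[Prediction]] = [None] * len(reads)
    for batch in batches:
        kmer_lists = [
            _read_kmer_list(reads[i].sequence, store.spec, mode) for i in batch
        ]
        per_class: dict[int, np.ndarray] = {}

        def _score(taxid: int) -> tuple[int, np.ndarray]:
            model = store.load_class(taxid)
            return taxid, _score_class_over_batch(model, kmer_lists)

        if threads == 1:
            results = map(_score, class_ids)
        else:
            with ThreadPoolExecutor(max_workers=threads) as pool:
                results = list(pool.map(_score, class_ids))
        for taxid, scores in results:
            per_class[taxid] = scores

        for pos, read_idx in enumerate(batch):
            best_taxid, best_score = None, -math.inf
            for taxid in class_ids:  # sorted: ties keep the smallest taxid
                s = float(per_class[taxid][pos])
                if s > best_score:
                    best_taxid, best_score = taxid, s
            predictions[read_idx] = Prediction(
                read_id=reads[read_idx].read_id,
                predicted_species=best_taxid,
                log_likelihood=best_score,
                scores=(
                    {t: float(per_class[t][pos]) for t in class_ids}
                    if keep_scores
                    else None
                ),
            )
    return [p for p in predictions if p is not None]


def posterior_probabilities(scores: dict[int, float]) -> dict[int, float]:
    """Normalize per-class log-likelihoods into posterior probabilities.

    Uniform prior; log-sum-exp over classes. The argmax is unchanged by
    this normalization — it exists for users who want calibrated-looking
    numbers, not for prediction.
    """
    taxids = sorted(scores)
    values = np.array([scores[t] for t in taxids])
    log_z = logsumexp(values)
    return {t: float(np.exp(v - log_z)) for t, v in zip(taxids, values)}


def read_fasta_reads(path: str | Path) -> list[ReadRecord]:
    """Load query reads from FASTA, in file order."""
    return [
        ReadRecord(read_id=record.id, sequence=str(record.seq))
        for record in SeqIO.parse(str(path), "fasta")
    ]


def write_predictions_tsv(
    path: str | Path,
    predictions: Iterable[Prediction],
    all_scores: bool = False,
) -> None:
    """Write predictions as TSV: read_id, predicted taxid, log-likelihood.

    With ``all_scores``, a wide table with one extra column per class.
    """
    predictions = list(predictions)
    with open(path, "w") as fh:
        if all_scores and predictions and predictions[0].scores is not None:
            taxids = sorted(predictions[0].scores)
            header = ["read_id", "predicted_species_taxid", "log_likelihood"]
            header += [f"score_{t}" for t in taxids]
            fh.write("\t".join(header) + "\n")
            for p in predictions:
                row = [p.read_id, str(p.predicted_species), f"{p.log_likelihood:.6f}"]
                row += [f"{p.scores[t]:.6f}" for t in taxids]
                fh.write("\t".join(row) + "\n")
        else:
            fh.write("read_id\tpredicted_species_taxid\tlog_likelihood\n")
            for p in predictions:
                fh.write(
                    f"{p.read_id}\t{p.predicted_species}\t{p.log_likelihood:.6f}\n"
                )


def read_predictions_tsv(path: str | Path) -> list[Prediction]:
    """Read back a predictions TSV written by :func:`write_predictions_tsv`."""
    out: list[Prediction] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            row = dict(zip(header, fields))
            out.append(
                Prediction(
                    read_id=row["read_id"],
                    predicted_species=int(row["predicted_species_taxid"]),
                    log_likelihood=float(row["log_likelihood"]),
                )
            )
    return out
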