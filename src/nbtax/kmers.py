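"""k-mer extraction and counting from nucleotide sequences.

k-mers (length-k substrings over the DNA alphabet) are the feature unit of the
classifier: every genome and every query read is reduced to a table of k-mer
counts before any model sees it. Windows containing characters outside
{A, C, G, T} (IUPAC ambiguity codes, gaps) contribute nothing; input case is
ignored and keys are stored uppercase. An optional canonical mode collapses
each k-mer with its reverse complement onto the lexicographically smaller of
the two, for strand-insensitive counting.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "KmerError",
    "SpecMismatchError",
    "KmerSpec",
    "KmerCountTable",
    "revcomp",
    "canonical_form",
    "count_kmers",
    "iter_kmers",
    "merge_tables",
    "shared_kmers",
    "count_fasta",
    "read_jellyfish_dump",
]

MAX_K = 31  # 2-bit packing of a 31-mer fits one 64-bit word

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_RUN = re.compile(r"[ACGT]+")


class KmerError(ValueError):
    """Invalid k-mer configuration or malformed k-mer input."""


class SpecMismatchError(KmerError):
    """Two k-mer containers with incompatible (k, canonical) settings."""


@dataclass(frozen=True)
class KmerSpec:
    """Counting configuration: k-mer length and strand handling.

    Parameters
    ----------
    k : int
        k-mer length, 1 <= k <= 31.
    canonical : bool
        If True, a k-mer and its reverse complement are counted under one
        key, the lexicographic minimum of the pair. Default False: count
        k-mers exactly as read on the given strand.
    """

    k: int
    canonical: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.k, int) or not (1 <= self.k <= MAX_K):
            raise KmerError(f"k must be an integer in [1, {MAX_K}], got {self.k!r}")

    @property
    def n_possible(self) -> int:
        """Alphabet size of the feature space, 4**k."""
        return 4 ** self.k


def revcomp(sequence: str) -> str:
    """Reverse complement of an uppercase A/C/G/T string."""
    return sequence.translate(_COMPLEMENT)[::-1]


def canonical_form(kmer: str) -> str:
    """The lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerCountTable:
    """Sparse k-mer count table: map from k-mer string to positive count.

    Zero-count keys are never stored; ``total`` is the sum of all stored
    counts (for a clean length-L sequence, L - k + 1).
    """

    spec: KmerSpec
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def __getitem__(self, kmer: str) -> int:
        return self.counts.get(kmer, 0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KmerCountTable):
            return NotImplemented
        return self.spec == other.spec and self.counts == other.counts


def iter_kmers(sequence: str, spec: KmerSpec) -> Iterable[str]:
    """Yield every valid k-mer window of ``sequence`` in order.

    Windows overlapping a non-ACGT character are skipped. Yields repeats;
    callers wanting the distinct set should wrap in ``set``.
    """
    k = spec.k
    seq = sequence.upper()
    for match in _VALID_RUN.finditer(seq):
        run = match.group()
        if len(run) < k:
            continue
        if spec.canonical:
            for i in range(len(run) - k + 1):
                yield canonical_form(run[i : i + k])
        else:
            for i in range(len(run) - k + 1):
                yield run[i : i + k]


def count_kmers(sequence: str, spec: KmerSpec) -> KmerCountTable:
    """Count every valid k-mer window of a nucleotide sequence.

    Lowercase input is accepted; windows containing any character outside
    {A, C, G, T} are dropped. For a clean sequence of length L >= k the
    total is exactly L - k + 1.
    """
    counts = Counter(iter_kmers(sequence, spec))
    return KmerCountTable(spec=spec, counts=dict(counts))


def merge_tables(a: KmerCountTable, b: KmerCountTable) -> KmerCountTable:
    """Key-wise sum of two count tables sharing a spec.

    Commutative and associative; the total of the result is the sum of the
    inputs' totals.
    """
    if a.spec != b.spec:
        raise SpecMismatchError(
            f"cannot merge tables with specs {a.spec} and {b.spec}"
        )
    merged = Counter(a.counts)
    merged.update(b.counts)
    return KmerCountTable(spec=a.spec, counts=dict(merged))


def shared_kmers(read: str, reference_kmers: Iterable[str], spec: KmerSpec) -> int:
    """Number of distinct valid k-mers of ``read`` present in a reference set.

    This is the diagnostic used when dissecting individual misclassified
    reads: how many of the read's k-mers each candidate class has seen in
    training.
    """
    ref = set(reference_kmers)
    return len(set(iter_kmers(read, spec)) & ref)


def count_fasta(path: str | Path, spec: KmerSpec) -> KmerCountTable:
    """Count k-mers over every record of a FASTA file, summed into one table."""
    table = KmerCountTable(spec=spec)
    for record in SeqIO.parse(str(path), "fasta"):
        table = merge_tables(table, count_kmers(str(record.seq), spec))
    return table


def read_jellyfish_dump(path: str | Path, spec: KmerSpec) -> KmerCountTable:
    """Import pre-computed counts in Jellyfish text-dump dialect.

    Accepts both the column dump (``<kmer> <count>`` per line) and the
    FASTA-like dump (``>count`` header followed by the k-mer). Keys are
    validated against ``spec.k``.
    """
    counts: Counter[str] = Counter()
    text = Path(path).read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith(">"):
            count = int(line[1:].strip())
            if i + 1 >= len(lines):
                raise KmerError(f"{path}: dangling FASTA-dump header {line!r}")
            kmer = lines[i + 1].upper()
            i += 2
        else:
            parts = line.split()
            if len(parts) != 2:
                raise KmerError(f"{path}: malformed dump line {line!r}")
            kmer, count = parts[0].upper(), int(parts[1])
            i += 1
        if len(kmer) != spec.k or not set(kmer) <= set("ACGT"):
            raise KmerError(f"{path}: key {kmer!r} does not match k={spec.k}")
        if count <= 0:
            raise KmerError(f"{path}: non-positive count for {kmer!r}")
        counts[canonical_form(kmer) if spec.canonical else kmer] += count
    return KmerCountTable(spec=spec, counts=dict(counts))
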