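"""Experimental harness: genome-level cross-validation, trace-back accuracy,
and the incremental yearly-snapshot experiment.

Evaluation follows the design used to measure how a reference-trained
classifier behaves as its database grows:

* genomes (not reads) are split into folds, so a species can appear in both
  training and test sets through different strains — and a species with a
  single genome is *unknown* to a model trained on the other folds;
* every read is classified at species level; accuracy at higher ranks is
  obtained by tracing both prediction and truth to their ancestors at that
  rank ("trace-back");
* in the snapshot experiment the model is updated year by year with only
  that year's training genomes, a fixed held-out read set is re-classified
  after each update, and the incrementally grown store is checked
  byte-for-byte against a store trained from scratch on everything seen so
  far — the exactness claim behind incremental training.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .classify import Prediction, ReadRecord, classify_batchwise
from .kmers import KmerCountTable, KmerSpec, count_fasta, count_kmers
from .model import ModelStore
from .simdata import SimGenome, simulate_reads
from .taxonomy import RANKS, TaxonomyTree

__all__ = [
    "GenomeRecord",
    "FoldAssignment",
    "RankAccuracy",
    "AccuracyReport",
    "SnapshotResult",
    "read_genome_metadata",
    "split_folds",
    "known_species",
    "accuracy_at_levels",
    "train_store",
    "snapshot_experiment",
    "kmer_size_sweep",
    "write_tidy_report",
]


@dataclass
class GenomeRecord:
    """One training/test genome with its species label and release year."""

    genome_id: str
    species_taxid: int
    release_year: int
    fasta_path: Optional[Path] = None
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.release_year < 1995:
            raise ValueError(
                f"{self.genome_id}: implausible release year {self.release_year}"
            )

    @classmethod
    def from_sim(cls, genome: SimGenome) -> "GenomeRecord":
        return cls(
            genome_id=genome.genome_id,
            species_taxid=genome.species_taxid,
            release_year=genome.release_year,
            fasta_path=genome.fasta_path,
            sequence=genome.sequence,
        )

    def kmer_table(self, spec: KmerSpec) -> KmerCountTable:
        if self.sequence is not None:
            return count_kmers(self.sequence, spec)
        if self.fasta_path is not None:
            return count_kmers_cached(self.fasta_path, spec)
        raise ValueError(f"{self.genome_id}: no sequence or FASTA path")


_fasta_cache: dict[tuple[str, KmerSpec], KmerCountTable] = {}


def count_kmers_cached(path: str | Path, spec: KmerSpec) -> KmerCountTable:
    key = (str(path), spec)
    if key not in _fasta_cache:
        _fasta_cache[key] = count_fasta(path, spec)
    return _fasta_cache[key]


def read_genome_metadata(path: str | Path) -> list[GenomeRecord]:
    """Parse a genome metadata table into records (no sequences attached).

    Accepts the plain dialect (columns genome_id, species_taxid,
    release_date) and the assembly-summary dialect ("#"-prefixed header,
    columns including assembly_accession, species_taxid, version_status,
    assembly_level, seq_rel_date); in the latter, rows are filtered to
    "Complete Genome" assembly level and "latest" version status. Release
    dates may be bare years or YYYY/MM/DD.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        return []
    records: list[GenomeRecord] = []
    header_line = lines[0]
    if header_line.startswith("#"):
        # assembly-summary dialect: last '#' line is the column header
        header_idx = max(i for i, ln in enumerate(lines) if ln.startswith("#"))
        columns = lines[header_idx].lstrip("# ").split("\t")
        col = {name: i for i, name in enumerate(columns)}
        id_col = col.get("assembly_accession", col.get("genome_id", 0))
        for line in lines[header_idx + 1 :]:
            if not line.strip():
                continue
            fields = line.split("\t")
            if "assembly_level" in col and fields[col["assembly_level"]].lower() != "complete genome":
                continue
            if "version_status" in col and fields[col["version_status"]] != "latest":
                continue
            date = fields[col["seq_rel_date"] if "seq_rel_date" in col else col["release_date"]]
            records.append(
                GenomeRecord(
                    genome_id=fields[id_col],
                    species_taxid=int(fields[col["species_taxid"]]),
                    release_year=int(date.split("/")[0].split("-")[0]),
                )
            )
    else:
        columns = header_line.split("\t")
        col = {name: i for i, name in enumerate(columns)}
        for line in lines[1:]:
            if not line.strip():
                continue
            fields = line.split("\t")
            date = fields[col["release_date"]]
            records.append(
                GenomeRecord(
                    genome_id=fields[col["genome_id"]],
                    species_taxid=int(fields[col["species_taxid"]]),
                    release_year=int(date.split("/")[0].split("-")[0]),
                )
            )
    return records


@dataclass
class FoldAssignment:
    """Genome-id -> fold mapping (folds numbered 1..n), plus its seed."""

    folds: dict[str, int]
    n_folds: int
    seed: int

    def fold_of(self, genome_id: str) -> int:
        return self.folds[genome_id]

    def members(self, fold: int) -> list[str]:
        return sorted(g for g, f in self.folds.items() if f == fold)


def split_folds(
    genomes: Sequence[GenomeRecord], n_folds: int = 5, seed: int = 0
) -> FoldAssignment:
    """Balanced random genome-level partition into folds (sizes differ <= 1).

    Deterministic for a fixed seed. Species may straddle folds: the split
    is by genome, so training can see some strains of a species while other
    strains are held out — and small species may be entirely held out.
    """
    if len(genomes) < n_folds:
        raise ValueError(
            f"need at least {n_folds} genomes for {n_folds} folds, got {len(genomes)}"
        )
    ids = sorted(g.genome_id for g in genomes)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds = {ids[int(idx)]: (pos % n_folds) + 1 for pos, idx in enumerate(order)}
    return FoldAssignment(folds=folds, n_folds=n_folds, seed=seed)


def known_species(training_genomes: Iterable[GenomeRecord]) -> set[int]:
    """Species with at least one training genome; reads from any other
    species are "unknown" and cannot be labelled correctly at species rank."""
    return {g.species_taxid for g in training_genomes}


@dataclass
class RankAccuracy:
    accuracy_all: float
    accuracy_known: float
    n_unresolved: int


@dataclass
class AccuracyReport:
    """Trace-back accuracy at each named rank, for all and for known reads."""

    per_rank: dict[str, RankAccuracy]
    fraction_known: float
    n_reads: int


def accuracy_at_levels(
    predictions: Sequence[Prediction],
    truth: dict[str, int],
    tree: TaxonomyTree,
    known_set: set[int],
) -> AccuracyReport:
    """Score predictions at species..phylum by ancestor trace-back.

    At each rank a read is correct iff the predicted and true species
    trace to the same (resolvable) ancestor. Reads whose *truth* lineage
    lacks the rank are skipped at that rank and counted as unresolved.
    A read is "known" iff its true species has a training genome.
    """
    n = len(predictions)
    if n == 0:
        raise ValueError("empty prediction set")
    known_flags = [truth[p.read_id] in known_set for p in predictions]
    n_known = sum(known_flags)
    per_rank: dict[str, RankAccuracy] = {}
    for rank in RANKS:
        correct_all = correct_known = 0
        denom_all = denom_known = 0
        unresolved = 0
        for pred, is_known in zip(predictions, known_flags):
            true_anc = tree.ancestor_at_rank(truth[pred.read_id], rank)
            if true_anc is None:
                unresolved += 1
                continue
            pred_anc = tree.ancestor_at_rank(pred.predicted_species, rank)
            hit = pred_anc is not None and pred_anc == true_anc
            denom_all += 1
            correct_all += hit
            if is_known:
                denom_known += 1
                correct_known += hit
        per_rank[rank] = RankAccuracy(
            accuracy_all=correct_all / denom_all if denom_all else float("nan"),
            accuracy_known=correct_known / denom_known if denom_known else float("nan"),
            n_unresolved=unresolved,
        )
    return AccuracyReport(
        per_rank=per_rank, fraction_known=n_known / n, n_reads=n
    )


def train_store(
    root: str | Path, genomes: Sequence[GenomeRecord], spec: KmerSpec
) -> ModelStore:
    """Batch-train a fresh store: group genomes by species, one update each."""
    store = ModelStore.create(root, spec)
    by_species: dict[int, list[GenomeRecord]] = {}
    for genome in genomes:
        by_species.setdefault(genome.species_taxid, []).append(genome)
    for taxid in sorted(by_species):
        tables = [g.kmer_table(spec) for g in by_species[taxid]]
        store.update_class(taxid, tables)
    return store


def _store_digest(store: ModelStore) -> str:
    """Order-independent digest over every file of a store directory."""
    digest = hashlib.sha256()
    for path in sorted(store.root.iterdir()):
        digest.update(path.name.encode())
        digest.update(path.read_bytes())
    return digest.hexdigest()


@dataclass
class SnapshotResult:
    """Outcome of the yearly incremental-snapshot experiment."""

    years: list[int]
    reports: dict[int, AccuracyReport]
    predictions: dict[int, list[Prediction]] = field(repr=False, default_factory=dict)
    scratch_identical: dict[int, bool] = field(default_factory=dict)
    genomes_processed_incremental: int = 0
    genomes_processed_scratch: int = 0


def snapshot_experiment(
    train_genomes: Sequence[GenomeRecord],
    test_reads: Sequence[ReadRecord],
    truth: dict[str, int],
    tree: TaxonomyTree,
    spec: KmerSpec,
    workdir: str | Path,
    years: Optional[Sequence[int]] = None,
    mode: str = "unique",
    verify_scratch: bool = True,
    keep_predictions: bool = False,
) -> SnapshotResult:
    """Grow a store year by year and re-classify a fixed held-out read set.

    For each year (ascending, or the given order) the store is updated with
    only that year's training genomes and the full test read set is
    classified; an AccuracyReport is emitted per year. With
    ``verify_scratch``, after every year a scratch store is batch-trained
    on all genomes seen so far and compared byte-for-byte with the
    incremental store. The genome-processing counters expose the cost
    asymmetry: the incremental path touches each genome once, the
    scratch-per-year path re-processes every prior genome at every year.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if years is None:
        years = sorted({g.release_year for g in train_genomes})
    years = list(years)
    by_year: dict[int, list[GenomeRecord]] = {y: [] for y in years}
    for genome in train_genomes:
        if genome.release_year in by_year:
            by_year[genome.release_year].append(genome)

    store = ModelStore.create(workdir / "incremental", spec)
    result = SnapshotResult(years=years, reports={})
    seen: list[GenomeRecord] = []
    for year in years:
        batch = by_year[year]
        by_species: dict[int, list[GenomeRecord]] = {}
        for genome in batch:
            by_species.setdefault(genome.species_taxid, []).append(genome)
        for taxid in sorted(by_species):
            store.update_class(
                taxid, [g.kmer_table(spec) for g in by_species[taxid]]
            )
        seen.extend(batch)
        result.genomes_processed_incremental += len(batch)

        if verify_scratch:
            scratch_root = workdir / f"scratch_{year}"
            if scratch_root.exists():
                shutil.rmtree(scratch_root)
            scratch = train_store(scratch_root, seen, spec)
            result.genomes_processed_scratch += len(seen)
            result.scratch_identical[year] = _store_digest(store) == _store_digest(
                scratch
            )
            shutil.rmtree(scratch_root)

        if store.index:
            predictions = classify_batchwise(store, test_reads, mode=mode)
            result.reports[year] = accuracy_at_levels(
                predictions, truth, tree, known_species(seen)
            )
            if keep_predictions:
                result.predictions[year] = predictions
    return result


def simulate_test_reads(
    genomes: Sequence[GenomeRecord],
    n_reads: int,
    read_length: int,
    seed: int,
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Simulate error-free reads from test genomes; return reads + truth map."""
    reads: list[ReadRecord] = []
    truth: dict[str, int] = {}
    for i, genome in enumerate(sorted(genomes, key=lambda g: g.genome_id)):
        if genome.sequence is None:
            raise ValueError(f"{genome.genome_id}: sequence required to simulate reads")
        for header, seq in simulate_reads(
            genome.sequence,
            n_reads,
            read_length,
            seed=seed + i,
            genome_id=genome.genome_id,
            species_taxid=genome.species_taxid,
        ):
            reads.append(ReadRecord(read_id=header, sequence=seq))
            truth[header] = genome.species_taxid
    return reads, truth


def kmer_size_sweep(
    genomes: Sequence[GenomeRecord],
    tree: TaxonomyTree,
    k_values: Sequence[int],
    workdir: str | Path,
    fold_assignment: Optional[FoldAssignment] = None,
    test_folds: Optional[Sequence[int]] = None,
    n_folds: int = 5,
    seed: int = 0,
    mode: str = "unique",
    reads_per_genome: int = 100,
    read_length: int = 150,
) -> dict[int, float]:
    """Mean species-level accuracy (all test reads) per k-mer size.

    Runs genome-level cross-validation at each k; ``test_folds`` restricts
    which folds serve as the held-out set (all folds by default).
    """
    workdir = Path(workdir)
    if fold_assignment is None:
        fold_assignment = split_folds(genomes, n_folds=n_folds, seed=seed)
    folds = list(test_folds) if test_folds else list(range(1, fold_assignment.n_folds + 1))
    results: dict[int, float] = {}
    for k in k_values:
        spec = KmerSpec(k=k)
        accuracies = []
        for fold in folds:
            train = [g for g in genomes if fold_assignment.fold_of(g.genome_id) != fold]
            test = [g for g in genomes if fold_assignment.fold_of(g.genome_id) == fold]
            reads, truth = simulate_test_reads(
                test, reads_per_genome, read_length, seed=seed + 1000 * fold
            )
            root = workdir / f"sweep_k{k}_fold{fold}"
            if root.exists():
                shutil.rmtree(root)
            store = train_store(root, train, spec)
            predictions = classify_batchwise(store, reads, mode=mode)
            report = accuracy_at_levels(
                predictions, truth, tree, known_species(train)
            )
            accuracies.append(report.per_rank["species"].accuracy_all)
            shutil.rmtree(root)
        results[k] = float(np.mean(accuracies))
    return results


def write_tidy_report(
    path: str | Path,
    rows: Iterable[tuple],
    header: Sequence[str] = ("fold", "year", "rank", "metric", "value"),
) -> None:
    """Write a tidy TSV of (fold, year, rank, metric, value) rows."""
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def report_rows(
    report: AccuracyReport, fold: object = "", year: object = ""
) -> list[tuple]:
    """Flatten an AccuracyReport into tidy rows for :func:`write_tidy_report`."""
    rows: list[tuple] = [(fold, year, "", "fraction_known", report.fraction_known)]
    for rank, acc in report.per_rank.items():
        rows.append((fold, year, rank, "accuracy_all", acc.accuracy_all))
        rows.append((fold, year, rank, "accuracy_known", acc.accuracy_known))
        rows.append((fold, year, rank, "n_unresolved", acc.n_unresolved))
    return rows


def summary_json(result: SnapshotResult) -> str:
    """JSON summary of a snapshot experiment (per-year accuracies, counters)."""
    payload = {
        "years": result.years,
        "genomes_processed_incremental": result.genomes_processed_incremental,
        "genomes_processed_scratch": result.genomes_processed_scratch,
        "scratch_identical": {str(y): v for y, v in result.scratch_identical.items()},
        "per_year": {
            str(year): {
                "fraction_known": report.fraction_known,
                "n_reads": report.n_reads,
                "accuracy_all": {
                    rank: acc.accuracy_all for rank, acc in report.per_rank.items()
                },
                "accuracy_known": {
                    rank: acc.accuracy_known for rank, acc in report.per_rank.items()
                },
            }
            for year, report in result.reports.items()
        },
    }
    return json.dumps(payload, indent=2, sort_keys=True)
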