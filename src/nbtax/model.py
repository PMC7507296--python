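"""Incremental naive Bayes model store.

Each species class is one savefile of raw integer k-mer counts f(x_j | y_i)
accumulated over all training genomes of that species, plus the genome tally.
Because savefiles hold raw counts (not probabilities), incremental updates
are integer addition and are therefore *exactly* equivalent to batch
training: any partition of the training genomes into update steps, in any
order, yields byte-identical savefiles. That exactness is the point of the
design — adding a genome, adding a whole new species, or merging two species
classes touches only the affected savefiles and never reprocesses old data.

Laplace (add-one) smoothing is applied at query time:

    P(x_j | y_i) = (f(x_j | y_i) + 1) / (T_i + 4**k)

with T_i the class's total k-mer count, so unseen k-mers get a small but
nonzero probability. All probabilities are returned as natural logs.
"""

from __future__ import annotations

import json
import math
import shutil
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .kmers import KmerCountTable, KmerSpec, SpecMismatchError, merge_tables

__all__ = [
    "ModelError",
    "ModelIntegrityError",
    "ClassModel",
    "ModelStore",
    "log_smoothed_prob",
]

FORMAT_VERSION = 1
_MANIFEST = "store.json"


class ModelError(Exception):
    """Base class for model-store failures."""


class ModelIntegrityError(ModelError):
    """Savefile fails its internal consistency checks."""


@dataclass
class ClassModel:
    """One species' model: raw k-mer counts, their total, and genome tally."""

    species_taxid: int
    counts: KmerCountTable
    n_genomes: int = 1

    @property
    def spec(self) -> KmerSpec:
        return self.counts.spec

    @property
    def total(self) -> int:
        """T_i: sum of all raw counts in the class."""
        return self.counts.total

    def log_denominator(self) -> float:
        """log(T_i + 4**k), the smoothing denominator in log space."""
        return math.log(self.total + self.spec.n_possible)


def log_smoothed_prob(model: ClassModel, kmer: str) -> float:
    """Natural-log Laplace-smoothed probability of one k-mer under a class.

    log[(f + 1) / (T_i + 4**k)] with f the stored raw count (0 if the class
    never saw the k-mer); finite for every k-mer by construction.
    """
    if len(kmer) != model.spec.k:
        raise ModelError(
            f"k-mer {kmer!r} has length {len(kmer)}, model expects k={model.spec.k}"
        )
    f = model.counts[kmer]
    return math.log(f + 1) - model.log_denominator()


def _format_savefile(model: ClassModel) -> str:
    lines = [
        f"# nbtax-class format {FORMAT_VERSION}",
        f"# species_taxid: {model.species_taxid}",
        f"# k: {model.spec.k}",
        f"# canonical: {'true' if model.spec.canonical else 'false'}",
        f"# n_genomes: {model.n_genomes}",
        f"# total: {model.total}",
    ]
    lines.extend(f"{kmer}\t{count}" for kmer, count in sorted(model.counts.counts.items()))
    return "\n".join(lines) + "\n"


def _parse_savefile(text: str, path: Path) -> ClassModel:
    header: dict[str, str] = {}
    counts: dict[str, int] = {}
    for line in text.splitlines():
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, value = body.split(":", 1)
                header[key.strip()] = value.strip()
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ModelIntegrityError(f"{path}: malformed count line {line!r}")
        counts[parts[0]] = int(parts[1])
    try:
        taxid = int(header["species_taxid"])
        k = int(header["k"])
        canonical = header["canonical"] == "true"
        n_genomes = int(header["n_genomes"])
        declared_total = int(header["total"])
    except KeyError as exc:
        raise ModelIntegrityError(f"{path}: savefile header missing {exc}") from exc
    spec = KmerSpec(k=k, canonical=canonical)
    if any(len(kmer) != k for kmer in counts):
        raise ModelIntegrityError(f"{path}: key of wrong length for k={k}")
    if any(c <= 0 for c in counts.values()):
        raise ModelIntegrityError(f"{path}: non-positive count stored")
    model = ClassModel(
        species_taxid=taxid,
        counts=KmerCountTable(spec=spec, counts=counts),
        n_genomes=n_genomes,
    )
    if model.total != declared_total:
        raise ModelIntegrityError(
            f"{path}: declared total {declared_total} != sum of counts {model.total}"
            " (truncated or corrupted savefile)"
        )
    return model


class ModelStore:
    """Directory of per-class savefiles plus a JSON manifest.

    Layout: ``<root>/<species_taxid>.nbc`` (one file per class) and
    ``<root>/store.json`` recording k, canonical flag, format version and the
    class index. All savefiles share one :class:`KmerSpec`.
    """

    def __init__(self, root: str | Path, spec: KmerSpec):
        self.root = Path(root)
        self.spec = spec

    # -- construction -------------------------------------------------

    @classmethod
    def create(cls, root: str | Path, spec: KmerSpec) -> "ModelStore":
        root = Path(root)
        root.mkdir(parents=True, exist_ok=True)
        if (root / _MANIFEST).exists():
            raise ModelError(f"{root}: store already exists")
        store = cls(root, spec)
        store._write_manifest([])
        return store

    @classmethod
    def open(cls, root: str | Path) -> "ModelStore":
        root = Path(root)
        manifest_path = root / _MANIFEST
        if not manifest_path.exists():
            raise ModelError(f"{root}: no store manifest found")
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("format_version") != FORMAT_VERSION:
            raise ModelError(
                f"{root}: unsupported store format {manifest.get('format_version')}"
            )
        spec = KmerSpec(k=manifest["k"], canonical=manifest["canonical"])
        store = cls(root, spec)
        on_disk = {int(p.stem) for p in root.glob("*.nbc")}
        if on_disk != set(manifest["classes"]):
            raise ModelIntegrityError(
                f"{root}: manifest class index does not match directory contents"
            )
        return store

    # -- manifest / index ---------------------------------------------

    def _write_manifest(self, classes: Iterable[int]) -> None:
        manifest = {
            "format_version": FORMAT_VERSION,
            "k": self.spec.k,
            "canonical": self.spec.canonical,
            "classes": sorted(set(classes)),
        }
        (self.root / _MANIFEST).write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )

    @property
    def index(self) -> list[int]:
        """Sorted species taxids with a savefile in the store."""
        manifest = json.loads((self.root / _MANIFEST).read_text())
        return sorted(manifest["classes"])

    def class_path(self, species_taxid: int) -> Path:
        return self.root / f"{species_taxid}.nbc"

    def __contains__(self, species_taxid: int) -> bool:
        return self.class_path(species_taxid).exists()

    def __len__(self) -> int:
        return len(self.index)

    # -- savefile I/O --------------------------------------------------

    def save_class(self, model: ClassModel) -> None:
        """Write one class savefile (byte-deterministic: keys sorted)."""
        if model.spec != self.spec:
            raise SpecMismatchError(
                f"class spec {model.spec} incompatible with store spec {self.spec}"
            )
        if model.n_genomes < 1:
            raise ModelError("a persisted class must have absorbed >= 1 genome")
        self.class_path(model.species_taxid).write_text(_format_savefile(model))
        self._write_manifest(set(self.index) | {model.species_taxid})

    def load_class(self, species_taxid: int) -> ClassModel:
        path = self.class_path(species_taxid)
        if not path.exists():
            raise ModelError(f"no savefile for species {species_taxid} in {self.root}")
        model = _parse_savefile(path.read_text(), path)
        if model.spec != self.spec:
            raise SpecMismatchError(
                f"{path}: savefile spec {model.spec} != store spec {self.spec}"
            )
        if model.species_taxid != species_taxid:
            raise ModelIntegrityError(
                f"{path}: header taxid {model.species_taxid} != filename"
            )
        return model

    # -- incremental operations ---------------------------------------

    def update_class(
        self, species_taxid: int, genome_tables: Sequence[KmerCountTable]
    ) -> ClassModel:
        """Absorb new genomes into one class (creating it if absent).

        Each element of ``genome_tables`` is the k-mer count table of one
        genome; the class's counts become the key-wise sum and the genome
        tally increments per genome. No other class's savefile is touched,
        which is what makes updates cheap regardless of store size.
        """
        for table in genome_tables:
            if table.spec != self.spec:
                raise SpecMismatchError(
                    f"genome table spec {table.spec} != store spec {self.spec}"
                )
        if species_taxid in self:
            model = self.load_class(species_taxid)
        else:
            model = ClassModel(
                species_taxid=species_taxid,
                counts=KmerCountTable(spec=self.spec),
                n_genomes=0,
            )
        counts = model.counts
        for table in genome_tables:
            counts = merge_tables(counts, table)
        model = ClassModel(
            species_taxid=species_taxid,
            counts=counts,
            n_genomes=model.n_genomes + len(genome_tables),
        )
        self.save_class(model)
        return model

    def merge_classes(self, from_taxid: int, into_taxid: int) -> ClassModel:
        """Fold class A into class B after a taxonomic merge.

        B's counts become the key-wise sum of A and B (genome tallies
        summed) and A's savefile is removed — exactly the model that
        training B on both classes' genomes from scratch would give.
        """
        if from_taxid == into_taxid:
            warnings.warn(
                f"merge of class {from_taxid} into itself is a no-op",
                stacklevel=2,
            )
            return self.load_class(into_taxid)
        source = self.load_class(from_taxid)
        target = self.load_class(into_taxid)
        merged = ClassModel(
            species_taxid=into_taxid,
            counts=merge_tables(source.counts, target.counts),
            n_genomes=source.n_genomes + target.n_genomes,
        )
        self.save_class(merged)
        self.class_path(from_taxid).unlink()
        self._write_manifest(set(self.index) - {from_taxid})
        return merged

    def delete_class(self, species_taxid: int) -> None:
        """Remove a class savefile (taxid retired from the reference)."""
        path = self.class_path(species_taxid)
        if not path.exists():
            raise ModelError(f"no savefile for species {species_taxid} in {self.root}")
        path.unlink()
        self._write_manifest(set(self.index) - {species_taxid})

    def copy_to(self, dest: str | Path) -> "ModelStore":
        """Byte-faithful copy of the whole store (for snapshot experiments)."""
        dest = Path(dest)
        if dest.exists():
            raise ModelError(f"{dest}: destination already exists")
        shutil.copytree(self.root, dest)
        return ModelStore.open(dest)
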