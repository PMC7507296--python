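"""Synthetic taxonomy, genomes and reads for self-contained experiments.

The generator emulates the structure of a reference-genome training corpus:

* a small taxonomy with full six-rank chains
  (root -> phylum -> class -> order -> family -> genus -> species), written
  in the exact NCBI dump dialect so the taxonomy parser consumes it
  unmodified;
* genomes derived by mutation from shared ancestors — one random ancestral
  sequence per genus, each species a mutated copy of its genus ancestor,
  each strain a (more lightly) mutated copy of its species sequence — so
  species are separable and congeneric species resemble each other more
  than cross-genus pairs;
* release years attached to strains round-robin, for incremental-snapshot
  experiments;
* error-free fixed-length reads cut from genomes at uniform random
  positions (100 per genome by default), with the truth species carried in
  the FASTA header.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .taxonomy import TaxonomyTree

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "simulate_taxonomy",
    "write_taxdump",
    "simulate_genomes",
    "simulate_reads",
    "simulate_dataset",
    "parse_read_header",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic corpus.

    Defaults give 2 phyla x 2 genera x 3 species x 2 strains (24 genomes of
    12 species) of 20 kb, with 10% per-base divergence between congeneric
    species and 1% between strains of one species, 100 error-free 150 bp
    reads per genome, and four release years.
    """

    n_phyla: int = 2
    genera_per_phylum: int = 2
    species_per_genus: int = 3
    strains_per_species: int = 2
    genome_length: int = 20_000
    species_divergence: float = 0.10
    strain_divergence: float = 0.01
    years: tuple[int, ...] = (2016, 2017, 2018, 2019)
    reads_per_genome: int = 100
    read_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_phyla",
            "genera_per_phylum",
            "species_per_genus",
            "strains_per_species",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("species_divergence", "strain_divergence"):
            d = getattr(self, name)
            if not (0.0 <= d <= 0.75):
                raise ValueError(f"{name} must be in [0, 0.75], got {d}")
        if self.strain_divergence >= self.species_divergence and self.species_divergence > 0:
            if self.strain_divergence > self.species_divergence:
                raise ValueError(
                    "strain_divergence must not exceed species_divergence"
                )


@dataclass
class SimGenome:
    """One simulated strain genome with its labels and provenance."""

    genome_id: str
    species_taxid: int
    genus_taxid: int
    release_year: int
    sequence: str
    fasta_path: Optional[Path] = None


@dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    config: SimConfig
    tree: TaxonomyTree
    genomes: list[SimGenome]
    taxdump_dir: Optional[Path] = None
    genomes_dir: Optional[Path] = None
    metadata_path: Optional[Path] = None

    def species_taxids(self) -> list[int]:
        return sorted({g.species_taxid for g in self.genomes})


def simulate_taxonomy(config: SimConfig) -> TaxonomyTree:
    """Build the synthetic taxonomy: full six-rank chains under one root.

    Taxids are assigned deterministically (depth-first, consecutive
    integers starting at 2; the root is 1), so the same config always
    produces the identical tree.
    """
    tree = TaxonomyTree(root_taxid=1)
    tree.nodes[1] = (1, "no rank", "root")
    next_id = 2
    chain_ranks = ("phylum", "class", "order", "family", "genus")
    for p in range(config.n_phyla):
        parent = 1
        # phylum gets its own node; class/order/family chain hangs per genus
        phylum_id = next_id
        tree.nodes[phylum_id] = (parent, "phylum", f"Phylum_{p + 1}")
        next_id += 1
        for g in range(config.genera_per_phylum):
            parent = phylum_id
            for rank in chain_ranks[1:]:
                label = f"{rank.capitalize()}_{p + 1}_{g + 1}"
                tree.nodes[next_id] = (parent, rank, label)
                parent = next_id
                next_id += 1
            genus_id = parent
            for s in range(config.species_per_genus):
                tree.nodes[next_id] = (
                    genus_id,
                    "species",
                    f"Species_{p + 1}_{g + 1}_{s + 1}",
                )
                next_id += 1
    tree.validate()
    return tree


def write_taxdump(tree: TaxonomyTree, outdir: str | Path) -> Path:
    """Write nodes.dmp / names.dmp (and merged.dmp if any) in NCBI dialect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "nodes.dmp", "w") as fh:
        for taxid in sorted(tree.nodes):
            parent, rank, _ = tree.nodes[taxid]
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(outdir / "names.dmp", "w") as fh:
        for taxid in sorted(tree.nodes):
            _, _, name = tree.nodes[taxid]
            fh.write(f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|\n")
    if tree.merged:
        with open(outdir / "merged.dmp", "w") as fh:
            for old in sorted(tree.merged):
                fh.write(f"{old}\t|\t{tree.merged[old]}\t|\n")
    return outdir


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mutate(
    rng: np.random.Generator, sequence: np.ndarray, rate: float
) -> np.ndarray:
    """Substitute each base independently with probability ``rate``.

    A substituted base is always changed (shift of 1-3 mod 4), so ``rate``
    is the realised per-base substitution fraction in expectation.
    """
    if rate <= 0.0:
        return sequence.copy()
    mask = rng.random(sequence.shape[0]) < rate
    shifts = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
    out = sequence.copy()
    out[mask] = (out[mask] + shifts) % 4
    return out


def _to_string(encoded: np.ndarray) -> str:
    return _BASES[encoded].tobytes().decode("ascii")


def simulate_genomes(
    tree: TaxonomyTree,
    config: SimConfig,
    outdir: str | Path | None = None,
) -> tuple[list[SimGenome], Optional[Path]]:
    """Generate strain genomes by hierarchical mutation; optionally write them.

    One random ancestral sequence per genus; each species mutates the genus
    ancestor at ``species_divergence``; each strain mutates its species
    sequence at ``strain_divergence``. Strains are assigned release years
    round-robin in generation order. When ``outdir`` is given, one FASTA
    per genome plus a metadata TSV (genome_id, species_taxid, release_date)
    are written and paths recorded.
    """
    rng = np.random.default_rng(config.seed)
    species_by_genus: dict[int, list[int]] = {}
    for taxid in sorted(tree.nodes):
        parent, rank, _ = tree.nodes[taxid]
        if rank == "species":
            species_by_genus.setdefault(parent, []).append(taxid)

    genomes: list[SimGenome] = []
    year_cursor = 0
    for genus_id in sorted(species_by_genus):
        ancestor = _random_sequence(rng, config.genome_length)
        for species_id in species_by_genus[genus_id]:
            species_seq = _mutate(rng, ancestor, config.species_divergence)
            for strain in range(config.strains_per_species):
                strain_seq = _mutate(rng, species_seq, config.strain_divergence)
                year = config.years[year_cursor % len(config.years)]
                year_cursor += 1
                genomes.append(
                    SimGenome(
                        genome_id=f"G{species_id}_{strain + 1}",
                        species_taxid=species_id,
                        genus_taxid=genus_id,
                        release_year=year,
                        sequence=_to_string(strain_seq),
                    )
                )

    metadata_path: Optional[Path] = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for genome in genomes:
            path = outdir / f"{genome.genome_id}.fasta"
            with open(path, "w") as fh:
                fh.write(f">{genome.genome_id} species_taxid={genome.species_taxid}\n")
                seq = genome.sequence
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
            genome.fasta_path = path
        metadata_path = outdir / "metadata.tsv"
        with open(metadata_path, "w") as fh:
            fh.write("genome_id\tspecies_taxid\trelease_date\n")
            for genome in genomes:
                fh.write(
                    f"{genome.genome_id}\t{genome.species_taxid}\t"
                    f"{genome.release_year}/01/01\n"
                )
    return genomes, metadata_path


def simulate_reads(
    genome: SimGenome | str,
    n_reads: int,
    read_length: int,
    seed: int,
    genome_id: str = "genome",
    species_taxid: int = 0,
    both_strands: bool = False,
) -> list[tuple[str, str]]:
    """Cut error-free fixed-length fragments at uniform random positions.

    Returns (header, sequence) pairs; the header carries the source genome
    id and truth species taxid (``<genome_id>|<taxid>|r<i>``). With
    ``both_strands`` the strand is drawn uniformly and reverse-complemented
    reads are emitted; default is forward-only, matching the default
    non-canonical k-mer counter.
    """
    if isinstance(genome, SimGenome):
        sequence = genome.sequence
        genome_id = genome.genome_id
        species_taxid = genome.species_taxid
    else:
        sequence = genome
    if read_length > len(sequence):
        raise ValueError(
            f"read_length {read_length} exceeds genome length {len(sequence)}"
        )
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, len(sequence) - read_length + 1, size=n_reads)
    if both_strands:
        flip = rng.random(n_reads) < 0.5
    else:
        flip = np.zeros(n_reads, dtype=bool)
    complement = str.maketrans("ACGT", "TGCA")
    reads = []
    for i, (start, rc) in enumerate(zip(starts, flip)):
        frag = sequence[int(start) : int(start) + read_length]
        if rc:
            frag = frag.translate(complement)[::-1]
        reads.append((f"{genome_id}|{species_taxid}|r{i}", frag))
    return reads


def parse_read_header(read_id: str) -> tuple[str, int]:
    """Recover (genome_id, species_taxid) from a simulated read id."""
    genome_id, taxid, _ = read_id.split("|")
    return genome_id, int(taxid)


def write_reads_fasta(path: str | Path, reads: list[tuple[str, str]]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for header, seq in reads:
            fh.write(f">{header}\n{seq}\n")
    return path


def simulate_dataset(
    config: SimConfig, outdir: str | Path | None = None
) -> SimulatedDataset:
    """Generate the full corpus: taxonomy, genomes, metadata (and dmp files)."""
    tree = simulate_taxonomy(config)
    taxdump_dir = None
    genomes_dir = None
    if outdir is not None:
        outdir = Path(outdir)
        taxdump_dir = write_taxdump(tree, outdir / "taxdump")
        genomes_dir = outdir / "genomes"
    genomes, metadata_path = simulate_genomes(tree, config, genomes_dir)
    return SimulatedDataset(
        config=config,
        tree=tree,
        genomes=genomes,
        taxdump_dir=taxdump_dir,
        genomes_dir=genomes_dir,
        metadata_path=metadata_path,
    )
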