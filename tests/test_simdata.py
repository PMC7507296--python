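"""Synthetic corpus generator: taxonomy structure, divergence statistics,
read simulation and byte determinism."""

import math

import numpy as np
import pytest

from nbtax.kmers import revcomp
from nbtax.simdata import (
    SimConfig,
    simulate_dataset,
    simulate_genomes,
    simulate_reads,
    simulate_taxonomy,
    parse_read_header,
    write_taxdump,
)
from nbtax.taxonomy import RANKS, load_taxdump


def small_config(**overrides):
    defaults = dict(
        n_phyla=1,
        genera_per_phylum=1,
        species_per_genus=2,
        strains_per_species=2,
        genome_length=2_000,
        seed=5,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


class TestSimulateTaxonomy:
    def test_minimal_structure(self):
        tree = simulate_taxonomy(small_config())
        species = [t for t, (_, r, _) in tree.nodes.items() if r == "species"]
        assert len(species) == 2
        genera = {tree.ancestor_at_rank(s, "genus") for s in species}
        assert len(genera) == 1  # both species share the one genus

    def test_every_species_has_all_six_ranks(self):
        tree = simulate_taxonomy(SimConfig(seed=0))
        for taxid, (_, rank, _) in tree.nodes.items():
            if rank == "species":
                for level in RANKS:
                    assert tree.ancestor_at_rank(taxid, level) is not None

    def test_dump_files_parse_and_are_deterministic(self, tmp_path):
        config = small_config()
        d1 = write_taxdump(simulate_taxonomy(config), tmp_path / "a")
        d2 = write_taxdump(simulate_taxonomy(config), tmp_path / "b")
        assert (d1 / "nodes.dmp").read_bytes() == (d2 / "nodes.dmp").read_bytes()
        assert (d1 / "names.dmp").read_bytes() == (d2 / "names.dmp").read_bytes()
        tree = load_taxdump(d1 / "nodes.dmp", d1 / "names.dmp")
        assert len(tree.nodes) == len(simulate_taxonomy(config).nodes)


class TestSimulateGenomes:
    def test_zero_strain_divergence_gives_identical_strains(self):
        config = small_config(strain_divergence=0.0, species_divergence=0.1)
        tree = simulate_taxonomy(config)
        genomes, _ = simulate_genomes(tree, config)
        by_species = {}
        for g in genomes:
            by_species.setdefault(g.species_taxid, []).append(g.sequence)
        for sequences in by_species.values():
            assert len(set(sequences)) == 1

    def test_strain_hamming_matches_binomial_expectation(self):
        # two strains mutate independently from the species sequence at rate d;
        # a site differs with probability 2d(1-d) + (2/3)d^2
        d = 0.05
        config = small_config(
            strain_divergence=d, species_divergence=0.2, genome_length=20_000
        )
        tree = simulate_taxonomy(config)
        genomes, _ = simulate_genomes(tree, config)
        by_species = {}
        for g in genomes:
            by_species.setdefault(g.species_taxid, []).append(g.sequence)
        p = 2 * d * (1 - d) + (2 / 3) * d * d
        for s1, s2 in by_species.values():
            observed = sum(a != b for a, b in zip(s1, s2)) / len(s1)
            sigma = math.sqrt(p * (1 - p) / len(s1))
            assert abs(observed - p) < 3 * sigma

    def test_same_seed_is_byte_identical(self, tmp_path):
        config = small_config()
        tree = simulate_taxonomy(config)
        _, meta1 = simulate_genomes(tree, config, tmp_path / "a")
        _, meta2 = simulate_genomes(tree, config, tmp_path / "b")
        assert meta1.read_bytes() == meta2.read_bytes()
        for f in sorted((tmp_path / "a").glob("*.fasta")):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_years_assigned_round_robin(self):
        config = small_config(years=(2001, 2002))
        tree = simulate_taxonomy(config)
        genomes, _ = simulate_genomes(tree, config)
        assert [g.release_year for g in genomes] == [2001, 2002, 2001, 2002]

    def test_strain_divergence_above_species_rejected(self):
        with pytest.raises(ValueError):
            small_config(strain_divergence=0.2, species_divergence=0.1)


class TestSimulateReads:
    def test_reads_are_exact_substrings(self):
        rng = np.random.default_rng(0)
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        reads = simulate_reads(genome, 50, 100, seed=2)
        for _, seq in reads:
            assert seq in genome

    def test_default_read_count_is_one_hundred(self):
        rng = np.random.default_rng(1)
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        reads = simulate_reads(genome, SimConfig().reads_per_genome, 150, seed=3)
        assert len(reads) == 100

    def test_both_strands_flag_emits_revcomp_fragments(self):
        rng = np.random.default_rng(4)
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        reads = simulate_reads(genome, 60, 80, seed=5, both_strands=True)
        forward = sum(seq in genome for _, seq in reads)
        reverse = sum(revcomp(seq) in genome for _, seq in reads)
        assert forward + reverse >= 60  # every read maps on one strand
        assert 0 < forward < 60  # both strands actually drawn

    def test_same_seed_identical(self):
        genome = "ACGT" * 500
        assert simulate_reads(genome, 20, 50, seed=7) == simulate_reads(
            genome, 20, 50, seed=7
        )

    def test_header_carries_truth_labels(self):
        reads = simulate_reads("ACGT" * 100, 3, 20, seed=1, genome_id="G9", species_taxid=9)
        for header, _ in reads:
            assert parse_read_header(header) == ("G9", 9)

    def test_read_longer_than_genome_rejected(self):
        with pytest.raises(ValueError):
            simulate_reads("ACGT", 5, 10, seed=0)


def test_closer_species_divergence_degrades_recovery(tmp_path):
    """Shrinking inter-species divergence toward the strain level makes
    species progressively harder to separate (classes get confused)."""
    from nbtax.classify import classify_batchwise
    from nbtax.evaluate import (
        GenomeRecord,
        accuracy_at_levels,
        known_species,
        simulate_test_reads,
        train_store,
    )
    from nbtax.kmers import KmerSpec

    accuracies = []
    for d_species in (0.10, 0.03, 0.01):
        dataset = simulate_dataset(
            SimConfig(
                n_phyla=1,
                genera_per_phylum=2,
                species_per_genus=2,
                strains_per_species=2,
                genome_length=10_000,
                species_divergence=d_species,
                strain_divergence=0.01,
                seed=31,
            )
        )
        records = [GenomeRecord.from_sim(g) for g in dataset.genomes]
        train = [r for r in records if r.genome_id.endswith("_1")]
        test = [r for r in records if r.genome_id.endswith("_2")]
        store = train_store(tmp_path / f"d{d_species}", train, KmerSpec(8))
        reads, truth = simulate_test_reads(test, 50, 150, seed=32)
        preds = classify_batchwise(store, reads)
        report = accuracy_at_levels(preds, truth, dataset.tree, known_species(train))
        accuracies.append(report.per_rank["species"].accuracy_all)
    assert accuracies[0] >= accuracies[1] >= accuracies[2]
    assert accuracies[2] < accuracies[0]


def test_dataset_bundle_is_parseable_end_to_end(tmp_path):
    dataset = simulate_dataset(small_config(), tmp_path)
    tree = load_taxdump(
        dataset.taxdump_dir / "nodes.dmp", dataset.taxdump_dir / "names.dmp"
    )
    for genome in dataset.genomes:
        assert genome.fasta_path.exists()
        assert tree.rank(genome.species_taxid) == "species"
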