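import pytest

from nbtax.evaluate import GenomeRecord
from nbtax.simdata import SimConfig, simulate_dataset
from nbtax.taxonomy import load_taxdump

# Hand-built miniature taxonomy in NCBI dump dialect:
#   root(1) -> phylum(2) -> class(3) -> order(4) -> family(5) -> genus(6)
#   genus(6) -> species 7, 8; strain 9 under species 7; merged id 999 -> 7.
NODES_DMP = "".join(
    f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n"
    for taxid, parent, rank in [
        (1, 1, "no rank"),
        (2, 1, "phylum"),
        (3, 2, "class"),
        (4, 3, "order"),
        (5, 4, "family"),
        (6, 5, "genus"),
        (7, 6, "species"),
        (8, 6, "species"),
        (9, 7, "no rank"),
    ]
)
NAMES_DMP = "".join(
    f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|\n"
    for taxid, name in [
        (1, "root"),
        (2, "P1"),
        (3, "C1"),
        (4, "O1"),
        (5, "F1"),
        (6, "G1"),
        (7, "S1"),
        (8, "S2"),
        (9, "S1 strain x"),
    ]
)
MERGED_DMP = "999\t|\t7\t|\n"


@pytest.fixture(scope="session")
def toy_taxdump(tmp_path_factory):
    d = tmp_path_factory.mktemp("taxdump")
    (d / "nodes.dmp").write_text(NODES_DMP)
    (d / "names.dmp").write_text(NAMES_DMP)
    (d / "merged.dmp").write_text(MERGED_DMP)
    return d


@pytest.fixture(scope="session")
def toy_tree(toy_taxdump):
    return load_taxdump(
        toy_taxdump / "nodes.dmp",
        toy_taxdump / "names.dmp",
        toy_taxdump / "merged.dmp",
    )


@pytest.fixture(scope="session")
def sim_default():
    """Default synthetic corpus: 24 strain genomes of 12 species."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def sim_records(sim_default):
    return [GenomeRecord.from_sim(g) for g in sim_default.genomes]


@pytest.fixture(scope="session")
def sim_small():
    """Smaller corpus for experiments that retrain many times."""
    return simulate_dataset(
        SimConfig(
            n_phyla=1,
            genera_per_phylum=2,
            species_per_genus=2,
            strains_per_species=2,
            genome_length=8_000,
            seed=3,
        )
    )
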