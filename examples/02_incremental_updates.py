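"""Incremental training is exactly batch training.

Splits a genome set into three arbitrary update waves, applies them one at
a time, and shows the resulting store is byte-identical to training on
everything at once — the property that makes yearly database updates cheap.
"""

import tempfile
from pathlib import Path

from nbtax import KmerSpec, ModelStore
from nbtax.evaluate import GenomeRecord, _store_digest, train_store
from nbtax.simdata import SimConfig, simulate_dataset

spec = KmerSpec(k=8)
dataset = simulate_dataset(SimConfig(seed=1))
records = [GenomeRecord.from_sim(g) for g in dataset.genomes]

with tempfile.TemporaryDirectory() as tmp:
    batch = train_store(Path(tmp) / "batch", records, spec)

    incremental = ModelStore.create(Path(tmp) / "incremental", spec)
    waves = [records[:5], records[5:16], records[16:]]
    for i, wave in enumerate(waves, 1):
        by_species = {}
        for genome in wave:
            by_species.setdefault(genome.species_taxid, []).append(
                genome.kmer_table(spec)
            )
        for taxid in sorted(by_species):
            incremental.update_class(taxid, by_species[taxid])
        print(f"wave {i}: absorbed {len(wave)} genomes, store now {len(incremental)} classes")

    print("batch store digest:      ", _store_digest(batch)[:16], "...")
    print("incremental store digest:", _store_digest(incremental)[:16], "...")
    print("byte-identical:", _store_digest(batch) == _store_digest(incremental))

# Because savefiles hold raw integer counts and updates are integer
# addition, the equality is exact — not approximate — for any partition
# and order of updates. "True" above is the whole point.
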