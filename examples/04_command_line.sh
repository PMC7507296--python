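#!/usr/bin/env bash
# Shell round trip: simulate a corpus, train a store, classify reads,
# and profile the predictions at genus level.
set -euo pipefail
work=$(mktemp -d)
trap 'rm -rf "$work"' EXIT

nbtax simulate --out "$work/data" --seed 4 --genome-length 8000 --reads-per-genome 25

nbtax train --store "$work/store" -k 8 \
  --metadata "$work/data/genomes/metadata.tsv" \
  --genomes-dir "$work/data/genomes"

cat "$work"/data/reads/*.reads.fasta > "$work/all_reads.fasta"
nbtax classify --store "$work/store" --reads "$work/all_reads.fasta" \
  --out "$work/predictions.tsv" -t 2 -m 64K

nbtax profile --predictions "$work/predictions.tsv" \
  --taxdump "$work/data/taxdump" --rank genus --out "$work/genus_profile.tsv"

echo "--- first predictions (read_id, species taxid, log-likelihood) ---"
head -n 4 "$work/predictions.tsv"
echo "--- genus profile (abundances sum to 1) ---"
cat "$work/genus_profile.tsv"
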