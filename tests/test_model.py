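"""Model store: smoothing arithmetic, incremental-equals-batch exactness,
savefile determinism and integrity checking."""

import itertools
import math
import random

import pytest

from nbtax.kmers import KmerCountTable, KmerSpec, SpecMismatchError, count_kmers
from nbtax.model import (
    ClassModel,
    ModelError,
    ModelIntegrityError,
    ModelStore,
    log_smoothed_prob,
)


def make_table(spec, counts):
    return KmerCountTable(spec, dict(counts))


class TestLogSmoothedProb:
    def test_empty_class_is_uniform(self):
        model = ClassModel(1, KmerCountTable(KmerSpec(1)))
        for base in "ACGT":
            assert log_smoothed_prob(model, base) == pytest.approx(math.log(1 / 4))

    def test_hand_arithmetic(self):
        # class {A:3}: P(A) = (3+1)/(3+4), P(C) = (0+1)/(3+4)
        model = ClassModel(1, make_table(KmerSpec(1), {"A": 3}))
        assert log_smoothed_prob(model, "A") == pytest.approx(math.log(4 / 7))
        assert log_smoothed_prob(model, "C") == pytest.approx(math.log(1 / 7))

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_distribution_normalizes(self, k):
        rng = random.Random(k)
        spec = KmerSpec(k)
        all_kmers = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
        counts = {
            kmer: rng.randint(1, 20)
            for kmer in rng.sample(all_kmers, len(all_kmers) // 3 + 1)
        }
        model = ClassModel(1, make_table(spec, counts))
        total = sum(math.exp(log_smoothed_prob(model, kmer)) for kmer in all_kmers)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_never_minus_infinity(self):
        model = ClassModel(1, make_table(KmerSpec(2), {"AA": 1000000}))
        assert math.isfinite(log_smoothed_prob(model, "GG"))

    def test_wrong_length_kmer_rejected(self):
        model = ClassModel(1, KmerCountTable(KmerSpec(3)))
        with pytest.raises(ModelError):
            log_smoothed_prob(model, "AA")

    def test_monotone_in_counts(self):
        spec = KmerSpec(1)
        before = ClassModel(1, make_table(spec, {"A": 2, "C": 1}))
        after = ClassModel(1, make_table(spec, {"A": 5, "C": 1}))
        assert log_smoothed_prob(after, "A") > log_smoothed_prob(before, "A")
        assert log_smoothed_prob(after, "C") < log_smoothed_prob(before, "C")


class TestUpdateClass:
    def test_creates_absent_class(self, tmp_path):
        store = ModelStore.create(tmp_path / "s", KmerSpec(1))
        model = store.update_class(7, [make_table(store.spec, {"A": 2})])
        assert model.total == 2
        assert model.n_genomes == 1
        assert 7 in store

    def test_update_merges_counts(self, tmp_path):
        store = ModelStore.create(tmp_path / "s", KmerSpec(1))
        store.update_class(7, [make_table(store.spec, {"A": 2})])
        model = store.update_class(7, [make_table(store.spec, {"A": 1, "C": 1})])
        assert model.counts.counts == {"A": 3, "C": 1}
        assert model.total == 4
        assert model.n_genomes == 2

    def test_sequential_updates_equal_joint_update(self, tmp_path):
        spec = KmerSpec(2)
        d1 = [make_table(spec, {"AA": 2}), make_table(spec, {"AC": 1})]
        d2 = [make_table(spec, {"AA": 1, "GT": 3})]
        seq_store = ModelStore.create(tmp_path / "seq", spec)
        seq_store.update_class(7, d1)
        seq_store.update_class(7, d2)
        joint_store = ModelStore.create(tmp_path / "joint", spec)
        joint_store.update_class(7, d1 + d2)
        assert (
            seq_store.class_path(7).read_bytes() == joint_store.class_path(7).read_bytes()
        )

    def test_other_classes_untouched(self, tmp_path):
        store = ModelStore.create(tmp_path / "s", KmerSpec(1))
        store.update_class(7, [make_table(store.spec, {"A": 2})])
        before = store.class_path(7).read_bytes()
        store.update_class(8, [make_table(store.spec, {"C": 5})])
        assert store.class_path(7).read_bytes() == before

    def test_spec_mismatch_rejected(self, tmp_path):
        store = ModelStore.create(tmp_path / "s", KmerSpec(1))
        with pytest.raises(SpecMismatchError):
            store.update_class(7, [make_table(KmerSpec(2), {"AA": 1})])


class TestIncrementalEqualsBatch:
    """Any partition and order of updates yields byte-identical savefiles."""

    def test_random_partitions(self, tmp_path):
        rng = random.Random(17)
        spec = KmerSpec(3)
        genomes = [
            count_kmers("".join(rng.choice("ACGT") for _ in range(120)), spec)
            for _ in range(6)
        ]
        batch_store = ModelStore.create(tmp_path / "batch", spec)
        batch_store.update_class(7, genomes)
        reference = batch_store.class_path(7).read_bytes()
        for trial in range(5):
            order = rng.sample(range(6), 6)
            store = ModelStore.create(tmp_path / f"inc{trial}", spec)
            i = 0
            while i < len(order):
                step = rng.randint(1, len(order) - i)
                store.update_class(7, [genomes[j] for j in order[i : i + step]])
                i += step
            assert store.class_path(7).read_bytes() == reference


class TestMergeClasses:
    def test_keywise_sum(self, tmp_path):
        store = ModelStore.create(tmp_path / "s", KmerSpec(1))
        store.update_class(7, [make_table(store.spec, {"A": 1})])
        store.update_class(8, [make_table(store.spec, {"A": 2, "C": 1})])
        merged = store.merge_classes(7, 8)
        assert merged.counts.counts == {"A": 3, "C": 1}
        assert 7 not in store
        assert store.index == [8]

    def test_equals_scratch_training(self, tmp_path):
        spec = KmerSpec(2)
        g1 = make_table(spec, {"AA": 4, "CC": 1})
        g2 = make_table(spec, {"AA": 1, "GT": 2})
        merged_store = ModelStore.create(tmp_path / "m", spec)
        merged_store.update_class(7, [g1])
        merged_store.update_class(8, [g2])
        merged_store.merge_classes(7, 8)
        scratch_store = ModelStore.create(tmp_path / "b", spec)
        scratch_store.update_class(8, [g1, g2])
        assert (
            merged_store.class_path(8).read_bytes()
            == scratch_store.class_path(8).read_bytes()
        )

    def test_self_merge_is_noop_with_warning(self, tmp_path):
        store = ModelStore.create(tmp_path / "s", KmerSpec(1))
        store.update_class(7, [make_table(store.spec, {"A": 1})])
        before = store.class_path(7).read_bytes()
        with pytest.warns(UserWarning):
            store.merge_classes(7, 7)
        assert store.class_path(7).read_bytes() == before

    def test_missing_class_is_error(self, tmp_path):
        store = ModelStore.create(tmp_path / "s", KmerSpec(1))
        store.update_class(7, [make_table(store.spec, {"A": 1})])
        with pytest.raises(ModelError):
            store.merge_classes(99, 7)


class TestSavefileRoundTrip:
    def test_round_trip_identity(self, tmp_path):
        rng = random.Random(3)
        spec = KmerSpec(3)
        table = count_kmers("".join(rng.choice("ACGT") for _ in range(200)), spec)
        store = ModelStore.create(tmp_path / "s", spec)
        saved = store.update_class(7, [table])
        loaded = store.load_class(7)
        assert loaded.counts == saved.counts
        assert loaded.n_genomes == saved.n_genomes
        assert loaded.species_taxid == 7

    def test_saves_are_byte_deterministic(self, tmp_path):
        spec = KmerSpec(2)
        model = ClassModel(7, make_table(spec, {"GT": 1, "AA": 2}))
        a = ModelStore.create(tmp_path / "a", spec)
        b = ModelStore.create(tmp_path / "b", spec)
        a.save_class(model)
        b.save_class(model)
        assert a.class_path(7).read_bytes() == b.class_path(7).read_bytes()

    def test_corrupted_total_is_integrity_error(self, tmp_path):
        spec = KmerSpec(1)
        store = ModelStore.create(tmp_path / "s", spec)
        store.update_class(7, [make_table(spec, {"A": 2, "C": 1})])
        path = store.class_path(7)
        path.write_text(path.read_text().replace("# total: 3", "# total: 9"))
        with pytest.raises(ModelIntegrityError):
            store.load_class(7)

    def test_truncated_file_is_integrity_error(self, tmp_path):
        spec = KmerSpec(1)
        store = ModelStore.create(tmp_path / "s", spec)
        store.update_class(7, [make_table(spec, {"A": 2, "C": 1})])
        path = store.class_path(7)
        text = path.read_text()
        path.write_text(text[: text.rindex("C\t")])  # drop the last count line
        with pytest.raises(ModelIntegrityError):
            store.load_class(7)

    def test_open_checks_manifest_vs_directory(self, tmp_path):
        spec = KmerSpec(1)
        store = ModelStore.create(tmp_path / "s", spec)
        store.update_class(7, [make_table(spec, {"A": 1})])
        store.class_path(7).unlink()  # directory now disagrees with manifest
        with pytest.raises(ModelIntegrityError):
            ModelStore.open(tmp_path / "s")
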