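"""Beat extraction windows, class mapping, imbalance stats and splits."""

import numpy as np
import pytest

from ecggen.io import BeatDataset, ECGRecord
from ecggen.segmentation import (
    MITBIH_CLASSES, ClassMap, class_distribution, downsample, extract_beats,
    kfold_indices, stratified_split,
)
from ecggen.simulate import BeatTemplateParams, beat_template, synth_record


def _ds(labels, length=12, class_names=("a", "b", "c")):
    labels = np.asarray(labels)
    return BeatDataset(np.zeros((labels.size, length)), labels,
                       list(class_names), 360.0)


class TestExtractBeats:
    def test_window_at_record_start_is_kept(self, cmap):
        rec = ECGRecord("t", 360.0, np.arange(1000.0), [(100, "N")])
        ds = extract_beats(rec, cmap, normalize=False)
        assert ds.n == 1 and ds.beat_length == 300
        np.testing.assert_array_equal(ds.beats[0], np.arange(300.0))

    def test_window_crossing_start_is_dropped(self, cmap):
        rec = ECGRecord("t", 360.0, np.zeros(1000), [(50, "N")])
        assert extract_beats(rec, cmap).n == 0

    def test_window_crossing_end_is_dropped(self, cmap):
        rec = ECGRecord("t", 360.0, np.zeros(1000), [(900, "N")])
        assert extract_beats(rec, cmap).n == 0

    def test_unmapped_symbols_skipped(self, cmap):
        rec = ECGRecord("t", 360.0, np.zeros(2000),
                        [(400, "A"), (800, "f"), (1200, "V")])
        ds = extract_beats(rec, cmap)
        assert list(ds.labels) == [cmap.index("A"), cmap.index("V")]

    def test_peak_lands_at_pre_offset(self, noiseless_params):
        rec = synth_record(["A", "V"], noiseless_params, seed=0)
        ds = extract_beats(rec, MITBIH_CLASSES, normalize=False)
        assert ds.n == 2
        for beat, label in zip(ds.beats, ds.labels):
            sym = MITBIH_CLASSES.symbols[label]
            tpl = beat_template(sym, noiseless_params)
            assert abs(int(np.argmax(beat)) - int(np.argmax(tpl))) <= 1

    def test_beat_count_bounded_by_annotations(self, fixture_record, cmap):
        ds = extract_beats(fixture_record, cmap)
        assert ds.n <= len(fixture_record.annotations)
        assert ds.beats.shape[1] == 300

    def test_invalid_window(self, cmap):
        rec = ECGRecord("t", 360.0, np.zeros(100), [])
        with pytest.raises(ValueError):
            extract_beats(rec, cmap, pre=0)


class TestDownsample:
    def test_identity_interval(self):
        ds = _ds([0, 1], length=30)
        out = downsample(ds, 1)
        np.testing.assert_array_equal(out.beats, ds.beats)

    def test_length_300_interval_3_gives_100(self):
        ds = BeatDataset(np.zeros((4, 300)), [0] * 4, ["a"], 360.0)
        assert downsample(ds, 3).beat_length == 100

    def test_strided_pick(self):
        ds = BeatDataset(np.arange(10.0)[None, :], [0], ["a"], 360.0)
        np.testing.assert_array_equal(downsample(ds, 4).beats[0], [0.0, 4.0, 8.0])

    def test_composition(self):
        rng = np.random.default_rng(0)
        ds = BeatDataset(rng.normal(size=(3, 60)), [0, 0, 0], ["a"], 360.0)
        a = downsample(downsample(ds, 2), 3)
        b = downsample(ds, 6)
        np.testing.assert_array_equal(a.beats, b.beats)

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            downsample(_ds([0]), 0)


class TestClassDistribution:
    def test_published_count_table(self):
        counts = {"N": 71732, "A": 1950, "V": 6974, "L": 6578, "R": 4967}
        labels = np.concatenate([
            np.full(n, i) for i, n in enumerate(counts.values())
        ])
        ds = BeatDataset(np.zeros((labels.size, 4)), labels,
                         list(counts.keys()), 360.0)
        rep = class_distribution(ds)
        assert rep.counts == counts
        assert rep.fractions["A"] == pytest.approx(1950 / 92201)
        assert rep.fractions["A"] * 100 == pytest.approx(2.115, abs=5e-4)
        assert rep.minority_fraction == pytest.approx(1950 / 92201)

    def test_single_class(self):
        rep = class_distribution(_ds([0, 0, 0], class_names=("a",)))
        assert rep.imbalance_ratio == 1.0

    def test_three_to_one(self):
        rep = class_distribution(_ds([0, 0, 0, 1], class_names=("a", "b")))
        assert rep.fractions == {"a": 0.75, "b": 0.25}
        assert rep.imbalance_ratio == 3.0

    def test_fractions_sum_to_one(self, balanced_dataset):
        rep = class_distribution(balanced_dataset)
        assert sum(rep.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_dataset(self):
        with pytest.raises(ValueError):
            class_distribution(_ds([], class_names=("a",)))


class TestSplits:
    def test_proportions_preserved(self):
        ds = _ds([0] * 80 + [1] * 20)
        train, test = stratified_split(ds, 0.8, seed=3)
        assert train.n == 80 and test.n == 20
        assert (train.labels == 0).sum() == 64 and (train.labels == 1).sum() == 16

    def test_same_seed_identical(self, balanced_dataset):
        a = stratified_split(balanced_dataset, 0.8, seed=5)
        b = stratified_split(balanced_dataset, 0.8, seed=5)
        np.testing.assert_array_equal(a[0].beats, b[0].beats)
        np.testing.assert_array_equal(a[1].labels, b[1].labels)

    def test_seed_changes_membership_not_counts(self):
        rng = np.random.default_rng(0)
        ds = BeatDataset(rng.normal(size=(100, 8)),
                         [0] * 70 + [1] * 30, ["a", "b"], 360.0)
        a, _ = stratified_split(ds, 0.8, seed=1)
        b, _ = stratified_split(ds, 0.8, seed=2)
        assert np.bincount(a.labels).tolist() == np.bincount(b.labels).tolist()
        assert not np.array_equal(a.beats, b.beats)

    def test_union_is_disjoint_partition(self):
        rng = np.random.default_rng(4)
        ds = BeatDataset(rng.normal(size=(50, 6)),
                         rng.integers(0, 3, 50), ["a", "b", "c"], 360.0)
        train, test = stratified_split(ds, 0.8, seed=9)
        assert train.n + test.n == ds.n
        merged = np.vstack([train.beats, test.beats])
        assert np.unique(merged, axis=0).shape[0] == np.unique(ds.beats, axis=0).shape[0]

    def test_singleton_class_warns(self):
        ds = _ds([0, 0, 0, 1], class_names=("a", "b"))
        with pytest.warns(UserWarning, match="single member"):
            stratified_split(ds, 0.8, seed=0)


class TestKFold:
    def test_equal_folds(self):
        folds = kfold_indices(10, 5, seed=0)
        assert [len(f) for f in folds] == [2] * 5

    def test_uneven_folds(self):
        sizes = sorted(len(f) for f in kfold_indices(10, 3, seed=0))
        assert sizes == [3, 3, 4]

    def test_partition_property(self):
        folds = kfold_indices(37, 5, seed=2)
        allidx = np.concatenate(folds)
        assert sorted(allidx.tolist()) == list(range(37))

    def test_k_larger_than_n(self):
        with pytest.raises(ValueError):
            kfold_indices(3, 5)


def test_classmap_rejects_duplicates():
    with pytest.raises(ValueError):
        ClassMap(symbols=("N", "N"), class_names=("a", "b"))
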