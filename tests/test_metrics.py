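"""Sequence-fidelity and classification metrics against hand computations
and a brute-force Fréchet oracle."""

import numpy as np
import pytest

from ecggen.io import BeatDataset
from ecggen.metrics import (
    augmentation_ratio, classification_report, f1_from_precision_recall,
    frechet_distance, generation_report, mae, prd, rmse,
)


def brute_force_frechet(a, b):
    """Minimum over all monotone couplings of the max pointwise distance,
    by explicit recursion over coupling moves (independent of the DP)."""
    a = list(a)
    b = list(b)

    def rec(i, j):
        d = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return d
        best = min(
            rec(pi, pj)
            for pi, pj in [(i - 1, j), (i, j - 1), (i - 1, j - 1)]
            if pi >= 0 and pj >= 0
        )
        return max(d, best)

    return rec(len(a) - 1, len(b) - 1)


class TestPRD:
    def test_identical_is_zero(self):
        assert prd([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_zero_candidate_is_hundred(self):
        assert prd([3.0, 4.0], [0.0, 0.0]) == pytest.approx(100.0)

    def test_hand_computed(self):
        assert prd([3.0, 4.0], [0.0, 4.0]) == pytest.approx(60.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            prd([0.0, 0.0], [1.0, 1.0])

    @pytest.mark.parametrize("scale", [0.1, 7.0])
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert prd(a, b) == pytest.approx(prd(scale * a, scale * b))


class TestFrechet:
    def test_identity(self):
        assert frechet_distance([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_constant_offset(self):
        assert frechet_distance([0.0, 0.0], [1.0, 1.0]) == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=7), rng.normal(size=9)
        assert frechet_distance(a, b) == pytest.approx(frechet_distance(b, a))

    def test_bounded_by_max_elementwise_difference(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=15), rng.normal(size=15)
        assert frechet_distance(a, b) <= np.abs(a - b).max() + 1e-12

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n, m = rng.integers(1, 7, size=2)
            a, b = rng.normal(size=n), rng.normal(size=m)
            assert frechet_distance(a, b) == pytest.approx(
                brute_force_frechet(a, b), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            frechet_distance([], [1.0])


class TestRMSEMAE:
    def test_identical(self):
        assert rmse([1.0], [1.0]) == 0.0 and mae([1.0], [1.0]) == 0.0

    def test_hand_computed(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))
        assert mae([0.0, 0.0], [3.0, 4.0]) == pytest.approx(3.5)

    def test_mae_never_exceeds_rmse(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a, b = rng.normal(size=30), rng.normal(size=30)
            assert mae(a, b) <= rmse(a, b) + 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestGenerationReport:
    def _real(self):
        rng = np.random.default_rng(5)
        beats = np.vstack([rng.normal(1.0, 0.1, size=(10, 20)),
                           rng.normal(-1.0, 0.1, size=(10, 20))])
        return BeatDataset(beats, [0] * 10 + [1] * 10, ["a", "b"], 360.0)

    def test_class_means_score_zero_rmse(self):
        real = self._real()
        means = np.stack([real.beats[real.labels == c].mean(axis=0)
                          for c in (0, 1)])
        synth = BeatDataset(means, [0, 1], ["a", "b"], 360.0, "synthetic")
        rep = generation_report(real, synth, pairing="mean")
        assert rep.rmse == pytest.approx(0.0, abs=1e-12)
        assert rep.fd == pytest.approx(0.0, abs=1e-12)

    def test_copy_of_real_gives_within_class_deviation(self):
        real = self._real()
        rep = generation_report(real, real, pairing="mean")
        dev = np.mean([
            np.sqrt(np.mean((b - real.beats[real.labels == c].mean(axis=0)) ** 2))
            for b, c in zip(real.beats, real.labels)
        ])
        assert rep.rmse == pytest.approx(dev)
        assert all(v >= 0 for v in (rep.prd, rep.fd, rep.rmse, rep.mae))

    def test_nearest_pairing_not_worse_than_mean(self):
        real = self._real()
        near = generation_report(real, real, pairing="nearest")
        assert near.rmse == pytest.approx(0.0, abs=1e-12)  # each beat is its own nearest

    def test_missing_class_rejected(self):
        real = self._real()
        synth = BeatDataset(np.zeros((1, 20)), [1], ["a", "b"], 360.0)
        only_a = real.subset(np.flatnonzero(real.labels == 0))
        with pytest.raises(ValueError, match="absent"):
            generation_report(only_a, synth)


# printed (precision, recall, F1) rows of the baseline five-class study
PUBLISHED_ROWS = [
    (99.3120, 99.4103, 99.3611),
    (85.9823, 84.6154, 85.2934),
    (94.1332, 96.8598, 95.4770),
    (95.9455, 95.3329, 95.6382),
    (96.7275, 92.8327, 94.7401),
]


class TestClassificationReport:
    @pytest.mark.parametrize("p,r,f1", PUBLISHED_ROWS)
    def test_f1_is_harmonic_mean_of_published_pairs(self, p, r, f1):
        assert f1_from_precision_recall(p, r) == pytest.approx(f1, abs=5e-5)

    def test_macro_f1_of_published_table(self):
        f1s = [f1_from_precision_recall(p, r) for p, r, _ in PUBLISHED_ROWS]
        assert np.mean(f1s) == pytest.approx(94.1020, abs=5e-4)

    def test_perfect_predictions(self):
        rep = classification_report([0, 1, 2, 0], [0, 1, 2, 0], 3)
        assert rep.macro_f1 == 100.0
        assert np.all(rep.precision == 100.0)

    def test_hand_computed_case(self):
        rep = classification_report([0, 0, 1, 1], [0, 1, 1, 1], 2)
        assert rep.precision[0] == pytest.approx(100.0)
        assert rep.recall[0] == pytest.approx(50.0)
        assert rep.f1[0] == pytest.approx(200 / 3, abs=1e-9)

    def test_confusion_rows_match_true_counts(self):
        rng = np.random.default_rng(6)
        truth = rng.integers(0, 4, 100)
        pred = rng.integers(0, 4, 100)
        rep = classification_report(truth, pred, 4)
        np.testing.assert_array_equal(rep.confusion.sum(axis=1),
                                      np.bincount(truth, minlength=4))
        np.testing.assert_array_equal(rep.confusion.sum(axis=0),
                                      np.bincount(pred, minlength=4))

    def test_unpredicted_class_gets_zero_precision(self):
        rep = classification_report([0, 1], [0, 0], 2)
        assert rep.precision[1] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classification_report([], [], 2)


class TestAugmentationRatio:
    # published before/after counts and the ratios printed for them
    # (printed values are truncated, not rounded, to 2 decimals)
    @pytest.mark.parametrize("before,after,printed", [
        (1950, 68024, 3488.41),
        (6974, 70726, 1014.13),
        (6578, 70180, 1066.88),
        (4967, 70354, 1416.42),
    ])
    def test_published_expansion_table(self, before, after, printed):
        ratio = augmentation_ratio(before, after)
        assert np.floor(ratio * 100) / 100 == pytest.approx(printed, abs=1e-9)

    def test_no_expansion_is_hundred(self):
        assert augmentation_ratio(10, 10) == 100.0

    def test_zero_before_rejected(self):
        with pytest.raises(ValueError):
            augmentation_ratio(0, 5)
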