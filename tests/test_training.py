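"""Training-loop behavior: loss descent, update ratios, determinism,
checkpoint-resume equality and conditional generation."""

import numpy as np
import pytest

from ecggen.networks import GANModel
from ecggen.training import (
    Trainer, fit, generate_scarce, kfold_evaluate, load_checkpoint, resume,
    train_autoencoder,
)


class TestAutoencoderPhase:
    def test_reconstruction_loss_falls(self, small_dataset, tiny_cfg):
        _, state = train_autoencoder(small_dataset, tiny_cfg, epochs=6, seed=0)
        hist = state.history["reconstruction"]
        assert len(hist) == 6
        assert hist[-1] < hist[0]

    def test_zero_epochs_is_identity(self, small_dataset, tiny_cfg):
        model, state = train_autoencoder(small_dataset, tiny_cfg, epochs=0, seed=0)
        fresh = GANModel(tiny_cfg, seed=0)
        for a, b in zip(model.encoder.state_arrays(), fresh.encoder.state_arrays()):
            np.testing.assert_array_equal(a, b)
        assert state.history["reconstruction"] == []

    def test_same_seed_same_history(self, small_dataset, tiny_cfg):
        _, s1 = train_autoencoder(small_dataset, tiny_cfg, epochs=3, seed=5)
        _, s2 = train_autoencoder(small_dataset, tiny_cfg, epochs=3, seed=5)
        assert s1.history["reconstruction"] == s2.history["reconstruction"]

    def test_empty_dataset_rejected(self, tiny_cfg):
        from ecggen.io import BeatDataset
        empty = BeatDataset(np.empty((0, 50)), np.empty(0, dtype=int),
                            ["a"], 360.0)
        with pytest.raises(ValueError, match="empty"):
            Trainer(GANModel(tiny_cfg, seed=0), empty)

    def test_wrong_beat_length_rejected(self, balanced_dataset, tiny_cfg):
        with pytest.raises(ValueError, match="seq_len"):
            Trainer(GANModel(tiny_cfg, seed=0), balanced_dataset)


class TestSupervisedPhase:
    def test_moment_distance_decreases(self, small_dataset, tiny_cfg):
        model = GANModel(tiny_cfg, seed=1)
        tr = Trainer(model, small_dataset, seed=1)
        for _ in range(3):
            tr.epoch_autoencoder()
        first = tr.epoch_supervised()
        for _ in range(4):
            last = tr.epoch_supervised()
        assert last < first

    def test_single_class_dataset_trains(self, tiny_cfg):
        from ecggen.segmentation import downsample
        from ecggen.simulate import make_imbalanced_dataset
        ds = downsample(make_imbalanced_dataset({"V": 40}, seed=3), 6)
        model = GANModel(tiny_cfg, seed=0)
        tr = Trainer(model, ds, seed=0)
        loss = tr.epoch_supervised()
        assert np.isfinite(loss)


class TestAdversarialPhase:
    def test_two_generator_updates_per_discriminator_update(
            self, small_dataset, tiny_cfg):
        model = GANModel(tiny_cfg, seed=2)
        tr = Trainer(model, small_dataset, seed=2)
        tr.epoch_adversarial()
        assert tr.state.g_updates == 2 * tr.state.d_updates
        assert tr.state.d_updates > 0

    def test_losses_finite(self, small_dataset, tiny_cfg):
        model = GANModel(tiny_cfg, seed=2)
        tr = Trainer(model, small_dataset, seed=2)
        for _ in range(2):
            d, g, r = tr.epoch_adversarial()
            assert np.isfinite(d) and np.isfinite(g) and np.isfinite(r)

    def test_discriminator_learns_against_frozen_generator(
            self, small_dataset, tiny_cfg):
        """With G frozen at initialization, D's accuracy on real-vs-fake
        should exceed one half after a few epochs."""
        model = GANModel(tiny_cfg, seed=4)
        tr = Trainer(model, small_dataset, seed=4)
        saved = [a.copy() for a in model.generator.state_arrays()]
        for _ in range(3):
            tr.epoch_adversarial()
            model.generator.load_state_arrays(saved)  # keep G frozen
        x = small_dataset.beats.astype(np.float32)
        y = small_dataset.labels
        z = np.random.default_rng(0).standard_normal(
            (x.shape[0], tiny_cfg.seq_len, tiny_cfg.noise_width)).astype(np.float32)
        fake = model.decode(model.generate(z, y))
        sel_real = np.take_along_axis(model.discriminate(x, y),
                                      y[:, None], axis=1)
        sel_fake = np.take_along_axis(model.discriminate(fake, y),
                                      y[:, None], axis=1)
        acc = 0.5 * ((sel_real > 0).mean() + (sel_fake <= 0).mean())
        assert acc > 0.5


class TestFit:
    def test_epoch_budget_and_history(self, small_dataset, tiny_cfg):
        _, state = fit(small_dataset, tiny_cfg, epochs=5, seed=0)
        assert state.epoch == 5
        assert len(state.plan) == 5

    def test_seed_reproducible_end_to_end(self, small_dataset, tiny_cfg):
        m1, s1 = fit(small_dataset, tiny_cfg, epochs=4, seed=9)
        m2, s2 = fit(small_dataset, tiny_cfg, epochs=4, seed=9)
        assert s1.history == s2.history
        for a, b in zip(m1.state_arrays(), m2.state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_checkpoint_round_trip(self, tmp_path, small_dataset, tiny_cfg):
        full, _ = fit(small_dataset, tiny_cfg, epochs=4, seed=3,
                      checkpoint_dir=tmp_path / "run")
        tr = load_checkpoint(tmp_path / "run" / "checkpoint.npz", small_dataset)
        for a, b in zip(tr.model.state_arrays(), full.state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_interrupted_run_resumes_bit_identically(
            self, tmp_path, small_dataset, tiny_cfg):
        full, s_full = fit(small_dataset, tiny_cfg, epochs=6, seed=3)

        # run the same plan but stop after 3 epochs, checkpointing
        from ecggen.training import _phase_plan, save_checkpoint
        model = GANModel(tiny_cfg, seed=3)
        tr = Trainer(model, small_dataset, seed=3)
        tr.state.plan = _phase_plan(6)
        tr.run_plan(tr.state.plan[:3],
                    checkpoint_path=tmp_path / "ck.npz")
        resumed_model, s_res = resume(tmp_path / "ck.npz", small_dataset)
        assert s_res.epoch == 6
        assert s_res.history == s_full.history
        for a, b in zip(resumed_model.state_arrays(), full.state_arrays()):
            np.testing.assert_array_equal(a, b)


@pytest.fixture(scope="module")
def trained(small_dataset, tiny_cfg):
    return fit(small_dataset, tiny_cfg, epochs=4, seed=7)[0]


class TestGenerateScarce:
    def test_exact_counts_and_labels(self, trained, small_dataset):
        names = list(small_dataset.class_names)
        out = generate_scarce(trained, {names[1]: 50}, names, seed=1)
        assert out.n == 50
        assert np.all(out.labels == 1)
        assert out.provenance == "synthetic"

    def test_multi_class_counts(self, trained, small_dataset):
        names = list(small_dataset.class_names)
        out = generate_scarce(trained, {names[0]: 7, names[3]: 11}, names, seed=1)
        assert (out.labels == 0).sum() == 7 and (out.labels == 3).sum() == 11

    def test_seed_reproducible(self, trained, small_dataset):
        names = list(small_dataset.class_names)
        a = generate_scarce(trained, {names[2]: 9}, names, seed=5)
        b = generate_scarce(trained, {names[2]: 9}, names, seed=5)
        np.testing.assert_array_equal(a.beats, b.beats)

    def test_unknown_class_rejected(self, trained, small_dataset):
        with pytest.raises(ValueError, match="unknown"):
            generate_scarce(trained, {"bogus": 3},
                            list(small_dataset.class_names), seed=0)


class TestKFold:
    def test_smoke_reports_finite(self, small_dataset, tiny_cfg):
        reports = kfold_evaluate(small_dataset, tiny_cfg, k=2, seed=0, epochs=2)
        assert len(reports) == 2
        for rep in reports:
            assert np.isfinite(rep.prd) and np.isfinite(rep.fd)
            assert np.isfinite(rep.rmse) and rep.rmse >= 0
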