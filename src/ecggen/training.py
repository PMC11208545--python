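"""Four-step training of the conditional beat-synthesis GAN.

Step 1 trains encoder+decoder as an autoencoder so the high-dimensional beat
space and the low-dimensional latent space are reversibly mapped.  Step 2
pre-trains the generator through the frozen decoder by class-conditional
mean regression: decoded generated beats are regressed onto the class-mean
beat of their conditioning class (the minimizer is the class-conditional
first moment, i.e. first-moment matching with dense per-sample gradients).
Step 3 trains generator and discriminator adversarially with non-saturating
binary cross-entropy, two generator updates per discriminator update; the
discriminator additionally sees real beats under mismatched labels as fakes
so it enforces label consistency, generation labels are drawn
class-balanced, the encoder/decoder stay frozen, and the Step-2 anchor
remains in the generator loss.  Step 4 (``generate_scarce``) draws
class-conditioned noise and decodes it into synthetic beats for the scarce
classes.

All randomness (batch order, noise draws, dropout) flows through one
``numpy.random.Generator`` whose state is checkpointed, so interrupted runs
resume bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io import BeatDataset
from .metrics import MetricsReport, generation_report
from .networks import GANConfig, GANModel
from .nn import Adam, Tensor, bce_with_logits, mse_loss, no_grad
from .segmentation import kfold_indices

__all__ = [
    "TrainState", "Trainer", "train_autoencoder", "train_supervised",
    "train_adversarial", "fit", "resume", "generate_scarce",
    "kfold_evaluate", "save_checkpoint", "load_checkpoint",
]


@dataclass
class TrainState:
    """Per-epoch loss histories and bookkeeping for one training run."""

    epoch: int = 0
    history: dict = field(default_factory=lambda: {
        "reconstruction": [], "supervised": [], "generator": [],
        "discriminator": [],
    })
    g_updates: int = 0
    d_updates: int = 0
    g_per_d: int = 2
    seed: int = 0
    plan: list = field(default_factory=list)


def _check_finite(value: float, what: str) -> float:
    if not np.isfinite(value):
        raise FloatingPointError(f"{what} loss diverged (non-finite value)")
    return value


class Trainer:
    """Holds the model, its three Adam optimizers and the run RNG."""

    def __init__(self, model: GANModel, data: BeatDataset, seed: int = 0,
                 g_per_d: int = 2):
        cfg = model.cfg
        if data.n == 0:
            raise ValueError("cannot train on an empty dataset")
        if data.beat_length != cfg.seq_len:
            raise ValueError(
                f"beat length {data.beat_length} != configured seq_len {cfg.seq_len}"
            )
        self.model = model
        self.cfg = cfg
        self.x = data.beats.astype(np.float32)[:, :, None]
        self.y = data.labels.astype(np.int64)
        # class-conditional mean beats: the supervised regression targets
        self.class_mean_beats = np.zeros(
            (cfg.n_classes, cfg.seq_len, 1), dtype=np.float32)
        for c in np.unique(self.y):
            self.class_mean_beats[c] = self.x[self.y == c].mean(axis=0)
        self.class_names = list(data.class_names)
        self.fs = data.fs
        self.rng = np.random.default_rng(seed)
        lr = cfg.learning_rate
        ae_params = model.encoder.parameters() + model.decoder.parameters()
        self.opt_ae = Adam(ae_params, lr=lr)
        self.opt_g = Adam(model.generator.parameters(), lr=lr)
        self.opt_d = Adam(model.discriminator.parameters(), lr=lr)
        self.state = TrainState(g_per_d=g_per_d, seed=seed)

    # ------------------------------------------------------------------
    def _batches(self):
        perm = self.rng.permutation(self.x.shape[0])
        bs = self.cfg.batch_size
        for lo in range(0, perm.size, bs):
            idx = perm[lo : lo + bs]
            yield self.x[idx], self.y[idx]

    def _noise(self, n: int) -> np.ndarray:
        return self.rng.standard_normal(
            (n, self.cfg.seq_len, self.cfg.noise_width)
        ).astype(np.float32)

    def _zero_all(self):
        self.opt_ae.zero_grad()
        self.opt_g.zero_grad()
        self.opt_d.zero_grad()

    # -- Step 1 ---------------------------------------------------------
    def epoch_autoencoder(self) -> float:
        m, losses = self.model, []
        for xb, _ in self._batches():
            xt = Tensor(xb)
            rec = m.decoder(m.encoder(xt, self.rng, train=True), self.rng, train=True)
            loss = mse_loss(rec, xt)
            self._zero_all()
            loss.backward()
            self.opt_ae.step()
            losses.append(float(loss.data))
        return _check_finite(float(np.mean(losses)), "reconstruction")

    def _balanced_labels(self, n: int) -> np.ndarray:
        """Uniform draw over the classes present in the data, so scarce
        classes receive as much conditioning gradient as common ones."""
        present = np.unique(self.y)
        return self.rng.choice(present, size=n)

    def _anchor_loss(self, decoded: Tensor, labels: np.ndarray) -> Tensor:
        """Squared distance of decoded generated beats to the class-mean
        beat of their conditioning class."""
        return ((decoded - Tensor(self.class_mean_beats[labels])) ** 2).mean()

    # -- Step 2 ---------------------------------------------------------
    def epoch_supervised(self) -> float:
        m, losses = self.model, []
        for xb, _ in self._batches():
            yg = self._balanced_labels(xb.shape[0])
            z = self._noise(xb.shape[0])
            lat = m.generator(z, yg, self.rng, train=True)
            loss = self._anchor_loss(m.decoder(lat), yg)
            self._zero_all()
            loss.backward()
            self.opt_g.step()
            losses.append(float(loss.data))
        return _check_finite(float(np.mean(losses)), "supervised")

    # -- Step 3 ---------------------------------------------------------
    def epoch_adversarial(self) -> tuple:
        m = self.model
        w = self.cfg.loss_weights
        d_losses, g_losses, rec_losses = [], [], []
        for xb, yb in self._batches():
            n = xb.shape[0]
            # discriminator update: real beats vs decoded fakes (G frozen);
            # fake conditioning labels are drawn class-balanced
            yg = self._balanced_labels(n)
            with no_grad():
                fake = m.decoder(m.generator(self._noise(n), yg)).data
            d_real = m.discriminator.select(
                m.discriminator(xb, yb, self.rng, train=True), yb)
            d_fake = m.discriminator.select(
                m.discriminator(fake, yg, self.rng, train=True), yg)
            # real beats paired with wrong labels count as fake, so the
            # discriminator enforces label consistency, not just realism
            y_wrong = (yb + self.rng.integers(1, self.cfg.n_classes, size=n)) \
                % self.cfg.n_classes
            d_wrong = m.discriminator.select(
                m.discriminator(xb, y_wrong, self.rng, train=True), y_wrong)
            loss_d = bce_with_logits(d_real, np.ones(n)) + \
                0.5 * bce_with_logits(d_fake, np.zeros(n)) + \
                0.5 * bce_with_logits(d_wrong, np.zeros(n))
            self._zero_all()
            loss_d.backward()
            self.opt_d.step()
            self.state.d_updates += 1
            d_losses.append(float(loss_d.data))
            # generator updates (2 per discriminator update); the encoder
            # and decoder are FROZEN in this phase so the generator and
            # discriminator play in a fixed latent/beat geometry — letting
            # the autoencoder drift here detrains the conditioning
            for _ in range(self.state.g_per_d):
                yg = self._balanced_labels(n)
                lat = m.generator(self._noise(n), yg, self.rng, train=True)
                fake_t = m.decoder(lat)
                scores = m.discriminator(fake_t, yg, self.rng, train=True)
                adv = bce_with_logits(m.discriminator.select(scores, yg),
                                      np.ones(n))
                sup = self._anchor_loss(fake_t, yg)
                loss_g = w["adversarial"] * adv + w["supervised"] * sup
                self._zero_all()
                loss_g.backward()
                self.opt_g.step()
                self.state.g_updates += 1
                g_losses.append(float(adv.data))
            with no_grad():
                rec = mse_loss(m.decoder(m.encoder(Tensor(xb))), Tensor(xb))
            rec_losses.append(float(rec.data))
        return (
            _check_finite(float(np.mean(d_losses)), "discriminator"),
            _check_finite(float(np.mean(g_losses)), "generator"),
            _check_finite(float(np.mean(rec_losses)), "reconstruction"),
        )

    # ------------------------------------------------------------------
    def run_plan(self, plan, checkpoint_path=None) -> TrainState:
        """Execute the remaining phase plan, checkpointing after each epoch."""
        h = self.state.history
        for phase in plan:
            if phase == "ae":
                h["reconstruction"].append(self.epoch_autoencoder())
            elif phase == "sup":
                h["supervised"].append(self.epoch_supervised())
            elif phase == "adv":
                d, g, r = self.epoch_adversarial()
                h["discriminator"].append(d)
                h["generator"].append(g)
                h["reconstruction"].append(r)
            else:
                raise ValueError(f"unknown training phase {phase!r}")
            self.state.epoch += 1
            if checkpoint_path is not None:
                save_checkpoint(checkpoint_path, self)
        return self.state


def _phase_plan(epochs: int, split=(0.35, 0.35, 0.3)) -> list:
    e1 = int(round(split[0] * epochs))
    e2 = int(round(split[1] * epochs))
    e3 = max(epochs - e1 - e2, 0)
    return ["ae"] * e1 + ["sup"] * e2 + ["adv"] * e3


# -- public entry points -------------------------------------------------

def train_autoencoder(data: BeatDataset, cfg: GANConfig, epochs: int,
                      seed: int = 0) -> tuple:
    """Step 1 alone; returns (model, TrainState)."""
    model = GANModel(cfg, seed=seed)
    tr = Trainer(model, data, seed=seed)
    tr.run_plan(["ae"] * epochs)
    return model, tr.state


def train_supervised(data: BeatDataset, cfg: GANConfig, epochs: int,
                     seed: int = 0, ae_epochs: int = 5) -> tuple:
    """Steps 1-2: autoencoding then generator conditional-mean regression."""
    model = GANModel(cfg, seed=seed)
    tr = Trainer(model, data, seed=seed)
    tr.run_plan(["ae"] * ae_epochs + ["sup"] * epochs)
    return model, tr.state


def train_adversarial(data: BeatDataset, cfg: GANConfig, epochs: int,
                      seed: int = 0, ae_epochs: int = 5,
                      sup_epochs: int = 5) -> tuple:
    """Steps 1-3 with an explicit adversarial epoch count."""
    model = GANModel(cfg, seed=seed)
    tr = Trainer(model, data, seed=seed)
    tr.run_plan(["ae"] * ae_epochs + ["sup"] * sup_epochs + ["adv"] * epochs)
    return model, tr.state


def fit(data: BeatDataset, cfg: GANConfig, epochs: int = 100, seed: int = 0,
        checkpoint_dir=None, split=(0.35, 0.35, 0.3)) -> tuple:
    """Run Steps 1-3 end to end; returns (model, TrainState).

    ``split`` apportions the epoch budget across the autoencoder, supervised
    and adversarial phases.
    """
    model = GANModel(cfg, seed=seed)
    tr = Trainer(model, data, seed=seed)
    tr.state.seed = seed
    tr.state.plan = _phase_plan(epochs, split)
    ckpt = None
    if checkpoint_dir is not None:
        Path(checkpoint_dir).mkdir(parents=True, exist_ok=True)
        ckpt = Path(checkpoint_dir) / "checkpoint.npz"
    tr.run_plan(tr.state.plan, checkpoint_path=ckpt)
    return model, tr.state


def resume(checkpoint_path, data: BeatDataset) -> tuple:
    """Continue an interrupted :func:`fit` run to the end of its plan."""
    tr = load_checkpoint(checkpoint_path, data)
    remaining = tr.state.plan[tr.state.epoch :]
    tr.run_plan(remaining, checkpoint_path=Path(checkpoint_path))
    return tr.model, tr.state


def generate_scarce(model: GANModel, target_counts: dict, class_names,
                    seed: int = 0, fs: float = 360.0) -> BeatDataset:
    """Step 4: class-conditioned synthesis of exactly the requested counts.

    ``target_counts`` maps class name (or index) to the number of beats to
    synthesize; the result carries provenance ``"synthetic"``.
    """
    cfg = model.cfg
    class_names = list(class_names)
    rng = np.random.default_rng(seed)
    beats, labels = [], []
    for key, n in target_counts.items():
        if isinstance(key, str) and key not in class_names:
            raise ValueError(f"unknown class {key!r}")
        c = class_names.index(key) if isinstance(key, str) else int(key)
        if not 0 <= c < cfg.n_classes:
            raise ValueError(f"unknown class {key!r}")
        if n == 0:
            continue
        done = 0
        while done < n:
            b = min(cfg.batch_size, n - done)
            z = rng.standard_normal((b, cfg.seq_len, cfg.noise_width)).astype(np.float32)
            lat = model.generate(z, np.full(b, c))
            beats.append(model.decode(lat))
            labels.extend([c] * b)
            done += b
    if not beats:
        raise ValueError("no beats requested")
    return BeatDataset(np.vstack(beats).astype(np.float64),
                       np.asarray(labels, dtype=np.int64),
                       class_names, fs, "synthetic")


def kfold_evaluate(data: BeatDataset, cfg: GANConfig, k: int, seed: int = 0,
                   epochs: int = 10) -> list:
    """Train on K-1 folds, synthesize the held-out fold's class mixture and
    score it (PRD/FD/RMSE/MAE, class-mean pairing); one report per fold."""
    folds = kfold_indices(data.n, k, seed=seed)
    reports: list[MetricsReport] = []
    for i, fold in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(data.n), fold)
        model, _ = fit(data.subset(train_idx), cfg, epochs=epochs, seed=seed + i)
        held = data.subset(fold)
        counts = {int(c): int((held.labels == c).sum())
                  for c in np.unique(held.labels)}
        synth = generate_scarce(model, counts, data.class_names,
                                seed=seed + i, fs=data.fs)
        reports.append(generation_report(held, synth))
    return reports


# -- checkpointing -------------------------------------------------------

def save_checkpoint(path, trainer: Trainer) -> None:
    """Serialize networks, optimizer moments, RNG state and history to npz."""
    arrays = {}
    nets = {"enc": trainer.model.encoder, "dec": trainer.model.decoder,
            "gen": trainer.model.generator, "disc": trainer.model.discriminator}
    for name, net in nets.items():
        for i, a in enumerate(net.state_arrays()):
            arrays[f"net_{name}_{i}"] = a
    for oname, opt in [("ae", trainer.opt_ae), ("g", trainer.opt_g),
                       ("d", trainer.opt_d)]:
        st = opt.state()
        for i, (m, v) in enumerate(zip(st["m"], st["v"])):
            arrays[f"opt_{oname}_m_{i}"] = m
            arrays[f"opt_{oname}_v_{i}"] = v
        arrays[f"opt_{oname}_t"] = np.array(st["t"])
    meta = {
        "cfg": asdict(trainer.cfg),
        "state": asdict(trainer.state),
        "rng_state": trainer.rng.bit_generator.state,
        "class_names": trainer.class_names,
        "fs": trainer.fs,
        "model_seed": trainer.model.seed,
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path, data: BeatDataset) -> Trainer:
    """Rebuild a :class:`Trainer` exactly as checkpointed."""
    with np.load(path) as f:
        arrays = {k: f[k] for k in f.files}
    meta = json.loads(bytes(arrays.pop("meta")).decode())
    cfg = GANConfig(**meta["cfg"])
    model = GANModel(cfg, seed=meta["model_seed"])
    tr = Trainer(model, data, seed=meta["state"]["seed"])
    nets = {"enc": model.encoder, "dec": model.decoder,
            "gen": model.generator, "disc": model.discriminator}
    for name, net in nets.items():
        n = len(net.parameters())
        net.load_state_arrays([arrays[f"net_{name}_{i}"] for i in range(n)])
    for oname, opt in [("ae", tr.opt_ae), ("g", tr.opt_g), ("d", tr.opt_d)]:
        n = len(opt.params)
        opt.load_state({
            "t": int(arrays[f"opt_{oname}_t"]),
            "m": [arrays[f"opt_{oname}_m_{i}"] for i in range(n)],
            "v": [arrays[f"opt_{oname}_v_{i}"] for i in range(n)],
        })
    st = meta["state"]
    tr.state = TrainState(
        epoch=st["epoch"], history=st["history"], g_updates=st["g_updates"],
        d_updates=st["d_updates"], g_per_d=st["g_per_d"], seed=st["seed"],
        plan=st["plan"],
    )
    tr.rng.bit_generator.state = meta["rng_state"]
    return tr
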