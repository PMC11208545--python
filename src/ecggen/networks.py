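"""The four conditional transformer networks: encoder, decoder, generator,
discriminator.

Each network shares the same trunk: a multi-scale convolutional stem
(kernels 1, 3, 5, each conv followed by a stride-1 same-padded max pool that
smooths without shortening the 100-sample axis), additive sinusoidal
positional encoding, layer-normalized multi-head self-attention with a
residual connection, and a width -> 2*width -> width feed-forward, also
residual.  The encoder lifts 1-channel beats to ``model_width`` latent
features; the decoder projects latents back to one channel per timestep; the
generator maps per-timestep Gaussian noise concatenated with a one-hot class
condition to a latent sequence; the discriminator consumes beats plus the
condition and emits one real/fake logit per class, of which the logit at the
conditioning class is used by the adversarial losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Conv1d, Dropout, LayerNorm, Linear, MaxPool1d, Module,
    MultiHeadAttention, Tensor, concat, no_grad, sinusoidal_encoding,
)

__all__ = ["GANConfig", "Encoder", "Decoder", "Generator", "Discriminator",
           "GANModel", "one_hot_sequence", "positional_encoding"]


@dataclass
class GANConfig:
    """Architecture hyperparameters shared by all four networks.

    Defaults follow the full-scale layer plan (width 512, 8 heads, batch
    128); :meth:`desk` returns the scaled-down preset used for CPU-scale
    experiments and tests.
    """

    seq_len: int = 100
    model_width: int = 512
    n_heads: int = 8
    conv_kernels: tuple = (1, 3, 5)
    ffn_multiplier: int = 2
    n_classes: int = 5
    dropout: float = 0.1
    noise_width: int | None = None
    cond_scale: float | None = None
    batch_size: int = 128
    learning_rate: float = 1e-4
    loss_weights: dict = field(
        default_factory=lambda: {"reconstruction": 10.0, "supervised": 10.0,
                                 "adversarial": 1.0}
    )

    def __post_init__(self):
        if self.model_width % self.n_heads:
            raise ValueError("model_width must be divisible by n_heads")
        if self.seq_len < max(self.conv_kernels):
            raise ValueError("seq_len must be >= the largest conv kernel")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.noise_width is None:
            self.noise_width = self.model_width
        if self.cond_scale is None:
            # keep the one-hot condition energetically comparable to the
            # unit-variance noise channels it is concatenated with
            self.cond_scale = float(np.sqrt(self.noise_width))

    @classmethod
    def desk(cls, n_classes: int = 5, seq_len: int = 100) -> "GANConfig":
        return cls(seq_len=seq_len, model_width=32, n_heads=4, n_classes=n_classes,
                   dropout=0.0, batch_size=32, learning_rate=1e-3)

    def stem_widths(self, from_signal: bool) -> tuple:
        w = self.model_width
        if from_signal:  # 1 -> w/8 -> w/4 -> w, mirroring the full plan 1->64->128->512
            return (max(w // 8, 4), max(w // 4, 8), w)
        return (w, w, w)


def positional_encoding(seq_len: int, width: int) -> np.ndarray:
    """Sinusoidal positional encoding matrix (seq_len, width), in [-1, 1]."""
    return sinusoidal_encoding(seq_len, width)


def one_hot_sequence(labels, n_classes: int, seq_len: int) -> np.ndarray:
    """(B, seq_len, n_classes) one-hot condition block, constant over time."""
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    eye = np.eye(n_classes, dtype=np.float32)
    return np.repeat(eye[labels][:, None, :], seq_len, axis=1)


class _Trunk(Module):
    """Conv stem + positional encoding + attention/feed-forward block."""

    def __init__(self, c_in: int, cfg: GANConfig, rng: np.random.Generator,
                 from_signal: bool):
        w = cfg.model_width
        w1, w2, w3 = cfg.stem_widths(from_signal)
        k1, k2, k3 = cfg.conv_kernels
        self.conv1 = Conv1d(c_in, w1, k1, rng)
        self.pool1 = MaxPool1d(k1)
        self.conv2 = Conv1d(w1, w2, k2, rng)
        self.pool2 = MaxPool1d(k2)
        self.conv3 = Conv1d(w2, w3, k3, rng)
        self.norm1 = LayerNorm(w)
        self.attn = MultiHeadAttention(w, cfg.n_heads, rng)
        self.norm2 = LayerNorm(w)
        self.fc1 = Linear(w, cfg.ffn_multiplier * w, rng)
        self.norm3 = LayerNorm(cfg.ffn_multiplier * w)
        self.fc2 = Linear(cfg.ffn_multiplier * w, w, rng)
        self.drop = Dropout(cfg.dropout)
        self.pos = sinusoidal_encoding(cfg.seq_len, w)

    def __call__(self, x: Tensor, rng=None, train: bool = False) -> Tensor:
        h = self.pool1(self.conv1(x))
        h = self.pool2(self.conv2(h))
        h = self.conv3(h)
        h = h + Tensor(self.pos)
        h = h + self.drop(self.attn(self.norm1(h)), rng, train)
        ff = self.fc2(self.norm3(self.fc1(self.norm2(h))).relu())
        return h + self.drop(ff, rng, train)


def _check_seq(x: np.ndarray, cfg: GANConfig, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:
        x = x[:, :, None]
    if x.shape[1] != cfg.seq_len:
        raise ValueError(
            f"{what} length {x.shape[1]} != configured seq_len {cfg.seq_len}"
        )
    return x


class Encoder(Module):
    """Beats (B, L, 1) -> latent sequences (B, L, model_width)."""

    def __init__(self, cfg: GANConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.trunk = _Trunk(1, cfg, rng, from_signal=True)

    def __call__(self, beats, rng=None, train: bool = False) -> Tensor:
        x = beats if isinstance(beats, Tensor) else Tensor(
            _check_seq(beats, self.cfg, "beat")
        )
        return self.trunk(x, rng, train)


class Decoder(Module):
    """Latent sequences (B, L, model_width) -> beats (B, L, 1)."""

    def __init__(self, cfg: GANConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.trunk = _Trunk(cfg.model_width, cfg, rng, from_signal=False)
        self.head = Linear(cfg.model_width, 1, rng)

    def __call__(self, latent, rng=None, train: bool = False) -> Tensor:
        x = latent if isinstance(latent, Tensor) else Tensor(
            _check_seq(latent, self.cfg, "latent")
        )
        return self.head(self.trunk(x, rng, train))


class Generator(Module):
    """Per-timestep Gaussian noise + one-hot condition -> latent sequence."""

    def __init__(self, cfg: GANConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.trunk = _Trunk(cfg.noise_width + cfg.n_classes, cfg, rng,
                            from_signal=False)

    def __call__(self, noise, labels, rng=None, train: bool = False) -> Tensor:
        cfg = self.cfg
        z = noise if isinstance(noise, Tensor) else Tensor(
            _check_seq(noise, cfg, "noise")
        )
        cond = Tensor(cfg.cond_scale *
                      one_hot_sequence(labels, cfg.n_classes, cfg.seq_len))
        return self.trunk(concat([z, cond], axis=-1), rng, train)


class Discriminator(Module):
    """Beats + condition -> per-class real/fake logits (B, n_classes)."""

    def __init__(self, cfg: GANConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.trunk = _Trunk(1 + cfg.n_classes, cfg, rng, from_signal=True)
        self.head = Linear(cfg.model_width, cfg.n_classes, rng)

    def __call__(self, beats, labels, rng=None, train: bool = False) -> Tensor:
        cfg = self.cfg
        x = beats if isinstance(beats, Tensor) else Tensor(
            _check_seq(beats, cfg, "beat")
        )
        cond = Tensor(cfg.cond_scale *
                      one_hot_sequence(labels, cfg.n_classes, cfg.seq_len))
        h = self.trunk(concat([x, cond], axis=-1), rng, train)
        return self.head(h.mean(axis=1))  # pool over time -> (B, n_classes)

    def select(self, scores: Tensor, labels) -> Tensor:
        """Pick the logit at each sample's conditioning class."""
        onehot = np.eye(self.cfg.n_classes, dtype=np.float32)[
            np.asarray(labels, dtype=np.int64)
        ]
        return (scores * Tensor(onehot)).sum(axis=-1)


class GANModel(Module):
    """Container for the four networks plus their configuration."""

    def __init__(self, cfg: GANConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.seed = seed
        self.encoder = Encoder(cfg, rng)
        self.decoder = Decoder(cfg, rng)
        self.generator = Generator(cfg, rng)
        self.discriminator = Discriminator(cfg, rng)

    # numpy-in / numpy-out conveniences (inference mode, no tape)
    def encode(self, beats: np.ndarray) -> np.ndarray:
        with no_grad():
            return self.encoder(beats).data

    def decode(self, latent: np.ndarray) -> np.ndarray:
        with no_grad():
            return self.decoder(latent).data[:, :, 0]

    def generate(self, noise: np.ndarray, labels) -> np.ndarray:
        with no_grad():
            return self.generator(noise, labels).data

    def discriminate(self, beats: np.ndarray, labels) -> np.ndarray:
        with no_grad():
            return self.discriminator(beats, labels).data
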