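"""Synthetic annotated ECG fixtures with class-distinct beat morphologies.

Each beat class is a sum of Gaussian bumps standing in for the P/Q/R/S/T
waves, with per-class parameter overrides that caricature the clinical
morphology: atrial premature beats get an early prominent P wave, ventricular
premature beats a wide high-amplitude QRS with no P, bundle-branch blocks a
widened, notched QRS.  Records place jittered RR intervals and additive
Gaussian noise; every source of randomness flows through the caller's seed.

This emulates the *class-separable* structure of an annotated arrhythmia
database, not its physiology (see docs/methods.md for what that implies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BeatDataset, ECGRecord
from .segmentation import MITBIH_CLASSES, ClassMap

__all__ = [
    "BeatTemplateParams", "DEFAULT_WAVES", "beat_template", "synth_record",
    "make_imbalanced_dataset", "nearest_template_labels", "class_templates",
]

# (amplitude mV, center offset relative to R in samples, width in samples)
DEFAULT_WAVES = {
    "N": [(0.15, -50, 8), (-0.10, -10, 3), (1.00, 0, 5), (-0.25, 12, 4), (0.30, 55, 14)],
    "A": [(0.30, -70, 6), (-0.10, -10, 3), (0.90, 0, 5), (-0.25, 12, 4), (0.25, 50, 13)],
    "V": [(1.40, 0, 14), (-0.55, 28, 10), (-0.40, 75, 16)],
    "L": [(0.80, -9, 9), (0.70, 14, 9), (-0.30, 40, 8), (-0.25, 75, 14)],
    "R": [(0.35, -14, 5), (0.90, 5, 8), (-0.60, 24, 11), (0.25, 65, 12)],
}


@dataclass
class BeatTemplateParams:
    """Morphology and timing parameters of the fixture generator.

    ``waves`` maps class symbol -> list of (amplitude mV, center offset from
    the R-peak in samples, Gaussian width in samples).  ``rr_mean``/``rr_sd``
    set the jittered beat-to-beat spacing in samples; ``noise_sd`` the
    additive Gaussian noise in mV.
    """

    waves: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_WAVES.items()})
    noise_sd: float = 0.05
    rr_mean: float = 330.0
    rr_sd: float = 12.0
    beat_length: int = 300
    r_offset: int = 100

    def __post_init__(self):
        if self.rr_mean <= self.beat_length * 0.5:
            raise ValueError("rr_mean must exceed half the beat length")
        for sym, waves in self.waves.items():
            if any(w[2] <= 0 for w in waves):
                raise ValueError(f"nonpositive wave width in class {sym}")


def beat_template(class_symbol: str, params: BeatTemplateParams | None = None,
                  length: int | None = None) -> np.ndarray:
    """Deterministic noiseless template of one beat class; R-peak at
    ``params.r_offset`` (index 100 by default)."""
    params = params or BeatTemplateParams()
    if class_symbol not in params.waves:
        raise ValueError(f"unknown beat class {class_symbol!r}")
    length = length or params.beat_length
    t = np.arange(length, dtype=np.float64) - params.r_offset
    out = np.zeros(length)
    for amp, center, width in params.waves[class_symbol]:
        out += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return out


def class_templates(cmap: ClassMap = MITBIH_CLASSES,
                    params: BeatTemplateParams | None = None) -> np.ndarray:
    """Stacked (C, L) matrix of class templates in ``cmap`` order."""
    params = params or BeatTemplateParams()
    return np.stack([beat_template(s, params) for s in cmap.symbols])


def synth_record(class_sequence, params: BeatTemplateParams | None = None,
                 fs: float = 360.0, seed: int = 0,
                 record_id: str = "synthetic") -> ECGRecord:
    """Continuous annotated record with one beat per entry of ``class_sequence``."""
    params = params or BeatTemplateParams()
    rng = np.random.default_rng(seed)
    n_beats = len(class_sequence)
    rr = np.maximum(
        rng.normal(params.rr_mean, params.rr_sd, size=n_beats),
        params.beat_length * 0.55,
    ).astype(int)
    r_positions = params.r_offset + 50 + np.cumsum(rr) - rr[0]
    total = int(r_positions[-1]) + params.beat_length + 50
    x = np.zeros(total)
    annotations = []
    for pos, sym in zip(r_positions, class_sequence):
        lo = int(pos) - params.r_offset
        x[lo : lo + params.beat_length] += beat_template(sym, params)
        annotations.append((int(pos), sym))
    if params.noise_sd > 0:
        x += rng.normal(0.0, params.noise_sd, size=total)
    return ECGRecord(record_id, fs, x, annotations)


def make_imbalanced_dataset(counts: dict, params: BeatTemplateParams | None = None,
                            cmap: ClassMap = MITBIH_CLASSES, seed: int = 0,
                            normalize: bool = True) -> BeatDataset:
    """Beat dataset with exactly the requested per-class counts.

    Beats are noisy copies of the class template; with ``normalize`` each beat
    is z-scored, matching the scale produced by record-level extraction.
    """
    params = params or BeatTemplateParams()
    if all(v == 0 for v in counts.values()):
        raise ValueError("at least one class count must be positive")
    rng = np.random.default_rng(seed)
    beats, labels = [], []
    for sym, n in counts.items():
        c = cmap.index(sym)
        if c is None:
            raise ValueError(f"symbol {sym!r} not in class map")
        if n == 0:
            continue
        tpl = beat_template(sym, params)
        block = tpl[None, :] + rng.normal(0.0, params.noise_sd,
                                          size=(n, params.beat_length))
        beats.append(block)
        labels.extend([c] * n)
    beats = np.vstack(beats)
    if normalize:
        mu = beats.mean(axis=1, keepdims=True)
        sd = beats.std(axis=1, keepdims=True)
        beats = (beats - mu) / np.where(sd > 0, sd, 1.0)
    return BeatDataset(beats, np.asarray(labels, dtype=np.int64),
                       list(cmap.class_names), 360.0, "real")


def nearest_template_labels(beats: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Assign each beat the class of the nearest template (both z-scored per
    trace, so the match is shape- not scale-based)."""

    def _z(a):
        mu = a.mean(axis=-1, keepdims=True)
        sd = a.std(axis=-1, keepdims=True)
        return (a - mu) / np.where(sd > 0, sd, 1.0)

    b = _z(np.atleast_2d(np.asarray(beats, dtype=np.float64)))
    t = _z(np.asarray(templates, dtype=np.float64))
    if b.shape[1] != t.shape[1]:
        raise ValueError(f"beat length {b.shape[1]} != template length {t.shape[1]}")
    d2 = ((b[:, None, :] - t[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)
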