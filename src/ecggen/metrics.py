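"""Generation-fidelity and classification metrics.

Generation quality is scored by four sequence metrics: the percentage
root-mean-square difference (PRD, reported on the x100 percent scale), the
discrete Fréchet distance (dynamic program over monotone couplings with
|a_i - b_j| as ground distance), RMSE and MAE.  Classification quality is
per-class precision/recall/F1 (percent) with a confusion matrix; "Avg" rows
are macro (unweighted) means over classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support as _sk_prfs

from .io import BeatDataset

__all__ = [
    "MetricsReport", "ClassReport", "prd", "frechet_distance", "rmse", "mae",
    "generation_report", "classification_report", "f1_from_precision_recall",
    "augmentation_ratio",
]


@dataclass
class MetricsReport:
    prd: float
    fd: float
    rmse: float
    mae: float
    pairing_mode: str = "mean"

    def as_dict(self) -> dict:
        return {"prd": self.prd, "fd": self.fd, "rmse": self.rmse,
                "mae": self.mae, "pairing_mode": self.pairing_mode}


@dataclass
class ClassReport:
    precision: np.ndarray  # percent, per class
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray
    class_names: list

    def as_dict(self) -> dict:
        return {
            "per_class": {
                name: {"precision": float(p), "recall": float(r), "f1": float(f)}
                for name, p, r, f in zip(self.class_names, self.precision,
                                         self.recall, self.f1)
            },
            "macro": {"precision": self.macro_precision,
                      "recall": self.macro_recall, "f1": self.macro_f1},
            "confusion": self.confusion.tolist(),
        }


def _pair(a, b, what="sequences"):
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"{what} must have equal length: {a.size} vs {b.size}")
    return a, b


def prd(reference, candidate) -> float:
    """100 * sqrt( sum (ref-cand)^2 / sum ref^2 )."""
    a, b = _pair(reference, candidate)
    denom = float(np.sum(a**2))
    if denom == 0.0:
        raise ValueError("PRD undefined for an all-zero reference")
    return 100.0 * float(np.sqrt(np.sum((a - b) ** 2) / denom))


def frechet_distance(a, b) -> float:
    """Discrete Fréchet distance between two sampled 1-D curves.

    Standard dynamic program: F(i,j) = max(|a_i - b_j|,
    min(F(i-1,j), F(i-1,j-1), F(i,j-1))).  Symmetric; zero iff the sequences
    are identical elementwise (and equal length).
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("Fréchet distance undefined for empty sequences")
    d = np.abs(a[:, None] - b[None, :])
    n, m = d.shape
    prev = np.empty(m)
    prev[0] = d[0, 0]
    for j in range(1, m):
        prev[j] = max(prev[j - 1], d[0, j])
    cur = np.empty(m)
    for i in range(1, n):
        cur[0] = max(prev[0], d[i, 0])
        row = d[i]
        for j in range(1, m):
            cur[j] = max(min(prev[j], prev[j - 1], cur[j - 1]), row[j])
        prev, cur = cur, prev
    return float(prev[m - 1])


def rmse(a, b) -> float:
    x, y = _pair(a, b)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def mae(a, b) -> float:
    x, y = _pair(a, b)
    return float(np.mean(np.abs(x - y)))


def generation_report(real: BeatDataset, synth: BeatDataset,
                      pairing: str = "mean") -> MetricsReport:
    """Score synthetic beats against real ones, class by class.

    ``pairing="mean"`` compares each synthetic beat to the mean real beat of
    its class; ``pairing="nearest"`` to its nearest real beat of the same
    class.  Per-beat PRD/FD/RMSE/MAE are averaged into one report.
    """
    if list(real.class_names) != list(synth.class_names):
        raise ValueError("datasets use different class maps")
    if pairing not in ("mean", "nearest"):
        raise ValueError(f"unknown pairing mode {pairing!r}")
    vals = {"prd": [], "fd": [], "rmse": [], "mae": []}
    for c in np.unique(synth.labels):
        real_c = real.beats[real.labels == c]
        if real_c.shape[0] == 0:
            raise ValueError(
                f"class {synth.class_names[c]!r} absent from the real dataset"
            )
        mean_c = real_c.mean(axis=0)
        for beat in synth.beats[synth.labels == c]:
            if pairing == "mean":
                ref = mean_c
            else:
                ref = real_c[np.argmin(((real_c - beat) ** 2).sum(axis=1))]
            vals["prd"].append(prd(ref, beat))
            vals["fd"].append(frechet_distance(ref, beat))
            vals["rmse"].append(rmse(ref, beat))
            vals["mae"].append(mae(ref, beat))
    return MetricsReport(
        prd=float(np.mean(vals["prd"])), fd=float(np.mean(vals["fd"])),
        rmse=float(np.mean(vals["rmse"])), mae=float(np.mean(vals["mae"])),
        pairing_mode=pairing,
    )


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean, F1 = 2 P R / (P + R); 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def classification_report(truth, predicted, n_classes: int,
                          class_names=None) -> ClassReport:
    """Per-class precision/recall/F1 in percent, plus confusion matrix.

    A class that is never predicted gets precision 0 by convention.
    """
    truth = np.asarray(truth, dtype=np.int64)
    predicted = np.asarray(predicted, dtype=np.int64)
    if truth.size == 0:
        raise ValueError("empty label arrays")
    if truth.shape != predicted.shape:
        raise ValueError("truth/predicted length mismatch")
    labels = list(range(n_classes))
    p, r, f, _ = _sk_prfs(truth, predicted, labels=labels, zero_division=0)
    cm = _sk_confusion(truth, predicted, labels=labels)
    names = list(class_names) if class_names is not None else [str(i) for i in labels]
    return ClassReport(
        precision=p * 100.0, recall=r * 100.0, f1=f * 100.0,
        macro_precision=float(p.mean() * 100.0),
        macro_recall=float(r.mean() * 100.0),
        macro_f1=float(f.mean() * 100.0),
        confusion=cm, class_names=names,
    )


def augmentation_ratio(before: int, after: int) -> float:
    """Post-expansion count over pre-expansion count, x100 percent."""
    if before < 1:
        raise ValueError("pre-expansion count must be >= 1")
    return 100.0 * after / before
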