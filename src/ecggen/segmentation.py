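"""R-peak-referenced beat segmentation, class mapping and data splitting.

Beats are cut as fixed windows around annotated R-peaks: ``pre`` samples
before the peak and ``post`` after (defaults 100/200 at 360 Hz, i.e. a
300-sample cycle).  Symbols are mapped to contiguous class indices by a
:class:`ClassMap`; windows crossing a record boundary and unmapped symbols
are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BeatDataset, ECGRecord

__all__ = [
    "ClassMap", "MITBIH_CLASSES", "CSPC_CLASSES", "DistributionReport",
    "extract_beats", "downsample", "class_distribution",
    "stratified_split", "kfold_indices",
]


@dataclass(frozen=True)
class ClassMap:
    """Bijective map from retained annotation symbols to class indices."""

    symbols: tuple
    class_names: tuple

    def __post_init__(self):
        if len(self.symbols) != len(self.class_names):
            raise ValueError("one name per symbol required")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("duplicate symbols")

    @property
    def n_classes(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str):
        try:
            return self.symbols.index(symbol)
        except ValueError:
            return None


#: the five MIT-BIH beat classes retained: normal, atrial premature,
#: premature ventricular, left and right bundle-branch block
MITBIH_CLASSES = ClassMap(
    symbols=("N", "A", "V", "L", "R"),
    class_names=(
        "normal", "atrial_premature", "ventricular_premature",
        "left_bundle_branch_block", "right_bundle_branch_block",
    ),
)

#: CSPC2020-style three-class map
CSPC_CLASSES = ClassMap(
    symbols=("N", "V", "S"),
    class_names=("normal", "ventricular_premature", "supraventricular_premature"),
)


@dataclass
class DistributionReport:
    counts: dict
    fractions: dict
    minority_fraction: float
    imbalance_ratio: float


def extract_beats(record: ECGRecord, cmap: ClassMap, pre: int = 100,
                  post: int = 200, normalize: bool = True) -> BeatDataset:
    """Cut ``[r-pre, r+post)`` windows around each mapped annotation.

    With ``normalize`` the record is z-scored (mean 0, sd 1 over the whole
    record) before cutting, giving the scale the generative model trains on.
    """
    if pre <= 0 or post <= 0:
        raise ValueError("pre and post must be positive")
    x = record.samples
    if normalize:
        sd = x.std()
        x = (x - x.mean()) / sd if sd > 0 else x - x.mean()
    n = x.shape[0]
    beats, labels = [], []
    for idx, sym in record.annotations:
        c = cmap.index(sym)
        if c is None:
            continue
        lo, hi = idx - pre, idx + post
        if lo < 0 or hi > n:
            continue
        beats.append(x[lo:hi])
        labels.append(c)
    beats = np.asarray(beats, dtype=np.float64).reshape(len(beats), pre + post)
    return BeatDataset(beats, np.asarray(labels, dtype=np.int64),
                       list(cmap.class_names), record.fs, "real")


def downsample(ds: BeatDataset, interval: int) -> BeatDataset:
    """Keep every ``interval``-th sample of each beat (plain strided pick,
    starting at index 0; no anti-alias filter)."""
    if interval < 1:
        raise ValueError(f"interval must be >= 1, got {interval}")
    return BeatDataset(ds.beats[:, ::interval], ds.labels.copy(),
                       list(ds.class_names), ds.fs / interval, ds.provenance)


def class_distribution(ds: BeatDataset) -> DistributionReport:
    """Per-class counts/fractions, minority fraction and majority/minority ratio."""
    if ds.n == 0:
        raise ValueError("empty dataset has no class distribution")
    counts = {
        name: int((ds.labels == i).sum()) for i, name in enumerate(ds.class_names)
    }
    fractions = {k: v / ds.n for k, v in counts.items()}
    nonzero = [v for v in counts.values() if v > 0]
    return DistributionReport(
        counts=counts, fractions=fractions,
        minority_fraction=min(nonzero) / ds.n,
        imbalance_ratio=max(nonzero) / min(nonzero),
    )


def stratified_split(ds: BeatDataset, train_fraction: float = 0.8, seed: int = 0):
    """Deterministic per-class split into (train, test) preserving proportions."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in range(len(ds.class_names)):
        idx = np.flatnonzero(ds.labels == c)
        if idx.size == 0:
            continue
        if idx.size < 2:
            import warnings
            warnings.warn(
                f"class {ds.class_names[c]} has a single member; assigned to train"
            )
            train_idx.append(idx)
            continue
        perm = rng.permutation(idx)
        k = int(round(train_fraction * idx.size))
        k = min(max(k, 1), idx.size - 1)
        train_idx.append(perm[:k])
        test_idx.append(perm[k:])
    train = np.sort(np.concatenate(train_idx)) if train_idx else np.array([], dtype=int)
    test = np.sort(np.concatenate(test_idx)) if test_idx else np.array([], dtype=int)
    return ds.subset(train), ds.subset(test)


def kfold_indices(n: int, k: int, seed: int = 0):
    """K disjoint shuffled folds covering [0, n); sizes differ by at most 1."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= K <= n, got K={k}, n={n}")
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]
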