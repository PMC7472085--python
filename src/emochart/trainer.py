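"""Training, evaluation and spectral introspection.

Protocol: segment-level 70/30 random split, Adam (initial learning rate 1e-3,
squared-gradient decay 0.99) with mini-batches of 240, cross-entropy loss on
the four quadrant classes. Confusion matrices are reported in count +
percent-of-test-set style with per-row precision, per-column recall and the
overall accuracy in the corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import nn
from .containers import SegmentSet
from .labels import QUADRANTS

__all__ = [
    "TrainConfig",
    "ConfusionMatrix",
    "random_split",
    "train",
    "evaluate",
    "predict_proba",
    "segments_to_sequences",
    "images_to_batch",
    "power_spectrum_report",
]


@dataclass
class TrainConfig:
    batch_size: int = 240
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.99  # squared-gradient decay factor
    epochs: int = 10
    seed: int = 0
    split_fraction: float = 0.7

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def random_split(
    n_or_set: int | SegmentSet,
    fraction: float = 0.7,
    seed: int = 0,
    stratify: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint exhaustive train/test index split, deterministic per seed.

    Train size is ``round(fraction · n)``. The default is the plain
    (unstratified) segment-level split; pass ``stratify=labels`` for a
    label-balanced variant.
    """
    n = len(n_or_set) if isinstance(n_or_set, SegmentSet) else int(n_or_set)
    if n < 2:
        raise ValueError("need at least 2 items to split")
    rng = np.random.default_rng(seed)
    if stratify is None:
        perm = rng.permutation(n)
        n_train = round(fraction * n)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])
    stratify = np.asarray(stratify)
    train_idx = []
    for cls in np.unique(stratify):
        idx = np.flatnonzero(stratify == cls)
        perm = rng.permutation(len(idx))
        train_idx.append(idx[perm[: round(fraction * len(idx))]])
    train_idx = np.sort(np.concatenate(train_idx))
    mask = np.ones(n, dtype=bool)
    mask[train_idx] = False
    return train_idx, np.flatnonzero(mask)


def subject_split(
    provenance: pd.DataFrame, fraction: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Subject-level split: all of a subject's segments stay on one side.

    The default protocol splits at segment level, which places segments of
    the same subject (and trial) on both sides; this variant supports a
    genuinely subject-independent evaluation instead.
    """
    subjects = provenance["subject"].to_numpy()
    unique = np.unique(subjects)
    if len(unique) < 2:
        raise ValueError("subject-level split needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(unique)
    n_train = max(1, min(len(unique) - 1, round(fraction * len(unique))))
    train_subjects = set(perm[:n_train].tolist())
    mask = np.isin(subjects, list(train_subjects))
    return np.flatnonzero(mask), np.flatnonzero(~mask)


def segments_to_sequences(seg_set: SegmentSet, channel: int = 0) -> np.ndarray:
    """(n, 128, 1) sequence batch from one channel of a segment set."""
    return seg_set.data[:, channel, :, None].astype(np.float32)


def images_to_batch(images: np.ndarray) -> np.ndarray:
    """(n, 81, 128, 1) image batch from stacked topographic matrices."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[..., None]
    return images


def train(
    model: nn.Sequential,
    x: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig | None = None,
) -> list[float]:
    """Mini-batch Adam training; returns the per-epoch mean loss curve."""
    cfg = cfg or TrainConfig()
    if len(x) == 0:
        raise ValueError("empty training set")
    if len(x) != len(y):
        raise ValueError("x and y length mismatch")
    y = np.asarray(y)
    opt = nn.Adam(model.params(), lr=cfg.learning_rate,
                  beta1=cfg.beta1, beta2=cfg.beta2)
    rng = np.random.default_rng(cfg.seed)
    curve: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            model.zero_grad()
            logits = model.forward(x[idx], train=True)
            loss, grad = nn.softmax_cross_entropy(logits, y[idx])
            model.backward(grad)
            opt.step()
            losses.append(loss)
        curve.append(float(np.mean(losses)))
    return curve


def predict_proba(model: nn.Sequential, x: np.ndarray, batch: int = 512) -> np.ndarray:
    """Class probabilities, computed in chunks to bound memory."""
    out = []
    for start in range(0, len(x), batch):
        logits = model.forward(x[start : start + batch], train=False)
        out.append(nn.softmax(logits))
    return np.concatenate(out, axis=0)


@dataclass
class ConfusionMatrix:
    """4×4 counts (output class × target class) with count+percent margins."""

    counts: np.ndarray  # rows: predicted, cols: true
    class_names: tuple[str, ...] = QUADRANTS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected {k}×{k} counts")

    @classmethod
    def from_predictions(cls, predicted: np.ndarray, target: np.ndarray,
                         n_classes: int = 4) -> "ConfusionMatrix":
        counts = np.zeros((n_classes, n_classes), dtype=np.int64)
        np.add.at(counts, (np.asarray(predicted), np.asarray(target)), 1)
        return cls(counts, QUADRANTS[:n_classes])

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.n) if self.n else float("nan")

    @property
    def percent(self) -> np.ndarray:
        """Per-cell percentage of the whole test set."""
        return 100.0 * self.counts / self.n

    @property
    def precision(self) -> np.ndarray:
        """Per output row: diagonal / row sum."""
        rows = self.counts.sum(axis=1)
        return np.divide(np.diag(self.counts), rows, where=rows > 0,
                         out=np.full(len(rows), np.nan))

    @property
    def recall(self) -> np.ndarray:
        """Per target column: diagonal / column sum."""
        cols = self.counts.sum(axis=0)
        return np.divide(np.diag(self.counts), cols, where=cols > 0,
                         out=np.full(len(cols), np.nan))

    def to_frame(self) -> pd.DataFrame:
        """Count + percent cells with Total margins (precision/recall/accuracy)."""
        k = len(self.class_names)
        cells = [
            [f"{self.counts[i, j]} ({self.percent[i, j]:.1f}%)" for j in range(k)]
            + [f"{100 * self.precision[i]:.1f}%"]
            for i in range(k)
        ]
        cells.append(
            [f"{100 * self.recall[j]:.1f}%" for j in range(k)]
            + [f"{100 * self.accuracy:.1f}%"]
        )
        return pd.DataFrame(
            cells,
            index=[*self.class_names, "Total"],
            columns=[*self.class_names, "Total"],
        )


def evaluate(
    model: nn.Sequential, x: np.ndarray, y: np.ndarray
) -> tuple[ConfusionMatrix, pd.DataFrame]:
    """Confusion matrix plus per-segment predictions with probabilities."""
    if len(x) == 0:
        raise ValueError("empty test set")
    probs = predict_proba(model, x)
    pred = probs.argmax(axis=1)
    cm = ConfusionMatrix.from_predictions(pred, y)
    frame = pd.DataFrame({"predicted": pred, "target": np.asarray(y)})
    for k, name in enumerate(QUADRANTS):
        frame[f"p_{name}"] = probs[:, k]
    return cm, frame


def power_spectrum_report(
    segments: np.ndarray,
    probs: np.ndarray,
    targets: np.ndarray,
    fs: float = 128.0,
) -> pd.DataFrame:
    """Best/worst instance per class by correct-class probability, with spectra.

    For every class present in ``targets``, selects the segment whose
    predicted probability for its true class is highest (best) and lowest
    (worst), and attaches each one's Welch power spectrum — the raw material
    for best/worst-case spectral comparison plots.
    """
    segments = np.asarray(segments)
    probs = np.asarray(probs)
    targets = np.asarray(targets)
    if probs.ndim != 2 or len(probs) != len(segments):
        raise ValueError("probabilities must be (n, n_classes) aligned with segments")
    rows = []
    for cls in np.unique(targets):
        idx = np.flatnonzero(targets == cls)
        p_true = probs[idx, cls]
        for which, sel in (("best", idx[p_true.argmax()]), ("worst", idx[p_true.argmin()])):
            sig = segments[sel].ravel()
            f, pxx = sps.welch(sig, fs=fs, nperseg=min(128, len(sig)))
            rows.append(
                {
                    "class": QUADRANTS[int(cls)],
                    "which": which,
                    "index": int(sel),
                    "p_true": float(probs[sel, cls]),
                    "freqs": f,
                    "psd": pxx,
                }
            )
    return pd.DataFrame(rows)
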