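"""End-to-end orchestration: synth → preprocess → encode → train → fuse.

These helpers glue the stage modules together for the common case of running
the whole chart on a synthetic dataset shape. They are what the CLI, the
example scripts and the acceptance checks call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from . import nets, synthgen, trainer
from .containers import SegmentSet, concat_segment_sets
from .fusion import VoteTable, fuse_report, majority_vote
from .preprocess import preprocess_trial_recording
from .synthgen import DatasetShape, SyntheticTrial
from .topomap import iter_encode

__all__ = [
    "preprocess_dataset",
    "preprocess_trials",
    "count_images",
    "ModalityResult",
    "train_modality",
    "run_benchmark",
]


def preprocess_trials(
    trials: Iterable[SyntheticTrial],
    shape: DatasetShape,
    modalities: tuple[str, ...] | None = None,
) -> Iterator[dict[str, SegmentSet]]:
    """Per trial, run the full preprocessing chain for each modality."""
    mods = modalities or shape.modalities()
    for tr in trials:
        label = synthgen.trial_label(tr, shape.rating_scale)
        yield {
            m: preprocess_trial_recording(
                tr.signals[m], tr.baselines[m],
                trim_s=shape.edge_trim_seconds, label=label,
            )
            for m in mods
        }


def preprocess_dataset(
    shape: DatasetShape,
    signatures: Mapping[str, synthgen.ClassSignature] | None = None,
    seed: int = 0,
    modalities: tuple[str, ...] | None = None,
) -> dict[str, SegmentSet]:
    """Generate and preprocess a whole dataset, one SegmentSet per modality."""
    mods = modalities or shape.modalities()
    per_mod: dict[str, list[SegmentSet]] = {m: [] for m in mods}
    trials = synthgen.iter_dataset(shape, signatures, seed)
    for result in preprocess_trials(trials, shape, mods):
        for m, segs in result.items():
            per_mod[m].append(segs)
    return {m: concat_segment_sets(v) for m, v in per_mod.items()}


def count_images(
    shape: DatasetShape,
    signatures: Mapping[str, synthgen.ClassSignature] | None = None,
    seed: int = 0,
) -> int:
    """Stream the EEG pipeline and count encoded topographic images.

    Processes trial by trial so arbitrarily large shapes fit in memory; each
    segment is actually encoded (not inferred from arithmetic).
    """
    trials = synthgen.iter_dataset(shape, signatures, seed)
    total = 0
    for result in preprocess_trials(trials, shape, modalities=("EEG",)):
        total += sum(1 for _ in iter_encode(result["EEG"]))
    return total


@dataclass
class ModalityResult:
    """Trained model plus evaluation artifacts for one modality."""

    modality: str
    model: object
    loss_curve: list[float]
    confusion: trainer.ConfusionMatrix
    predictions: pd.DataFrame
    test_idx: np.ndarray

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.confusion.accuracy


def _features(seg_set: SegmentSet) -> np.ndarray:
    if seg_set.modality == "EEG":
        imgs = np.stack([img.matrix for img in iter_encode(seg_set)])
        return trainer.images_to_batch(imgs)
    return trainer.segments_to_sequences(seg_set)


def train_modality(
    seg_set: SegmentSet,
    cfg: trainer.TrainConfig | None = None,
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> ModalityResult:
    """Train the appropriate architecture for one modality and evaluate it.

    EEG segments are encoded as 81×128 topographic images and classified by
    the 2-D CNN; ECG/GSR segments go through the 1-D CNN + LSTM.
    """
    cfg = cfg or trainer.TrainConfig()
    x = _features(seg_set)
    y = seg_set.labels
    if split is None:
        split = trainer.random_split(len(x), cfg.split_fraction, cfg.seed)
    train_idx, test_idx = split
    spec = nets.build_eeg_2dcnn() if seg_set.modality == "EEG" else nets.build_seq_1dcnn_lstm()
    model = nets.instantiate(spec, seed=cfg.seed)
    curve = trainer.train(model, x[train_idx], y[train_idx], cfg)
    cm, preds = trainer.evaluate(model, x[test_idx], y[test_idx])
    return ModalityResult(seg_set.modality, model, curve, cm, preds, test_idx)


def run_benchmark(
    shape: DatasetShape,
    signatures: Mapping[str, synthgen.ClassSignature] | None = None,
    seed: int = 0,
    cfg: trainer.TrainConfig | None = None,
    modalities: tuple[str, ...] = ("EEG", "ECG_L", "ECG_R"),
) -> tuple[dict[str, ModalityResult], pd.DataFrame]:
    """Full chart on a synthetic shape: per-modality results + fusion table.

    All modalities share one 70/30 split so their test votes stay aligned.
    """
    cfg = cfg or trainer.TrainConfig(seed=seed)
    segs = preprocess_dataset(shape, signatures, seed, modalities)
    n = len(next(iter(segs.values())))
    split = trainer.random_split(n, cfg.split_fraction, cfg.seed)
    results = {m: train_modality(segs[m], cfg, split) for m in modalities}
    targets = next(iter(segs.values())).labels[split[1]]
    table = VoteTable(
        votes={m: r.predictions["predicted"].to_numpy() for m, r in results.items()},
        probs={
            m: r.predictions[[f"p_{q}" for q in trainer.QUADRANTS]].to_numpy()
            for m, r in results.items()
        },
        targets=targets,
    )
    return results, fuse_report(table)
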