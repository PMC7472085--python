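"""In-memory containers shared across the pipeline.

A :class:`Recording` is one modality's raw or filtered multichannel signal for
a single subject/trial; a :class:`SegmentSet` is the stack of 1-second,
128-sample windows — the unit of classification — together with quadrant
labels and provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MODALITIES = ("EEG", "ECG_L", "ECG_R", "GSR")

#: samples per second after basic preprocessing, and the segment length
TARGET_FS = 128


@dataclass
class Recording:
    """One modality's channels × samples matrix for one subject/trial."""

    data: np.ndarray  # (channels, samples)
    fs: float
    modality: str
    subject_id: int = 0
    trial_id: int = 0
    role: str = "stimulus"  # or "baseline"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "EEG" and self.data.shape[0] != 14:
            raise ValueError(
                f"EEG recording must have 14 channels, got {self.data.shape[0]}"
            )
        if self.modality in ("ECG_L", "ECG_R", "GSR") and self.data.shape[0] != 1:
            raise ValueError(f"{self.modality} recording must have 1 channel")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "Recording":
        return replace(self, data=data, fs=self.fs if fs is None else fs)


@dataclass
class SegmentSet:
    """Stack of 1-s segments: (n, channels, 128) with labels and provenance.

    ``labels`` are integer quadrant codes (see :data:`emochart.labels.QUADRANTS`);
    ``provenance`` has one row per segment with subject, trial and segment index.
    """

    data: np.ndarray  # (n, channels, 128)
    labels: np.ndarray  # (n,) int codes
    provenance: pd.DataFrame  # columns: subject, trial, segment
    modality: str
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("segment data must be (n, channels, samples)")
        if self.data.shape[-1] != TARGET_FS:
            raise ValueError(
                f"segments must have {TARGET_FS} samples, got {self.data.shape[-1]}"
            )
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.labels) != len(self.data):
            raise ValueError("labels length must match segment count")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def select(self, idx: np.ndarray) -> "SegmentSet":
        return SegmentSet(
            self.data[idx],
            self.labels[idx],
            self.provenance.iloc[np.asarray(idx)].reset_index(drop=True),
            self.modality,
            self.normalized,
        )


def concat_segment_sets(sets: list[SegmentSet]) -> SegmentSet:
    """Stack segment sets of one modality, preserving order and provenance."""
    if not sets:
        raise ValueError("cannot concatenate an empty list of segment sets")
    modality = sets[0].modality
    if any(s.modality != modality for s in sets):
        raise ValueError("all segment sets must share a modality")
    norm = all(s.normalized for s in sets)
    return SegmentSet(
        np.concatenate([s.data for s in sets], axis=0),
        np.concatenate([s.labels for s in sets]),
        pd.concat([s.provenance for s in sets], ignore_index=True),
        modality,
        norm,
    )
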