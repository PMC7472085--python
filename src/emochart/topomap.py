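"""EEG topographic image encoding.

Each 1-s, 14-channel EEG segment is placed into a sparse 81-slot topological
vector ordered by the Nasion 10–20 montage: channel AF3 occupies slot 4, F7
slot 13, … AF4 slot 76 (1-based), all other 67 slots stay zero. Stacking the
128 time samples column-wise yields an 81 × 128 feature matrix per segment,
optionally exported as an 8-bit grayscale PNG.

The classifier consumes the real-valued matrix; PNG export uses a fixed
quantizer (clip to ±4 after z-scoring, linear map to 0–255, zero → mid-gray
128) so pixel intensities are comparable across images.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from PIL import Image

from .containers import TARGET_FS, SegmentSet

__all__ = [
    "CHANNELS",
    "SLOTS_1BASED",
    "N_SLOTS",
    "TopoImage",
    "encode_segment",
    "decode_image",
    "write_png",
    "read_png",
    "quantize",
    "encode_dataset",
    "iter_encode",
]

#: Emotiv Epoc channel order and their 1-based slots in the 81-slot vector.
CHANNELS = ("AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
            "O2", "P8", "T8", "FC6", "F4", "F8", "AF4")
SLOTS_1BASED = (4, 13, 19, 21, 29, 31, 37, 39, 47, 49, 55, 57, 67, 76)
N_SLOTS = 81

_SLOTS0 = np.asarray(SLOTS_1BASED) - 1  # stored 0-based internally

CLIP = 4.0  # quantizer clip on z-scored amplitudes


@dataclass
class TopoImage:
    """81 × 128 sparse topographic feature matrix for one EEG segment."""

    matrix: np.ndarray
    subject: int = 0
    trial: int = 0
    segment: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape != (N_SLOTS, TARGET_FS):
            raise ValueError(f"topo image must be {N_SLOTS}×{TARGET_FS}")

    @property
    def channel_index_map(self) -> dict[str, int]:
        return dict(zip(CHANNELS, SLOTS_1BASED))


def encode_segment(seg: np.ndarray, subject: int = 0, trial: int = 0,
                   segment: int = 0) -> TopoImage:
    """Place a 14 × 128 segment into its 81 × 128 topographic matrix."""
    seg = np.asarray(seg)
    if seg.shape != (len(CHANNELS), TARGET_FS):
        raise ValueError(f"expected {len(CHANNELS)}×{TARGET_FS} segment, got {seg.shape}")
    img = np.zeros((N_SLOTS, TARGET_FS), dtype=seg.dtype)
    img[_SLOTS0] = seg
    return TopoImage(img, subject, trial, segment)


def decode_image(img: TopoImage) -> np.ndarray:
    """Inverse mapping: extract the 14 mapped rows (bit-exact round trip)."""
    return img.matrix[_SLOTS0].copy()


def quantize(matrix: np.ndarray, clip: float = CLIP) -> np.ndarray:
    """Fixed 8-bit quantizer: clip to ±clip, map linearly to 0–255, 0 → 128."""
    x = np.clip(np.asarray(matrix, dtype=np.float64), -clip, clip)
    return np.rint((x + clip) / (2 * clip) * 255.0).astype(np.uint8)


def write_png(img: TopoImage, path: Path, clip: float = CLIP) -> Path:
    """Write the image as 81 × 128 8-bit grayscale PNG."""
    if not np.all(np.isfinite(img.matrix)):
        raise ValueError("topo image contains non-finite values")
    path = Path(path)
    Image.fromarray(quantize(img.matrix, clip), mode="L").save(path)
    return path


def read_png(path: Path) -> np.ndarray:
    """Read back an exported PNG as a uint8 array."""
    return np.asarray(Image.open(Path(path)).convert("L"))


def iter_encode(segments: SegmentSet) -> Iterator[TopoImage]:
    """Lazily encode every segment of an EEG segment set."""
    if segments.modality != "EEG":
        raise ValueError("topographic encoding applies to EEG segments")
    prov = segments.provenance
    for i in range(len(segments)):
        row = prov.iloc[i]
        yield encode_segment(
            segments.data[i], int(row.subject), int(row.trial), int(row.segment)
        )


def encode_dataset(
    segments: SegmentSet, out_dir: Path | None = None
) -> tuple[list[TopoImage], pd.DataFrame]:
    """Encode all segments; optionally export PNGs; return images + manifest."""
    images = list(iter_encode(segments))
    rows = []
    for img, label in zip(images, segments.labels):
        rec = {
            "subject": img.subject,
            "trial": img.trial,
            "segment": img.segment,
            "quadrant": int(label),
        }
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            p = out_dir / f"s{img.subject:02d}_t{img.trial:02d}_k{img.segment:03d}.png"
            write_png(img, p)
            rec["path"] = str(p)
        rows.append(rec)
    return images, pd.DataFrame(rows)
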