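"""Preprocess one trial end to end and encode its EEG as topographic images.

Shows the two preprocessing tiers on a single synthetic trial — common-average
referencing, 4-45 Hz band-pass and edge trim for EEG; down-sampling and 60 Hz
low-pass for ECG — followed by 1-s segmentation, baseline removal, z-scoring,
and the sparse 81x128 topographic encoding (optionally exported as PNG).
"""

import numpy as np

from emochart import synthgen
from emochart.preprocess import preprocess_trial_recording
from emochart.topomap import encode_dataset

shape = synthgen.dreamer_shape()
trial = next(iter(synthgen.iter_dataset(shape, seed=3)))

label = synthgen.trial_label(trial, shape.rating_scale)
print(f"trial quadrant: {trial.quadrant} (label code {label})")

eeg = preprocess_trial_recording(
    trial.signals["EEG"], trial.baselines["EEG"], trim_s=2.0, label=label)
print(f"EEG: {trial.signals['EEG'].n_samples} raw samples -> "
      f"{eeg.data.shape[0]} segments of {eeg.data.shape[1]}x{eeg.data.shape[2]}")
print(f"  per-segment mean |{np.abs(eeg.data.mean(axis=-1)).max():.1e}|, "
      f"sd-1 |{np.abs(eeg.data.std(axis=-1) - 1).max():.1e}|  (z-scored)")

ecg = preprocess_trial_recording(
    trial.signals["ECG_R"], trial.baselines["ECG_R"], trim_s=2.0, label=label)
print(f"ECG_R: 256 Hz raw -> {ecg.data.shape[0]} segments @ 128 Hz")

images, manifest = encode_dataset(eeg)
nonzero_rows = np.any(images[0].matrix != 0, axis=1).sum()
print(f"\nencoded {len(images)} topographic images (81x128); "
      f"{nonzero_rows} electrode rows carry signal, "
      f"{81 - nonzero_rows} rows are zero padding")
print("channel -> slot map (1-based):", images[0].channel_index_map)
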