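"""Two-tier physiological-signal preprocessing.

Basic tier (generic signal conditioning):

* EEG: common-average referencing, 4–45 Hz band-pass (zero-phase FIR, 60 dB
  stopband), 2 s edge trim.
* ECG: polyphase down-sampling 256 → 128 Hz, 60 Hz low-pass, 2 s edge trim.
* GSR: 60 Hz low-pass (already at 128 Hz).

Specialized tier (specific to emotion elicitation): segmentation into 1-s /
128-sample windows, subtraction of the mean 1-s baseline segment recorded
without stimulus, and per-segment-channel z-score normalization.

All operations accept and return :class:`~emochart.containers.Recording` or
:class:`~emochart.containers.SegmentSet` and never mutate their inputs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import TARGET_FS, Recording, SegmentSet

__all__ = [
    "common_average_reference",
    "bandpass_eeg",
    "trim_edges",
    "preprocess_ecg",
    "lowpass",
    "segment",
    "mean_baseline",
    "remove_baseline",
    "zscore",
    "preprocess_trial_recording",
]


def common_average_reference(rec: Recording) -> Recording:
    """Re-reference EEG by subtracting the instantaneous mean of all channels.

    Removes channel biases introduced by the online reference. After CAR the
    per-sample sum over channels is exactly zero, and the operation is a
    projection (applying it twice equals applying it once).
    """
    if rec.modality != "EEG":
        raise ValueError("common average referencing applies to EEG recordings")
    if rec.n_channels != 14:
        raise ValueError(f"expected 14 EEG channels, got {rec.n_channels}")
    mean = rec.data.mean(axis=0, keepdims=True)
    return rec.with_data(rec.data - mean)


# Band-pass design: zero-phase FIR (Kaiser window) sized for >=60 dB stopband
# with a 2 Hz transition at fs=128 Hz; filtfilt doubles the attenuation.
_BP_TRANSITION_HZ = 2.0
_BP_ATTEN_DB = 60.0


def _filtfilt(taps: np.ndarray, data: np.ndarray) -> np.ndarray:
    # pad length capped so short (few-second) baselines remain filterable
    padlen = min(3 * (len(taps) - 1), data.shape[-1] - 1)
    return sps.filtfilt(taps, [1.0], data, axis=-1, padlen=padlen)


def _bandpass_taps(lo: float, hi: float, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    numtaps, beta = sps.kaiserord(_BP_ATTEN_DB, _BP_TRANSITION_HZ / nyq)
    numtaps |= 1  # odd length keeps a symmetric type-I FIR
    return sps.firwin(numtaps, [lo, hi], window=("kaiser", beta), fs=fs, pass_zero=False)


def bandpass_eeg(rec: Recording, lo: float = 4.0, hi: float = 45.0) -> Recording:
    """Band-pass each EEG channel (default 4–45 Hz), zero phase.

    Attenuates slow drift/ocular artifacts below 4 Hz and mains-range noise
    around 50 Hz by at least 60 dB in the stopbands.
    """
    if lo >= hi:
        raise ValueError(f"passband must satisfy lo < hi, got ({lo}, {hi})")
    if hi >= rec.fs / 2:
        raise ValueError(f"upper edge {hi} Hz requires fs > {2 * hi} Hz, got {rec.fs}")
    taps = _bandpass_taps(lo, hi, rec.fs)
    return rec.with_data(_filtfilt(taps, rec.data))


def trim_edges(rec: Recording, trim_s: float = 2.0) -> Recording:
    """Drop ``trim_s`` seconds from each end (filter edge transients)."""
    if trim_s == 0:
        return rec.with_data(rec.data.copy())
    n_trim = int(round(trim_s * rec.fs))
    if rec.n_samples <= 2 * n_trim:
        raise ValueError(
            f"recording of {rec.duration:.1f} s too short to trim {trim_s} s per edge"
        )
    return rec.with_data(rec.data[:, n_trim : rec.n_samples - n_trim])


def lowpass(rec: Recording, cutoff: float = 60.0, transition: float = 6.0) -> Recording:
    """Zero-phase FIR low-pass; default 60 Hz cutoff for peripheral signals."""
    nyq = rec.fs / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must lie below Nyquist {nyq} Hz")
    numtaps, beta = sps.kaiserord(_BP_ATTEN_DB, min(transition, 2 * (nyq - cutoff)) / nyq)
    numtaps |= 1
    taps = sps.firwin(numtaps, cutoff, window=("kaiser", beta), fs=rec.fs)
    return rec.with_data(_filtfilt(taps, rec.data))


def preprocess_ecg(rec: Recording, trim_s: float = 2.0) -> Recording:
    """Basic ECG conditioning: down-sample to 128 Hz, 60 Hz low-pass, edge trim.

    Raw 256 Hz input is decimated by 2 with a polyphase anti-alias filter;
    input already at 128 Hz skips the rate change and is low-passed only.
    """
    if rec.fs == 2 * TARGET_FS:
        data = sps.resample_poly(rec.data, up=1, down=2, axis=1)
        rec = rec.with_data(data, fs=TARGET_FS)
    elif rec.fs != TARGET_FS:
        raise ValueError(f"unsupported ECG sampling rate {rec.fs} Hz")
    rec = lowpass(rec, 60.0)
    if trim_s:
        rec = trim_edges(rec, trim_s)
    return rec


def segment(rec: Recording, seconds: float = 1.0, label: int = -1) -> SegmentSet:
    """Cut a recording into contiguous non-overlapping 1-s / 128-sample windows.

    Windows are half-open ``[t, t + seconds)``; a trailing partial window is
    discarded. Provenance records (subject, trial, segment-index) per window.
    """
    if rec.fs != TARGET_FS:
        raise ValueError(f"segmentation expects fs={TARGET_FS} Hz, got {rec.fs}")
    win = int(round(seconds * rec.fs))
    n_seg = rec.n_samples // win
    if n_seg == 0:
        raise ValueError("recording shorter than one window")
    data = rec.data[:, : n_seg * win].reshape(rec.n_channels, n_seg, win)
    data = np.ascontiguousarray(data.transpose(1, 0, 2))
    prov = pd.DataFrame(
        {
            "subject": rec.subject_id,
            "trial": rec.trial_id,
            "segment": np.arange(n_seg),
        }
    )
    return SegmentSet(data, np.full(n_seg, label), prov, rec.modality)


def mean_baseline(baseline: Recording) -> np.ndarray:
    """Per-channel mean 1-s segment of a no-stimulus baseline recording.

    The baseline is cut into 1-s segments (trailing partial second discarded)
    and averaged across segments, giving a (channels, 128) template of neutral
    activity.
    """
    if baseline.fs != TARGET_FS:
        raise ValueError(f"baseline must be at {TARGET_FS} Hz, got {baseline.fs}")
    win = TARGET_FS
    n_seg = baseline.n_samples // win
    if n_seg == 0:
        raise ValueError("baseline shorter than 1 s")
    segs = baseline.data[:, : n_seg * win].reshape(baseline.n_channels, n_seg, win)
    return segs.mean(axis=1)


def remove_baseline(seg_set: SegmentSet, mean_bl: np.ndarray) -> SegmentSet:
    """Subtract the mean baseline segment from every 1-s stimulus segment."""
    mean_bl = np.asarray(mean_bl)
    if mean_bl.shape != (seg_set.n_channels, TARGET_FS):
        raise ValueError(
            f"mean baseline shape {mean_bl.shape} does not match segments "
            f"({seg_set.n_channels}, {TARGET_FS})"
        )
    return SegmentSet(
        seg_set.data - mean_bl[None],
        seg_set.labels,
        seg_set.provenance,
        seg_set.modality,
        normalized=False,
    )


def zscore(seg_set: SegmentSet) -> SegmentSet:
    """Standardize each segment-channel to zero mean and unit variance.

    A constant (zero-variance) segment-channel is mapped to all zeros with a
    warning rather than propagating NaNs.
    """
    mu = seg_set.data.mean(axis=-1, keepdims=True)
    sd = seg_set.data.std(axis=-1, keepdims=True)
    flat = sd == 0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} constant segment-channel(s) mapped to zeros",
            RuntimeWarning,
            stacklevel=2,
        )
    out = (seg_set.data - mu) / np.where(flat, 1.0, sd)
    out = np.where(flat, 0.0, out)
    return SegmentSet(
        out, seg_set.labels, seg_set.provenance, seg_set.modality, normalized=True
    )


def preprocess_trial_recording(
    stimulus: Recording,
    baseline: Recording,
    trim_s: float = 2.0,
    label: int = -1,
) -> SegmentSet:
    """Full pipeline for one trial of one modality.

    EEG: CAR → band-pass → trim → segment → baseline removal → z-score.
    ECG: down-sample → low-pass → trim → segment → baseline removal → z-score.
    GSR: low-pass → trim → segment → baseline removal → z-score.
    The baseline recording goes through the same basic tier before its 1-s
    mean template is computed.
    """

    def basic(rec: Recording) -> Recording:
        if rec.modality == "EEG":
            rec = common_average_reference(rec)
            rec = bandpass_eeg(rec)
            if trim_s:
                rec = trim_edges(rec, trim_s)
            return rec
        if rec.modality in ("ECG_L", "ECG_R"):
            return preprocess_ecg(rec, trim_s)
        rec = lowpass(rec, 60.0)
        return trim_edges(rec, trim_s) if trim_s else rec

    segs = segment(basic(stimulus), label=label)
    bl = mean_baseline(basic(baseline))
    return zscore(remove_baseline(segs, bl))
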