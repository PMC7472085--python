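"""Synthetic multi-modal affective datasets.

Generates DREAMER-shaped (23 subjects × 18 trials, 64 s raw trials, 61 s
baselines, ECG at 256 Hz, ratings on 1–5) and AMIGOS-shaped (33 subjects × 16
trials, variable full-length trials, 5 s baselines, ratings on 1–9) recordings
whose four quadrant classes differ by their relative band power — the
statistical structure the downstream classifiers exploit. Signals are sums of
band-limited random-phase sinusoids plus pink and white noise; ECG channels
additionally carry a periodic synthetic QRS-like spike train, and all channels
of a modality share a common-mode drift plus offset so that re-referencing and
baseline removal have observable effects.

This is deliberately *not* physiologically realistic morphology; it provides
controllable class-conditional spectra so every pipeline stage is testable
without the real datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import Recording
from .labels import QUADRANTS, RatingRecord, midpoint, quadrant, quadrant_code

__all__ = [
    "BANDS",
    "DatasetShape",
    "ClassSignature",
    "SyntheticTrial",
    "dreamer_shape",
    "amigos_shape",
    "fixture_shape",
    "default_signatures",
    "high_separability_signatures",
    "neutral_signature",
    "draw_trial_durations",
    "iter_dataset",
    "make_dataset",
    "spectral_separability",
    "save_dataset",
    "load_dataset",
]

#: EEG frequency bands (Hz) used for class signatures, inside the 4–45 Hz passband.
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}


@dataclass(frozen=True)
class DatasetShape:
    """Geometry of a dataset: counts, durations, rates and rating scale."""

    name: str
    n_subjects: int
    n_trials: int
    trial_seconds: tuple[int, ...]  # length n_trials or n_subjects*n_trials
    baseline_seconds: int
    rating_scale: tuple[float, float]
    fs_eeg: int = 128
    fs_ecg_raw: int = 256
    eeg_channels: int = 14
    ecg_channels: int = 2
    gsr_channels: int = 0
    edge_trim_seconds: float = 2.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("shape needs at least one subject and one trial")
        n = self.n_subjects * self.n_trials
        if len(self.trial_seconds) not in (self.n_trials, n):
            raise ValueError(
                "trial_seconds must list one duration per trial, or per subject×trial"
            )
        if min(self.trial_seconds) <= 0 or self.baseline_seconds <= 0:
            raise ValueError("durations must be positive")

    @property
    def n_trials_total(self) -> int:
        return self.n_subjects * self.n_trials

    def trial_duration(self, subject: int, trial: int) -> int:
        if len(self.trial_seconds) == self.n_trials:
            return self.trial_seconds[trial]
        return self.trial_seconds[subject * self.n_trials + trial]

    def modalities(self) -> tuple[str, ...]:
        mods = ["EEG", "ECG_L", "ECG_R"][: 1 + self.ecg_channels]
        if self.gsr_channels:
            mods.append("GSR")
        return tuple(mods)


@dataclass(frozen=True)
class ClassSignature:
    """Spectral fingerprint of one quadrant class.

    ``band_powers`` holds the relative power per frequency band; ``noise_sd``
    scales additive white noise (pink noise is half that); ``baseline_offset``
    is a DC offset shared by all channels.
    """

    quadrant: str
    band_powers: Mapping[str, float]
    noise_sd: float = 0.5
    baseline_offset: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.band_powers.values()):
            raise ValueError("band powers must be nonnegative")

    def content_key(self) -> str:
        """Stable textual identity used to derive per-signature random seeds.

        Band powers are normalized to unit sum here, so uniformly rescaled
        signatures share the same draws — spectral distances are then exactly
        scale-invariant, not merely approximately.
        """
        total = sum(self.band_powers.values()) or 1.0
        items = sorted((k, round(float(v) / total, 12)) for k, v in self.band_powers.items())
        return json.dumps(
            [self.quadrant, items, float(self.noise_sd), float(self.baseline_offset)]
        )


@dataclass
class SyntheticTrial:
    subject_id: int
    trial_id: int
    quadrant: str
    valence: float
    arousal: float
    signals: dict[str, Recording]
    baselines: dict[str, Recording]


# --- canonical shapes -------------------------------------------------------


def dreamer_shape() -> DatasetShape:
    """23 subjects × 18 trials; last 64 s of each stimulus kept, 61 s baseline."""
    return DatasetShape(
        name="dreamer-like",
        n_subjects=23,
        n_trials=18,
        trial_seconds=(64,) * 18,
        baseline_seconds=61,
        rating_scale=(1.0, 5.0),
        fs_ecg_raw=256,
        gsr_channels=0,
        edge_trim_seconds=2.0,
    )


def amigos_shape(total_segments: int = 45474, seed: int = 0) -> DatasetShape:
    """33 subjects × 16 trials, variable full-length trials, 5 s baselines.

    Trial durations (in whole seconds, 51–150 s) are drawn so their total is
    exactly ``total_segments`` (default 45,474 one-second segments over 528
    trials, i.e. a mean of 86.125), making the reference dataset totals
    reproducible. ECG ships already down-sampled to 128 Hz and no edge trim is
    applied, mirroring use of the curators' basic-preprocessed release.
    """
    durations = draw_trial_durations(33 * 16, total_segments, 51, 150, seed)
    return DatasetShape(
        name="amigos-like",
        n_subjects=33,
        n_trials=16,
        trial_seconds=tuple(durations),
        baseline_seconds=5,
        rating_scale=(1.0, 9.0),
        fs_ecg_raw=128,
        gsr_channels=1,
        edge_trim_seconds=0.0,
    )


def fixture_shape(n_subjects: int = 10, n_trials: int = 16, trial_seconds: int = 29) -> DatasetShape:
    """Small benchmark shape: 10×16 trials of 29 s (→ 25 segments after trim).

    Yields 10·16·25 = 4000 segments per modality with exactly balanced classes
    (16 trials divide evenly by 4), used as the learnability benchmark.
    """
    return DatasetShape(
        name="fixture",
        n_subjects=n_subjects,
        n_trials=n_trials,
        trial_seconds=(trial_seconds,) * n_trials,
        baseline_seconds=7,
        rating_scale=(1.0, 9.0),
        fs_ecg_raw=256,
        gsr_channels=1,
        edge_trim_seconds=2.0,
    )


def draw_trial_durations(
    n: int, total: int, lo: int, hi: int, seed: int = 0
) -> np.ndarray:
    """Integer durations in [lo, hi] summing exactly to ``total`` (deterministic)."""
    if not lo * n <= total <= hi * n:
        raise ValueError(f"total {total} unreachable with {n} trials in [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    d = rng.integers(lo, hi + 1, size=n)
    diff = total - int(d.sum())
    step = 1 if diff > 0 else -1
    while diff != 0:
        i = rng.integers(0, n)
        if lo <= d[i] + step <= hi:
            d[i] += step
            diff -= step
    return d


# --- class signatures -------------------------------------------------------

_PROFILES = {
    "HVHA": {"theta": 0.1, "alpha": 0.2, "beta": 0.6, "gamma": 1.0},
    "HVLA": {"theta": 0.3, "alpha": 1.0, "beta": 0.3, "gamma": 0.1},
    "LVHA": {"theta": 0.2, "alpha": 0.3, "beta": 1.0, "gamma": 0.3},
    "LVLA": {"theta": 1.0, "alpha": 0.4, "beta": 0.2, "gamma": 0.1},
}


def default_signatures(noise_sd: float = 0.5) -> dict[str, ClassSignature]:
    """One spectral signature per quadrant, pairwise distinct by construction."""
    return {
        q: ClassSignature(q, _PROFILES[q], noise_sd=noise_sd, baseline_offset=0.0)
        for q in QUADRANTS
    }


_DOMINANT = {"HVHA": "gamma", "HVLA": "alpha", "LVHA": "beta", "LVLA": "theta"}


def high_separability_signatures() -> dict[str, ClassSignature]:
    """Maximal inter-class spectral variability for learnability benchmarks.

    Each class concentrates its power in one dominant band (40:1 contrast
    against the other bands) with low additive noise, so the four classes are
    spectrally near-disjoint. Calibration target: an independent spectral
    classifier (log-Welch features + multinomial logistic regression) must
    separate the classes nearly perfectly on a single channel, so that a
    network benchmark on this fixture measures the network, not the data.
    """
    return {
        q: ClassSignature(
            q, {b: (4.0 if b == _DOMINANT[q] else 0.1) for b in BANDS},
            noise_sd=0.25, baseline_offset=0.0,
        )
        for q in QUADRANTS
    }


def neutral_signature(noise_sd: float = 0.5, offset: float = 2.0) -> ClassSignature:
    """Class-free signature for baseline (no-stimulus) recordings.

    Flat band profile and a nonzero DC offset, so baseline removal has an
    observable effect on the peripheral channels.
    """
    flat = {b: 0.4 for b in BANDS}
    return ClassSignature("HVHA", flat, noise_sd=noise_sd, baseline_offset=offset)


# --- signal synthesis -------------------------------------------------------


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    pink = np.fft.irfft(spec / np.sqrt(f), n=n)
    sd = pink.std()
    return pink / sd if sd else pink


def _band_mixture(
    rng: np.random.Generator,
    n: int,
    fs: float,
    band_powers: Mapping[str, float],
    n_components: int = 3,
) -> np.ndarray:
    """Sum of random-phase sinusoids per band, RMS per band = sqrt(power)."""
    t = np.arange(n) / fs
    x = np.zeros(n)
    for band, power in band_powers.items():
        if power <= 0:
            continue
        f_lo, f_hi = BANDS[band]
        freqs = rng.uniform(f_lo, f_hi, size=n_components)
        phases = rng.uniform(0, 2 * np.pi, size=n_components)
        amp = np.sqrt(2.0 * power / n_components)
        for f0, ph in zip(freqs, phases):
            x += amp * np.sin(2 * np.pi * f0 * t + ph)
    return x


def _qrs_train(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Periodic Gaussian-derivative spikes at ~1.1 Hz with beat jitter."""
    x = np.zeros(n)
    width = 0.02 * fs
    t = 0.0
    while t < n:
        center = int(t)
        lo, hi = max(0, center - int(4 * width)), min(n, center + int(4 * width))
        if hi > lo:
            u = (np.arange(lo, hi) - center) / width
            x[lo:hi] += -3.0 * u * np.exp(-0.5 * u**2)
        t += fs * (1.0 / 1.1) * rng.uniform(0.92, 1.08)
    return x


def _channels(
    rng: np.random.Generator,
    n_channels: int,
    seconds: float,
    fs: float,
    sig: ClassSignature,
    qrs: bool = False,
) -> np.ndarray:
    n = int(round(seconds * fs))
    # common-mode term shared by all channels (removed by CAR for EEG)
    t = np.arange(n) / fs
    common = sig.baseline_offset + 1.5 * np.sin(
        2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi)
    )
    out = np.empty((n_channels, n))
    for c in range(n_channels):
        x = _band_mixture(rng, n, fs, sig.band_powers)
        x += 0.5 * sig.noise_sd * _pink_noise(rng, n)
        x += sig.noise_sd * rng.standard_normal(n)
        if qrs:
            x += _qrs_train(rng, n, fs)
        out[c] = rng.uniform(0.9, 1.1) * x + common
    return out


def _subject_quadrants(subject: int, n_trials: int, rng: np.random.Generator) -> list[str]:
    """Balanced class assignment: each subject cycles the four quadrants, shuffled."""
    codes = (np.arange(n_trials) + subject) % 4
    rng.shuffle(codes)
    return [QUADRANTS[c] for c in codes]


def _draw_rating(
    rng: np.random.Generator, scale: tuple[float, float], high: bool
) -> float:
    lo, hi = scale
    mid = midpoint(scale)
    margin = 0.05 * (hi - lo)
    if high:
        return float(rng.uniform(mid + margin, hi))
    return float(rng.uniform(lo, mid - margin))


def iter_dataset(
    shape: DatasetShape,
    signatures: Mapping[str, ClassSignature] | None = None,
    seed: int = 0,
    baseline_sig: ClassSignature | None = None,
) -> Iterator[SyntheticTrial]:
    """Lazily generate all subject × trial recordings (deterministic per seed)."""
    signatures = dict(signatures or default_signatures())
    missing = set(QUADRANTS) - set(signatures)
    if missing:
        raise ValueError(f"signatures missing quadrants: {sorted(missing)}")
    baseline_sig = baseline_sig or neutral_signature()
    root = np.random.SeedSequence(seed)
    children = root.spawn(shape.n_trials_total + shape.n_subjects)
    label_rngs = [
        np.random.default_rng(children[shape.n_trials_total + s])
        for s in range(shape.n_subjects)
    ]
    order = [
        _subject_quadrants(s, shape.n_trials, label_rngs[s])
        for s in range(shape.n_subjects)
    ]
    for s in range(shape.n_subjects):
        for k in range(shape.n_trials):
            rng = np.random.default_rng(children[s * shape.n_trials + k])
            q = order[s][k]
            sig = signatures[q]
            valence = _draw_rating(rng, shape.rating_scale, q.startswith("HV"))
            arousal = _draw_rating(rng, shape.rating_scale, q[2] == "H")
            dur = shape.trial_duration(s, k)
            signals: dict[str, Recording] = {}
            baselines: dict[str, Recording] = {}
            for mod in shape.modalities():
                if mod == "EEG":
                    n_ch, fs = shape.eeg_channels, shape.fs_eeg
                elif mod in ("ECG_L", "ECG_R"):
                    n_ch, fs = 1, shape.fs_ecg_raw
                else:
                    n_ch, fs = 1, shape.fs_eeg
                qrs = mod.startswith("ECG")
                signals[mod] = Recording(
                    _channels(rng, n_ch, dur, fs, sig, qrs=qrs),
                    fs, mod, s, k, role="stimulus",
                )
                baselines[mod] = Recording(
                    _channels(rng, n_ch, shape.baseline_seconds, fs, baseline_sig, qrs=qrs),
                    fs, mod, s, k, role="baseline",
                )
            yield SyntheticTrial(s, k, q, valence, arousal, signals, baselines)


def make_dataset(
    shape: DatasetShape,
    signatures: Mapping[str, ClassSignature] | None = None,
    seed: int = 0,
    baseline_sig: ClassSignature | None = None,
) -> list[SyntheticTrial]:
    """Materialize :func:`iter_dataset` (use the iterator for large shapes)."""
    return list(iter_dataset(shape, signatures, seed, baseline_sig))


# --- spectral separability --------------------------------------------------


def _signature_mean_spectrum(
    sig: ClassSignature, n_draws: int, fs: float, seconds: float, seed: int
) -> np.ndarray:
    # seed derived from signature content: identical signatures → identical draws
    content = np.frombuffer(sig.content_key().encode(), dtype=np.uint8)
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, *content.astype(np.uint32)])
    )
    n = int(seconds * fs)
    acc = None
    for _ in range(n_draws):
        x = _band_mixture(rng, n, fs, sig.band_powers)
        x += 0.5 * sig.noise_sd * _pink_noise(rng, n)
        x += sig.noise_sd * rng.standard_normal(n)
        _, p = sps.welch(x, fs=fs, nperseg=min(256, n))
        acc = p if acc is None else acc + p
    mean = acc / n_draws
    total = mean.sum()
    return mean / total if total else mean


def spectral_separability(
    signatures: Sequence[ClassSignature] | Mapping[str, ClassSignature],
    n_draws: int = 100,
    seed: int = 0,
    fs: float = 128.0,
    seconds: float = 4.0,
) -> pd.DataFrame:
    """Pairwise L2 distance between normalized mean Welch spectra of signatures.

    Each signature's mean spectrum is estimated from ``n_draws`` independent
    realizations (seeded from the signature's content, so identical signatures
    give exactly zero distance) and normalized to unit total power, making the
    distance invariant to uniform power rescaling.
    """
    if isinstance(signatures, Mapping):
        names = list(signatures)
        sigs = [signatures[k] for k in names]
    else:
        sigs = list(signatures)
        names = [f"{s.quadrant}#{i}" for i, s in enumerate(sigs)]
    if len(sigs) < 2:
        raise ValueError("need at least 2 signatures")
    if n_draws < 2:
        raise ValueError("need n_draws >= 2")
    spectra = [
        _signature_mean_spectrum(s, n_draws, fs, seconds, seed) for s in sigs
    ]
    k = len(sigs)
    table = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = float(np.linalg.norm(spectra[i] - spectra[j]))
            table[i, j] = table[j, i] = d
    return pd.DataFrame(table, index=names, columns=names)


# --- on-disk layout ---------------------------------------------------------


def save_dataset(trials: Iterator[SyntheticTrial] | list[SyntheticTrial], root: Path) -> pd.DataFrame:
    """Write ``<root>/s<subject>/t<trial>/<modality>.npy`` plus manifest.csv."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in trials:
        d = root / f"s{tr.subject_id:02d}" / f"t{tr.trial_id:02d}"
        d.mkdir(parents=True, exist_ok=True)
        for mod, rec in tr.signals.items():
            np.save(d / f"{mod}.npy", rec.data)
            np.save(d / f"{mod}_baseline.npy", tr.baselines[mod].data)
        rows.append(
            {
                "subject": tr.subject_id,
                "trial": tr.trial_id,
                "quadrant": tr.quadrant,
                "valence": tr.valence,
                "arousal": tr.arousal,
                "modalities": "|".join(tr.signals),
                "fs": "|".join(str(tr.signals[m].fs) for m in tr.signals),
                "duration_s": tr.signals[next(iter(tr.signals))].duration,
                "baseline_s": tr.baselines[next(iter(tr.baselines))].duration,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(root / "manifest.csv", index=False)
    return manifest


def load_dataset(root: Path) -> list[SyntheticTrial]:
    """Read back a directory written by :func:`save_dataset`."""
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv")
    trials = []
    for _, row in manifest.iterrows():
        s, k = int(row.subject), int(row.trial)
        d = root / f"s{s:02d}" / f"t{k:02d}"
        mods = str(row.modalities).split("|")
        rates = [float(x) for x in str(row.fs).split("|")]
        signals, baselines = {}, {}
        for mod, fs in zip(mods, rates):
            signals[mod] = Recording(np.load(d / f"{mod}.npy"), fs, mod, s, k)
            baselines[mod] = Recording(
                np.load(d / f"{mod}_baseline.npy"), fs, mod, s, k, role="baseline"
            )
        trials.append(
            SyntheticTrial(
                s, k, str(row.quadrant), float(row.valence), float(row.arousal),
                signals, baselines,
            )
        )
    return trials


def export_mat_layout(trials: list[SyntheticTrial], path: Path) -> Path:
    """Write one MAT-file per subject mimicking the curated releases' layout.

    Each file holds ``EEG_stimuli``/``EEG_baseline`` cell-style arrays (one
    entry per trial), the ECG/GSR equivalents present in the data, and a
    ``ratings`` (n_trials × 2) valence/arousal matrix — enough structure to
    exercise MAT-file adapter code without the real accession.
    """
    from scipy.io import savemat

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    by_subject: dict[int, list[SyntheticTrial]] = {}
    for tr in trials:
        by_subject.setdefault(tr.subject_id, []).append(tr)
    for s, trs in by_subject.items():
        trs = sorted(trs, key=lambda t: t.trial_id)
        mdict: dict = {
            "ratings": np.array([[t.valence, t.arousal] for t in trs]),
        }
        for mod in trs[0].signals:
            mdict[f"{mod}_stimuli"] = np.empty(len(trs), dtype=object)
            mdict[f"{mod}_baseline"] = np.empty(len(trs), dtype=object)
            for i, t in enumerate(trs):
                mdict[f"{mod}_stimuli"][i] = t.signals[mod].data
                mdict[f"{mod}_baseline"][i] = t.baselines[mod].data
        savemat(path / f"subject_{s:02d}.mat", mdict)
    return path


def trial_label(trial: SyntheticTrial, scale: tuple[float, float]) -> int:
    """Quadrant code recomputed from the trial's ratings (consistency contract)."""
    return quadrant_code(quadrant(RatingRecord(trial.valence, trial.arousal, scale)))
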