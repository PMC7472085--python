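# Methods

## Scope and design

`emochart` implements a complete emotion-charting pipeline for physiological
signals — preprocessing, EEG topographic image encoding, two neural
classifiers, evaluation protocol and decision-level fusion — together with a
synthetic-data generator that stands in for the gated DREAMER/AMIGOS-style
datasets. The package's claims are therefore about the *pipeline* (its
transformations, counts, invariants and learnability on controlled data),
not about accuracy on real recordings.

## Synthetic data generator

Each trial draws a quadrant class (balanced per subject), a quadrant-
consistent (valence, arousal) rating, and per-modality recordings:

- **Signal model** — a sum of band-limited random-phase sinusoids (3
  components per band; bands θ 4–8, α 8–13, β 13–30, γ 30–45 Hz) whose
  per-band RMS² follows the class signature's `band_powers`, plus pink noise
  (sd = noise_sd/2), white noise (sd = noise_sd), and a common-mode term
  (DC offset + 0.3 Hz drift) shared by all channels of a modality so that
  re-referencing has an observable effect. ECG channels add a ~1.1 Hz
  Gaussian-derivative spike train with ±8 % beat jitter so the
  down-sampling/low-pass stages act on recognizably pulse-like structure.
- **Baselines** are generated from a class-free neutral signature (flat band
  profile, nonzero DC offset) so baseline removal has an observable effect.
- **Geometry** — the DREAMER-like shape is 23 subjects × 18 trials of 64 s
  (EEG 128 Hz, ECG raw 256 Hz, 61 s baselines, ratings 1–5, 2 s edge trim);
  the AMIGOS-like shape is 33 subjects × 16 trials of 51–150 s (integer
  durations drawn to total exactly 45,474 s over 528 trials, i.e. a mean of
  86.125 one-second segments per trial), 5 s baselines, ratings 1–9, no edge
  trim (its real counterpart ships basic-preprocessed, full-length trials).
- **Determinism** — one `SeedSequence` per dataset spawns one child per
  trial; a fixed seed reproduces every sample bitwise, including after a
  save/load round trip.

**Class signatures.** The default set gives each class a distinct multi-band
profile (e.g. γ-dominant for HVHA, α-dominant for HVLA) with noise_sd 0.5 —
deliberately imperfect classes. The *high-separability* set used by the
learnability benchmark concentrates each class's power in one band at 40:1
contrast with noise_sd 0.25. That set is calibrated against an independent
oracle — multinomial logistic regression on log-Welch spectra must separate
the four classes at ≳97 % on a *single* channel — so that the network
benchmark measures the classifier, not the data. (With the default
multi-band signatures the same oracle reaches only ~77–82 % on one ECG
channel: the per-trial random component frequencies and the QRS/noise
nuisance give substantial class overlap, which is the realistic, harder
condition.)

**Spectral separability** between signatures is the L2 distance between
unit-normalized mean Welch spectra over `n_draws` realizations. Draw seeds
derive from a content hash of the signature (with band powers normalized to
unit sum), which makes two identical — or uniformly rescaled — signatures
produce exactly zero distance. The metric itself is this package's choice;
"inter-class spectral variability" has no canonical quantitative definition
in this literature.

## Preprocessing

Stage order for EEG: common-average reference → 4–45 Hz band-pass → edge
trim → 1-s segmentation → baseline removal → per-segment-channel z-score.
ECG: polyphase down-sample 256→128 Hz → 60 Hz low-pass → trim → segment →
baseline → z-score; GSR the same minus the rate change.

Numerical choices:

- **Filters** are zero-phase FIR (Kaiser window sized for 60 dB stopband
  attenuation with a 2 Hz transition for the band-pass, 6 Hz for the
  low-pass), applied with `filtfilt` (pad length capped at signal length − 1
  so few-second baselines remain filterable). Forward–backward filtering
  doubles the design attenuation; tests assert a conservative −30 dB at 2
  and 55 Hz and ±1 dB at 10 Hz.
- **Down-sampling** uses `resample_poly` with its built-in anti-alias
  filter *before* the 60 Hz low-pass. The nominal stage order
  (down-sample, then low-pass) is preserved in the API; the polyphase
  anti-alias step exists to prevent aliasing, not as a separate stage.
- **Baselines** pass through the same basic tier as stimuli before their
  1-s mean template is computed (61 s DREAMER-like baselines trim to 57
  usable segments; AMIGOS-like use all 5).
- **Segmentation** uses half-open windows [t, t+1 s), 0-based indices
  internally; trailing partial seconds are discarded.
- **Z-scoring** is per segment-channel (mean 0, sd 1 within 1e-9); a
  zero-variance segment-channel maps to zeros with a `RuntimeWarning`
  rather than producing NaNs.
- CAR and the band-pass are both linear and in fact commute (one acts
  across channels, the other along time); the documented order is pinned by
  a regression test, and the non-commuting stages (z-score vs baseline
  removal) are asserted to be order-sensitive.

## Topographic encoding

The 14 channels are placed at fixed rows (4, 13, 19, 21, 29, 31, 37, 39, 47,
49, 55, 57, 67, 76 — 1-based) of an 81×128 matrix, other rows zero; the
inverse mapping recovers the segment bit-exactly. The classifier consumes
the real-valued matrix; PNG export (8-bit grayscale) uses a fixed quantizer
— clip z-scored values to ±4, map linearly to 0–255, zero → mid-gray 128 —
so intensities are comparable across images (per-image min–max scaling would
destroy amplitude information). No scalp interpolation is performed: the
encoding is deliberately a sparse 1-D topological layout, not an azimuthal
projection.

## Networks and training

Both architectures exist twice: as a declarative layer table with
closed-form learnable counts (conv: k_h·k_w·c_in·f + f; dense: i·o + o;
LSTM: 4H(I+H) + 4H; batch-norm: 2c) and as a runtime model on the package's
numpy NN core; the audit asserts integer equality between the two.

- Image net: three 3×3 same-padded conv blocks (8/16/16 filters) with
  batch-norm and ReLU, 2×2/stride-2 ceil-mode max-pooling after the first
  two (81×128 → 41×64 → 21×32), one dense layer to 4 logits.
- Sequence net: two 3-tap same-padded 1-D convs (16/32 filters) with ReLU
  and size-2/stride-1 pooling (length stays 128), flatten to 4096, LSTM with
  128 hidden units (gate order input/forget/candidate/output, sigmoid gates,
  tanh state), dense 256→128→4 with dropout 0.5 after each — including after
  the final logits during training, disabled at inference. Each sample is a
  length-1 sequence of one 4096-feature step (classification needs only one
  second of signal); the LSTM also supports multi-step sequences, so a
  trial's segments can be presented as a longer sequence experimentally.
  With length-1 input the recurrent weights receive zero gradient but are
  counted as learnables, matching the reference totals. No batch-norm exists
  in the sequence net.

Training: Adam with β₁ = 0.9, β₂ = 0.99 (the "squared-gradient decay
factor"), learning rate 10⁻³, batch 240, segment-level 70/30 random split
(train size = round(0.7 n)); a stratified and a subject-level split are
available but the protocol default is the plain segment-level split, which
mixes subjects across train and test — an acknowledged optimistic protocol.
Parameters are float32 at runtime (float64 in the gradient tests); all
randomness flows through explicit numpy `Generator`s, so a fixed seed
reproduces partitions and loss curves exactly.

The NN core itself (conv1d/conv2d as shifted channel-mixing GEMMs,
batch-norm, pooling, LSTM with full BPTT, dropout, Adam, softmax
cross-entropy) is verified layer-by-layer against central finite
differences at 1e-7 tolerance, and the 2-D convolution additionally against
`scipy.signal.correlate2d`.

## Evaluation and fusion

Confusion matrices are 4×4 counts (output class × target class) with
per-cell percent-of-test-set, per-row precision, per-column recall and
overall accuracy in the corner. The best/worst spectral report selects, per
class, the test segment with the highest and lowest correct-class softmax
probability and attaches Welch spectra — the raw material for inspecting
*why* a modality performs well or badly.

Majority-vote fusion operates per segment over aligned modality votes; ties
(unavoidable for 2 or 4 voters) are broken by the largest summed softmax
probability among tied classes, then by fixed class order HVHA < HVLA <
LVHA < LVLA — the only order-sensitive element, making fused output
otherwise invariant to modality column order. `fuse_report` enumerates all
modality subsets of size ≥ 2 (11 combinations for 4 modalities). Whether
hard labels or probabilities should vote is unspecified in this pipeline
family; hard labels with confidence tie-breaking was chosen because both
are available and the rule is deterministic.

## Benchmark sizes and limitations

The learnability benchmark uses 10 subjects × 16 trials × 25 usable seconds
= 4000 segments (exactly balanced classes), 10 epochs — sized so the whole
suite trains both networks on one CPU in minutes while leaving clear room
between the pass bars (sequence net ≥ 90 %, image net ≥ 85 %, shuffled-label
control 25 ± 3 %) and chance.

What passing these tests shows: the implementation learns class-conditional
spectral structure through the full pipeline, the counts and shapes match
the specified tables exactly, and every documented invariant holds. What it
does not show: performance on real EEG/ECG/GSR, which has nonstationary
artifacts, inter-subject variability and far weaker class signal than any
synthetic signature here; the published headline accuracies on the real
datasets are out of scope by construction. Other known limitations: no
ICA/artifact-subspace cleaning, no heartbeat detection, no feature-level
fusion, no subject-independent protocol by default, and ratings exactly at
the scale midpoint are assigned to "low" by convention.
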