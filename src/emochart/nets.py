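"""The two classifier architectures and their learnable-parameter audit.

``eeg_2dcnn`` consumes 81 × 128 topographic EEG images: three blocks of
3×3 same-padded convolution (8, 16, 16 filters) + batch-norm + ReLU, the first
two followed by 2×2/stride-2 max pooling (81×128 → 41×64 → 21×32), then a
single fully-connected layer of 4 units and softmax.

``seq_1dcnn_lstm`` consumes 1 × 128 one-second sequences (ECG or GSR): two
3×1 same-padded 1-D convolutions (16, 32 filters) each with ReLU and
size-2/stride-1 max pooling, flattened to a 4096-vector, an LSTM with 128
hidden units, then dense layers of 256, 128 and 4 units, each followed by
dropout 0.5, and softmax.

Each architecture is described twice: as an :class:`ArchSpec` layer table with
closed-form learnable counts, and as an instantiated numpy model whose
enumerated parameter arrays must agree exactly — the audit asserts both routes
match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "LayerSpec",
    "ArchSpec",
    "build_eeg_2dcnn",
    "build_seq_1dcnn_lstm",
    "count_learnables",
    "instantiate",
    "hidden_activations",
    "N_CLASSES",
]

N_CLASSES = 4


@dataclass(frozen=True)
class LayerSpec:
    """One row of an architecture table."""

    index: int
    kind: str
    name: str
    activation_shape: tuple[int, ...]
    learnables: int
    detail: str = ""


@dataclass
class ArchSpec:
    name: str
    layers: list[LayerSpec] = field(default_factory=list)
    n_classes: int = N_CLASSES

    @property
    def total_learnables(self) -> int:
        return sum(l.learnables for l in self.layers)

    def layer(self, name: str) -> LayerSpec:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    def to_rows(self) -> list[dict]:
        return [
            {
                "serial": l.index,
                "layer": l.kind,
                "name": l.name,
                "activations": "×".join(map(str, l.activation_shape)),
                "learnables": l.learnables,
                "detail": l.detail,
            }
            for l in self.layers
        ]


# --- closed-form learnable counts -------------------------------------------


def count_learnables(kind: str, **p) -> int:
    """Closed-form learnable count for one layer kind.

    conv2d: kh·kw·c_in·filters + filters; conv1d: k·c_in·filters + filters;
    dense: n_in·n_out + n_out; lstm: 4H(I+H) + 4H; batchnorm: 2·channels;
    everything else: 0.
    """
    if kind == "conv2d":
        return p["kh"] * p["kw"] * p["c_in"] * p["filters"] + p["filters"]
    if kind == "conv1d":
        return p["k"] * p["c_in"] * p["filters"] + p["filters"]
    if kind == "dense":
        return p["n_in"] * p["n_out"] + p["n_out"]
    if kind == "lstm":
        return 4 * p["hidden"] * (p["n_in"] + p["hidden"]) + 4 * p["hidden"]
    if kind == "batchnorm":
        return 2 * p["channels"]
    if kind in ("input", "relu", "maxpool2d", "maxpool1d", "flatten",
                "dropout", "softmax", "output", "sequence"):
        return 0
    raise ValueError(f"unknown layer kind {kind!r}")


def _ceil2(n: int) -> int:
    return -(-n // 2)


def build_eeg_2dcnn(input_hw: tuple[int, int] = (81, 128)) -> ArchSpec:
    """Layer table of the 2-D CNN for topographic EEG images."""
    h, w = input_hw
    spec = ArchSpec("eeg_2dcnn")
    rows: list[LayerSpec] = []
    idx = 1

    def add(kind, name, shape, learn=0, detail=""):
        nonlocal idx
        rows.append(LayerSpec(idx, kind, name, shape, learn, detail))
        idx += 1

    add("input", "input", (h, w, 1))
    chain = [(1, 8, True), (8, 16, True), (16, 16, False)]
    for k, (c_in, f, pool) in enumerate(chain, start=1):
        add("conv2d", f"conv{k}", (h, w, f),
            count_learnables("conv2d", kh=3, kw=3, c_in=c_in, filters=f),
            f"3×3×{c_in}×{f}, same")
        add("batchnorm", f"bn{k}", (h, w, f),
            count_learnables("batchnorm", channels=f))
        add("relu", f"relu{k}", (h, w, f))
        if pool:
            h, w = _ceil2(h), _ceil2(w)
            add("maxpool2d", f"pool{k}", (h, w, f), detail="2×2 stride 2, ceil")
    fc_in = h * w * 16
    add("dense", "fc", (N_CLASSES,),
        count_learnables("dense", n_in=fc_in, n_out=N_CLASSES), f"{N_CLASSES}×{fc_in}")
    add("softmax", "softmax", (N_CLASSES,))
    add("output", "output", (N_CLASSES,))
    spec.layers = rows
    _audit_shapes(spec)
    return spec


def build_seq_1dcnn_lstm(length: int = 128) -> ArchSpec:
    """Layer table of the 1-D CNN + LSTM for one-second ECG/GSR sequences."""
    spec = ArchSpec("seq_1dcnn_lstm")
    rows: list[LayerSpec] = []
    idx = 1

    def add(kind, name, shape, learn=0, detail=""):
        nonlocal idx
        rows.append(LayerSpec(idx, kind, name, shape, learn, detail))
        idx += 1

    add("input", "input", (length, 1))
    for k, (c_in, f) in enumerate([(1, 16), (16, 32)], start=1):
        add("conv1d", f"conv{k}", (length, f),
            count_learnables("conv1d", k=3, c_in=c_in, filters=f),
            f"3×1×{c_in}×{f}, same")
        add("relu", f"relu{k}", (length, f))
        add("maxpool1d", f"pool{k}", (length, f), detail="2×1 stride 1, same")
    flat = length * 32
    add("flatten", "flatten", (flat,))
    add("lstm", "lstm", (128,),
        count_learnables("lstm", n_in=flat, hidden=128),
        f"input 512×{flat}, recurrent 512×128")
    for k, (n_in, n_out) in enumerate([(128, 256), (256, 128), (128, N_CLASSES)], start=1):
        add("dense", f"fc{k}", (n_out,),
            count_learnables("dense", n_in=n_in, n_out=n_out), f"{n_out}×{n_in}")
        add("dropout", f"drop{k}", (n_out,), detail="rate 0.5")
    add("softmax", "softmax", (N_CLASSES,))
    add("output", "output", (N_CLASSES,))
    spec.layers = rows
    _audit_shapes(spec)
    return spec


def _audit_shapes(spec: ArchSpec) -> None:
    """Fail construction if consecutive activation shapes cannot chain."""
    prev: tuple[int, ...] | None = None
    for l in spec.layers:
        if prev is not None:
            if l.kind in ("conv2d", "batchnorm", "relu", "dropout", "softmax", "output"):
                if l.kind == "conv2d" and l.activation_shape[:2] != prev[:2]:
                    raise ValueError(f"shape break at {l.name}: {prev} → {l.activation_shape}")
                if l.kind in ("batchnorm", "relu", "softmax", "output", "dropout") \
                        and l.activation_shape != prev:
                    raise ValueError(f"shape break at {l.name}: {prev} → {l.activation_shape}")
            if l.kind == "maxpool2d":
                eh, ew = _ceil2(prev[0]), _ceil2(prev[1])
                if l.activation_shape[:2] != (eh, ew):
                    raise ValueError(f"pool shape break at {l.name}")
            if l.kind == "flatten" and int(np.prod(prev)) != l.activation_shape[0]:
                raise ValueError(f"flatten width {l.activation_shape[0]} ≠ prod{prev}")
        prev = l.activation_shape
    if spec.layers[-1].activation_shape != (spec.n_classes,):
        raise ValueError("final layer must emit one logit per class")


# --- runtime models ----------------------------------------------------------


def instantiate(spec: ArchSpec, seed: int = 0, dtype=np.float32) -> nn.Sequential:
    """Build the trainable numpy model matching an architecture table.

    Softmax is applied inside the loss (and in ``predict``), so the model's
    last layer is the final dense/dropout; the table's softmax and output rows
    carry no learnables and need no runtime counterpart. Parameters default to
    float32, which is ample for these shallow nets and halves memory traffic.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6E65]))
    layers: list[nn.Layer] = []
    if spec.name == "eeg_2dcnn":
        for c_in, f, pool, k in [(1, 8, True, 1), (8, 16, True, 2), (16, 16, False, 3)]:
            layers.append(nn.Conv2D(c_in, f, rng=rng, name=f"conv{k}"))
            layers.append(nn.BatchNorm(f, name=f"bn{k}"))
            layers.append(nn.ReLU(name=f"relu{k}"))
            if pool:
                layers.append(nn.MaxPool2D(name=f"pool{k}"))
        layers.append(nn.Flatten(name="flatten"))
        fc_in = spec.layer("fc").learnables // N_CLASSES - 1
        layers.append(nn.Dense(fc_in, N_CLASSES, rng, name="fc"))
    elif spec.name == "seq_1dcnn_lstm":
        for c_in, f, k in [(1, 16, 1), (16, 32, 2)]:
            layers.append(nn.Conv1D(c_in, f, rng=rng, name=f"conv{k}"))
            layers.append(nn.ReLU(name=f"relu{k}"))
            layers.append(nn.MaxPool1D(name=f"pool{k}"))
        layers.append(nn.Flatten(name="flatten"))
        flat = spec.layer("flatten").activation_shape[0]
        layers.append(nn.ToSequence())
        layers.append(nn.LSTM(flat, 128, rng, name="lstm"))
        for k, (n_in, n_out) in enumerate([(128, 256), (256, 128), (128, N_CLASSES)], start=1):
            layers.append(nn.Dense(n_in, n_out, rng, name=f"fc{k}"))
            layers.append(nn.Dropout(0.5, rng, name=f"drop{k}"))
    else:
        raise ValueError(f"unknown architecture {spec.name!r}")
    return nn.Sequential(layers).astype(dtype)


def hidden_activations(
    model: nn.Sequential, x: np.ndarray, layer: str | None = None
) -> dict[str, np.ndarray] | np.ndarray:
    """Activations after any named layer (plus 'softmax'), inference mode."""
    acts = model.activations(x)
    acts["softmax"] = nn.softmax(acts[model.layers[-1].name])
    if layer is None:
        return acts
    if layer not in acts:
        raise KeyError(f"unknown layer {layer!r}; available: {sorted(acts)}")
    return acts[layer]
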