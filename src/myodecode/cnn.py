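"""Compact convolutional decoders for windowed multichannel sEMG.

Two variants share one topology — three convolution blocks
(conv -> batch-norm -> RReLU -> max-pool over time -> dropout) feeding a
flattened representation into two fully connected blocks (300 then 50 units,
each with batch-norm and RReLU, dropout after the first) and a final dense
output layer:

* ``cnet2d`` uses kernels (3,13), (3,9), (3,5) spanning 3 adjacent electrode
  channels ('valid' along the channel axis, 'same' along time) so the channel
  extent shrinks 10 -> 8 -> 6 -> 4;
* ``cnet1d`` uses kernels (1,13), (1,9), (1,5) that never mix channels.

Training uses Adam with cross-entropy, a seeded random validation hold-out
(20 % by default), min-validation-loss checkpointing and optional
early-stopping patience.  The number of convolution filters per block is
configurable (default 32, 64, 64); every printed head parameter count is
independent of this choice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .core_data import WindowSet
from .nn import (BatchNorm, Conv2D, Dense, Dropout, FitConfig, Flatten,
                 MaxPoolTime, RReLU, Sequential, SigmoidBCE,
                 SoftmaxCrossEntropy, count_trainable, rrelu)  # noqa: F401 (re-export)

# layer indices inside the Sequential produced by build_cnet
FEATURE_END = 16          # layers [0:16] = conv stack through flatten
FC300_END = 19            # layers [0:19] = ... + dense300 block (no dropout)
DENSE300_50 = 20          # the 300 -> 50 dense layer
BN50 = 21                 # its batch norm
OUTPUT_DENSE = 23         # the final dense layer


@dataclass(frozen=True)
class ArchitectureConfig:
    variant: str = "cnet1d"                 # cnet1d | cnet2d
    n_channels: int = 10
    window_len: int = 512
    n_classes: int = 8
    conv_filters: tuple[int, int, int] = (32, 64, 64)
    kernel_times: tuple[int, int, int] = (13, 9, 5)
    pool_time: int = 4                      # 4 -> 2048 Hz style, 3 -> 2 kHz style
    dropout_p: float = 0.3
    rrelu_lower: float = 1 / 8
    rrelu_upper: float = 1 / 3
    head_dims: tuple[int, int] = (300, 50)
    output_activation: str = "softmax"      # softmax | sigmoid

    def __post_init__(self):
        if self.variant not in ("cnet1d", "cnet2d"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.output_activation not in ("softmax", "sigmoid"):
            raise ValueError(f"unknown output activation {self.output_activation!r}")

    @property
    def kernel_channels(self) -> tuple[int, int, int]:
        return (3, 3, 3) if self.variant == "cnet2d" else (1, 1, 1)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 400
    batch_size: int = 128
    lr: float = 1e-3
    lr_end: float | None = None     # set for decaying-schedule styles
    val_fraction: float = 0.2
    patience: int | None = 100
    seed: int = 0


NEARLAB_TRAIN = TrainConfig(epochs=400, lr=1e-3, patience=100)
NINAPRO_TRAIN = TrainConfig(epochs=600, lr=1e-3, lr_end=5e-7, patience=None)


@dataclass
class TrainedModel:
    """A built network, its architecture, class vocabulary and training log."""

    net: Sequential
    arch: ArchitectureConfig
    classes: tuple[str, ...]
    history: nn.History | None = None

    @property
    def loss(self):
        return (SoftmaxCrossEntropy() if self.arch.output_activation == "softmax"
                else SigmoidBCE())


def build_cnet(cfg: ArchitectureConfig, rng: np.random.Generator | None = None
               ) -> Sequential:
    """Assemble the layer stack, validating per-block shapes as it goes."""
    rng = rng or np.random.default_rng(0)
    kc = cfg.kernel_channels
    h, w = cfg.n_channels, cfg.window_len
    layers: list[nn.Layer] = []
    shapes = [(1, h, w)]
    in_ch = 1
    for b, (f, kh, kw) in enumerate(zip(cfg.conv_filters, kc, cfg.kernel_times)):
        h_out = h - kh + 1
        w_out = w // cfg.pool_time
        if h_out < 1 or w_out < 1:
            raise ValueError(
                f"block {b}: shape {(in_ch, h, w)} collapses under kernel "
                f"({kh},{kw}) / pool (1,{cfg.pool_time}); per-block shapes so far: "
                f"{shapes}")
        layers += [
            Conv2D(in_ch, f, (kh, kw), rng, name=f"conv{b}"),
            BatchNorm(f, conv=True, name=f"bn{b}"),
            RReLU(cfg.rrelu_lower, cfg.rrelu_upper, name=f"rrelu{b}"),
            MaxPoolTime(cfg.pool_time, name=f"pool{b}"),
            Dropout(cfg.dropout_p, name=f"drop{b}"),
        ]
        in_ch, h, w = f, h_out, w_out
        shapes.append((in_ch, h, w))
    flat = in_ch * h * w
    d1, d2 = cfg.head_dims
    layers += [
        Flatten(name="flatten"),
        Dense(flat, d1, rng, name="fc300"),
        BatchNorm(d1, conv=False, name="fc300_bn"),
        RReLU(cfg.rrelu_lower, cfg.rrelu_upper, name="fc300_rrelu"),
        Dropout(cfg.dropout_p, name="fc300_drop"),
        Dense(d1, d2, rng, name="fc50"),
        BatchNorm(d2, conv=False, name="fc50_bn"),
        RReLU(cfg.rrelu_lower, cfg.rrelu_upper, name="fc50_rrelu"),
        Dense(d2, cfg.n_classes, rng, name="output"),
    ]
    return Sequential(layers, name=cfg.variant)


def _as_input(windows: np.ndarray) -> np.ndarray:
    """(n, channels, time) float32 with a singleton map axis."""
    return np.asarray(windows, dtype=nn.DTYPE)[:, None, :, :]


def _encode_labels(labels: np.ndarray, classes: tuple[str, ...]) -> np.ndarray:
    lut = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([lut[l] for l in labels], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} not in model classes {classes}") from exc


def train_model(arch: ArchitectureConfig, ws: WindowSet, cfg: TrainConfig,
                classes: tuple[str, ...] | None = None) -> TrainedModel:
    """Build and train a decoder on a labeled window set."""
    if ws.n_windows == 0:
        raise ValueError("empty training window set")
    if classes is None:
        classes = tuple(sorted(set(ws.labels)))
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    arch = replace(arch, n_channels=ws.n_channels, window_len=ws.window_len,
                   n_classes=len(classes))
    init_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 71]))
    net = build_cnet(arch, init_rng)
    model = TrainedModel(net=net, arch=arch, classes=classes)
    y = _encode_labels(ws.labels, classes)
    if arch.output_activation == "sigmoid":
        y = np.eye(len(classes))[y]
    fit_cfg = FitConfig(epochs=cfg.epochs, batch_size=cfg.batch_size, lr=cfg.lr,
                        lr_end=cfg.lr_end, val_fraction=cfg.val_fraction,
                        patience=cfg.patience, seed=cfg.seed)
    model.history = nn.fit(net, model.loss, _as_input(ws.windows), y, fit_cfg)
    return model


def predict_activations(model: TrainedModel, windows: np.ndarray | WindowSet,
                        batch: int = 256) -> np.ndarray:
    """Eval-mode output-layer activations (softmax probabilities or sigmoid
    activations, depending on the model's output head)."""
    w = windows.windows if isinstance(windows, WindowSet) else windows
    X = _as_input(w)
    if X.shape[2] != model.arch.n_channels or X.shape[3] != model.arch.window_len:
        raise ValueError(
            f"window shape {X.shape[2:]} does not match model input "
            f"({model.arch.n_channels}, {model.arch.window_len})")
    logits = np.concatenate(
        [model.net.forward(X[i:i + batch], train=False, rng=None)
         for i in range(0, len(X), batch)], axis=0)
    return model.loss.activate(logits)


def predict_proba(model: TrainedModel, windows: np.ndarray | WindowSet,
                  batch: int = 256) -> np.ndarray:
    """Probability rows (each non-negative, summing to 1)."""
    act = predict_activations(model, windows, batch)
    if model.arch.output_activation == "sigmoid":
        act = act / act.sum(axis=1, keepdims=True)
    return act


def predict_label(model: TrainedModel, windows: np.ndarray | WindowSet,
                  batch: int = 256) -> np.ndarray:
    """Argmax class tokens (lowest index wins ties)."""
    act = predict_activations(model, windows, batch)
    idx = act.argmax(axis=1)
    return np.array([model.classes[i] for i in idx], dtype=object)


def accuracy_on(model: TrainedModel, ws: WindowSet) -> float:
    pred = predict_label(model, ws)
    return float(np.mean(pred == np.asarray(ws.labels)))


def save_model(model: TrainedModel, path: str) -> None:
    """Serialize as ``<path>.npz`` weights + ``<path>.json`` spec."""
    import json
    from dataclasses import asdict
    arrays = {f"p{i}": p.value for i, p in enumerate(model.net.params())}
    arrays.update({f"b{i}": b for i, b in enumerate(model.net.buffers())})
    np.savez(path + ".npz", **arrays)
    with open(path + ".json", "w") as fh:
        json.dump({"arch": asdict(model.arch), "classes": list(model.classes)},
                  fh, indent=1)


def load_model(path: str) -> TrainedModel:
    import json
    with open(path + ".json") as fh:
        spec = json.load(fh)
    arch_d = spec["arch"]
    for key in ("conv_filters", "kernel_times", "head_dims"):
        arch_d[key] = tuple(arch_d[key])
    arch = ArchitectureConfig(**arch_d)
    net = build_cnet(arch, np.random.default_rng(0))
    with np.load(path + ".npz") as data:
        for i, p in enumerate(net.params()):
            p.value[...] = data[f"p{i}"]
        for i, b in enumerate(net.buffers()):
            b[...] = data[f"b{i}"]
    return TrainedModel(net=net, arch=arch, classes=tuple(spec["classes"]))
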