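"""Subject-transfer decoding: the parallel-feature-concatenation network.

PFCnet concatenates two frozen convolutional feature extractors — one trained
on the target subject, one trained on the pooled data of source subjects —
and trains a fresh classifier head (300 -> 50 -> n_classes, randomly
initialized) on the target subject's training windows.  Convolution weights
are frozen; batch-norm scale/shift stay trainable and batch-norm running
statistics keep updating, so the frozen extractors can re-calibrate their
normalization to the target data.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .cnn import (FEATURE_END, ArchitectureConfig, TrainConfig, TrainedModel,
                  _as_input, _encode_labels, accuracy_on, train_model)
from .core_data import WindowSet
from .nn import (BatchNorm, Dense, Dropout, FitConfig, Parallel, RReLU,
                 Sequential, SoftmaxCrossEntropy)

# Table-3-style schedules: the source extractor trains at a higher rate and
# fewer epochs than the final (head) stage.
SOURCE_TRAIN = TrainConfig(epochs=100, lr=3e-3, patience=None)
FINAL_TRAIN = TrainConfig(epochs=200, lr=1e-3, patience=80)


def select_source_subjects(all_subjects: list[str], target: str,
                           grouping: str = "all_others",
                           blocks: list[list[str]] | None = None) -> list[str]:
    """Source roster for a target subject.

    ``all_others``: every subject except the target.  ``blocks``: the
    target's block minus the target (for large cohorts split into groups).
    """
    if target not in all_subjects:
        raise ValueError(f"unknown target subject {target!r}")
    if grouping == "all_others":
        return [s for s in all_subjects if s != target]
    if grouping == "blocks":
        if not blocks:
            raise ValueError("blocks grouping requires explicit blocks")
        for block in blocks:
            if target in block:
                return [s for s in block if s != target]
        raise ValueError(f"target {target!r} not found in any block")
    raise ValueError(f"unknown grouping {grouping!r}")


@dataclass
class PFCnetModel:
    """Parallel frozen extractors + fresh trainable head."""

    net: Sequential               # Parallel(extractors) followed by the head
    arch: ArchitectureConfig
    classes: tuple[str, ...]
    concat_dim: int
    history: nn.History | None = None


def _extractor(model: TrainedModel) -> Sequential:
    """Deep copy of the conv stack through flatten, conv weights frozen,
    batch-norm scale/shift left trainable."""
    branch = copy.deepcopy(model.net[0:FEATURE_END])
    for layer in branch.layers:
        for p in layer.params():
            p.trainable = isinstance(layer, BatchNorm)
    return branch


def build_pfcnet(target_model: TrainedModel, source_model: TrainedModel,
                 n_classes: int | None = None,
                 rng: np.random.Generator | None = None) -> PFCnetModel:
    """Concatenate the two feature extractors under a new random head."""
    ta, sa = target_model.arch, source_model.arch
    if (ta.n_channels, ta.window_len) != (sa.n_channels, sa.window_len):
        raise ValueError(
            f"incompatible extractor input shapes {(ta.n_channels, ta.window_len)} "
            f"vs {(sa.n_channels, sa.window_len)}")
    if n_classes is None:
        n_classes = ta.n_classes
    rng = rng or np.random.default_rng(0)
    bt, bs = _extractor(target_model), _extractor(source_model)
    probe = np.zeros((1, 1, ta.n_channels, ta.window_len), dtype=nn.DTYPE)
    concat_dim = (bt.forward(probe).shape[1] + bs.forward(probe).shape[1])
    d1, d2 = ta.head_dims
    head = [
        Dense(concat_dim, d1, rng, name="pfc_fc300"),
        BatchNorm(d1, conv=False, name="pfc_fc300_bn"),
        RReLU(ta.rrelu_lower, ta.rrelu_upper, name="pfc_fc300_rrelu"),
        Dropout(ta.dropout_p, name="pfc_fc300_drop"),
        Dense(d1, d2, rng, name="pfc_fc50"),
        BatchNorm(d2, conv=False, name="pfc_fc50_bn"),
        RReLU(ta.rrelu_lower, ta.rrelu_upper, name="pfc_fc50_rrelu"),
        Dense(d2, n_classes, rng, name="pfc_output"),
    ]
    net = Sequential([Parallel(bt, bs, name="pfc_extractors")] + head, name="pfcnet")
    return PFCnetModel(net=net, arch=ta, classes=target_model.classes,
                       concat_dim=concat_dim)


def train_pfcnet(model: PFCnetModel, target_train: WindowSet,
                 cfg: TrainConfig = FINAL_TRAIN) -> PFCnetModel:
    """Final-stage training: head + batch-norm only, on target windows."""
    if target_train.n_windows == 0:
        raise ValueError("empty target training window set")
    y = _encode_labels(target_train.labels, model.classes)
    fit_cfg = FitConfig(epochs=cfg.epochs, batch_size=cfg.batch_size, lr=cfg.lr,
                        lr_end=cfg.lr_end, val_fraction=cfg.val_fraction,
                        patience=cfg.patience, seed=cfg.seed)
    model.history = nn.fit(model.net, SoftmaxCrossEntropy(),
                           _as_input(target_train.windows), y, fit_cfg)
    return model


def predict_label_pfc(model: PFCnetModel, ws: WindowSet, batch: int = 256
                      ) -> np.ndarray:
    X = _as_input(ws.windows)
    logits = np.concatenate(
        [model.net.forward(X[i:i + batch], train=False, rng=None)
         for i in range(0, len(X), batch)], axis=0)
    idx = logits.argmax(axis=1)
    return np.array([model.classes[i] for i in idx], dtype=object)


def accuracy_pfc(model: PFCnetModel, ws: WindowSet) -> float:
    return float(np.mean(predict_label_pfc(model, ws) == np.asarray(ws.labels)))


def restrict_to_repetitions(ws: WindowSet, n_keep: int) -> WindowSet:
    """Keep the first ``n_keep`` repetitions per (class, orientation) cell."""
    keep = np.zeros(ws.n_windows, dtype=bool)
    keys = list(zip(ws.labels, ws.orientations))
    for key in set(keys):
        sel = np.array([k == key for k in keys])
        reps = np.unique(ws.repetition_ids[sel])
        keep |= sel & np.isin(ws.repetition_ids, reps[:n_keep])
    return ws.subset(keep)


def data_budget_experiment(train_ws: WindowSet, test_ws: WindowSet,
                           fractions: list[tuple[int, int]],
                           methods: dict, seed: int = 0) -> pd.DataFrame:
    """Accuracy per (fraction x method) with whole-repetition data budgets.

    ``fractions`` are (kept, total) pairs, e.g. [(1,3),(2,3),(3,3)]; each must
    be realizable by keeping whole repetitions of the training set.
    ``methods`` maps a name to a callable (train_ws, seed) -> model with an
    ``accuracy(model, test_ws)`` pairing: the callable returns
    (model, accuracy_fn).
    """
    reps_per_cell = _reps_per_cell(train_ws)
    rows = {}
    for kept, total in fractions:
        if total != reps_per_cell or not (1 <= kept <= total):
            raise ValueError(
                f"fraction {kept}/{total} not realizable with {reps_per_cell} "
                f"training repetitions per class")
        sub = restrict_to_repetitions(train_ws, kept)
        rows[f"{kept}/{total}"] = {
            name: fn(sub, test_ws, seed) for name, fn in methods.items()}
    return pd.DataFrame(rows).T


def _reps_per_cell(ws: WindowSet) -> int:
    keys = list(zip(ws.labels, ws.orientations))
    counts = {key: len(np.unique(ws.repetition_ids[
        np.array([k == key for k in keys])])) for key in set(keys)}
    vals = set(counts.values())
    if len(vals) != 1:
        raise ValueError(f"unequal repetition counts per cell: {counts}")
    return vals.pop()


def fit_target_only(train_ws: WindowSet, test_ws: WindowSet, seed: int,
                    arch: ArchitectureConfig, cfg: TrainConfig) -> float:
    model = train_model(arch, train_ws, TrainConfig(
        epochs=cfg.epochs, batch_size=cfg.batch_size, lr=cfg.lr,
        lr_end=cfg.lr_end, val_fraction=cfg.val_fraction,
        patience=cfg.patience, seed=seed))
    return accuracy_on(model, test_ws)
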