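"""Task transfer: decoding combined movements from basic-movement knowledge.

Three stages of increasing target-domain supervision:

1. **Syn0net** (zero samples) — because every combined movement is one wrist
   rotation plus one hand function, a decoder trained on the 8 basic classes
   can predict a combined class directly: argmax over the two rotation
   outputs, argmax over the three function outputs, compose.  Works with
   either a softmax or a sigmoid output head.
2. **Sia5net** (5 query samples per class) — a two-branch Siamese network
   built from the trained basic-class decoder: both branches share weights up
   to the 300-unit representation, joined by an element-wise L1 distance and
   a single sigmoid unit.  Only that unit's 301 parameters (300 weights + 1
   bias) train, on same/different pairs of basic-movement windows
   (0 = same-class convention).  A test window is scored against the query
   bank and assigned the most similar class.
3. **FTnet** (about one repetition per class) — the basic-class decoder's
   output layer is replaced by a 6-unit sigmoid layer.  Stage 1 trains only
   those 306 parameters; stage 2 additionally unlocks the 50-unit fully
   connected block (dense 300->50 plus its batch norm), 15,456 parameters in
   total, fine-tuned at a low learning rate.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .cnn import (BN50, DENSE300_50, FC300_END, OUTPUT_DENSE, TrainConfig,
                  TrainedModel, _as_input, predict_activations)
from .core_data import (LabelTaxonomy, WindowSet, compose_combined,
                        decompose_combined, ROTATIONS, FUNCTIONS)
from .nn import Dense, FitConfig, Sequential, SigmoidBCE, sigmoid


# ---------------------------------------------------------------------------
# stage 1: Syn0net

def syn0_predict(prob: np.ndarray, taxonomy: LabelTaxonomy,
                 classes: tuple[str, ...]) -> str:
    """Combined-class prediction from a basic-class activation vector.

    Rotation = argmax over the pronation/supination entries, function =
    argmax over the pinch/lateral-pinch/grip entries (ties -> lowest index);
    the remaining basic-class entries are ignored.
    """
    prob = np.asarray(prob, dtype=float)
    if not np.all(np.isfinite(prob)):
        raise ValueError("activation vector must be finite")
    try:
        rot_idx = [classes.index(r) for r in ROTATIONS]
        fun_idx = [classes.index(f) for f in FUNCTIONS]
    except ValueError as exc:
        raise ValueError(
            "model class vocabulary lacks rotation/function classes") from exc
    rotation = ROTATIONS[int(np.argmax(prob[rot_idx]))]
    function = FUNCTIONS[int(np.argmax(prob[fun_idx]))]
    return compose_combined(rotation, function, taxonomy)


def syn0_evaluate(model: TrainedModel, combined_ws: WindowSet,
                  taxonomy: LabelTaxonomy) -> dict[str, float]:
    """Overall / rotation / function accuracies of the zero-shot rule.

    Overall counts a window correct only when both components are correct.
    """
    for label in set(combined_ws.labels):
        if not taxonomy.is_combined(label):
            raise ValueError(f"window label {label!r} is not a combined class")
    act = predict_activations(model, combined_ws)
    n = combined_ws.n_windows
    ok_rot = ok_fun = ok_both = 0
    for i in range(n):
        pred = syn0_predict(act[i], taxonomy, model.classes)
        pr, pf = decompose_combined(pred, taxonomy)
        tr, tf = decompose_combined(combined_ws.labels[i], taxonomy)
        ok_rot += pr == tr
        ok_fun += pf == tf
        ok_both += (pr == tr) and (pf == tf)
    return {"overall": ok_both / n, "rotation": ok_rot / n, "function": ok_fun / n}


# ---------------------------------------------------------------------------
# stage 2: Sia5net

@dataclass(frozen=True)
class PairSpec:
    """How to sample training pairs for the Siamese head.

    Negative pairs are drawn mostly within the function group and within the
    rotation group: those are the separations that matter for combined
    movements, while rotation-vs-function pairs are de-emphasized.
    Label convention: same-class -> 0, different-class -> 1.
    """

    positive_fraction: float = 0.5
    negative_mix: tuple[float, float, float] = (0.4, 0.4, 0.2)
    # (function-function, rotation-rotation, other)
    batch_size: int = 32
    epochs: int = 100
    lr: float = 1e-3
    lr_end: float = 5e-5

    def __post_init__(self):
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")
        if abs(sum(self.negative_mix) - 1) > 1e-9 or min(self.negative_mix) < 0:
            raise ValueError("negative_mix must be non-negative and sum to 1")


@dataclass
class SiameseModel:
    """Weight-shared branch to the 300-unit representation + 301-param head."""

    branch: Sequential
    head: Dense
    base_classes: tuple[str, ...]

    def params(self):
        return self.branch.params() + self.head.params()

    def features(self, windows: np.ndarray, batch: int = 256) -> np.ndarray:
        """Eval-mode 300-unit representations (branches are frozen, so the
        representation of a window is a pure function of its samples)."""
        X = _as_input(windows)
        return np.concatenate(
            [self.branch.forward(X[i:i + batch], train=False, rng=None)
             for i in range(0, len(X), batch)], axis=0)

    def score_features(self, fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
        """Similarity scores in (0,1) from branch features; 0 = same-class."""
        d = np.abs(fa - fb)
        return sigmoid(d @ self.head.W.value + self.head.b.value)[:, 0]

    def score(self, wa: np.ndarray, wb: np.ndarray) -> np.ndarray:
        return self.score_features(self.features(wa), self.features(wb))


def build_siamese(base: TrainedModel,
                  rng: np.random.Generator | None = None) -> SiameseModel:
    """Siamese spec from a trained basic-class decoder.

    The branch is everything up to the 300-unit activation (the 50-unit and
    output layers are dropped); all inherited weights are frozen, leaving the
    301 head parameters trainable.
    """
    d1 = base.arch.head_dims[0]
    layers = base.net.layers
    if len(layers) <= FC300_END or not isinstance(layers[FC300_END - 3], Dense) \
            or layers[FC300_END - 3].n_out != d1:
        raise ValueError(f"base model lacks a {d1}-unit representation layer")
    branch = copy.deepcopy(base.net[0:FC300_END])
    for p in branch.params():
        p.trainable = False
    rng = rng or np.random.default_rng(0)
    head = Dense(d1, 1, rng, name="siamese_head")
    return SiameseModel(branch=branch, head=head, base_classes=base.classes)


def generate_pairs(ws: WindowSet, spec: PairSpec, rng: np.random.Generator,
                   n_pairs: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index pairs (ia, ib) with 0/1 labels from an 8-class window set.

    The positive count is exact (round(positive_fraction * n_pairs));
    negative pair categories are drawn from ``negative_mix``.
    """
    labels = np.asarray(ws.labels)
    classes = sorted(set(labels))
    by_class = {c: np.flatnonzero(labels == c) for c in classes}
    for c, idx in by_class.items():
        if len(idx) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 windows")
    fun_present = [c for c in FUNCTIONS if c in by_class]
    rot_present = [c for c in ROTATIONS if c in by_class]
    ff_pairs = [(a, b) for i, a in enumerate(fun_present)
                for b in fun_present[i + 1:]]
    rr_pairs = [(a, b) for i, a in enumerate(rot_present)
                for b in rot_present[i + 1:]]
    all_pairs = [(a, b) for i, a in enumerate(classes) for b in classes[i + 1:]]
    excluded = {frozenset(p) for p in ff_pairs + rr_pairs}
    other_pairs = [p for p in all_pairs if frozenset(p) not in excluded]

    n_pos = int(round(spec.positive_fraction * n_pairs))
    ia = np.empty(n_pairs, dtype=np.int64)
    ib = np.empty(n_pairs, dtype=np.int64)
    y = np.empty(n_pairs, dtype=np.int64)
    for k in range(n_pos):
        c = classes[rng.integers(len(classes))]
        a, b = rng.choice(by_class[c], size=2, replace=False)
        ia[k], ib[k], y[k] = a, b, 0
    cat_pools = [ff_pairs, rr_pairs, other_pairs]
    probs = np.array(spec.negative_mix, dtype=float)
    usable = np.array([len(p) > 0 for p in cat_pools])
    if not usable[probs > 0].all():
        raise ValueError("a requested negative category has no class pairs")
    for k in range(n_pos, n_pairs):
        cat = rng.choice(3, p=probs)
        c1, c2 = cat_pools[cat][rng.integers(len(cat_pools[cat]))]
        ia[k] = rng.choice(by_class[c1])
        ib[k] = rng.choice(by_class[c2])
        y[k] = 1
    return ia, ib, y


def train_siamese(model: SiameseModel, ws: WindowSet, spec: PairSpec = PairSpec(),
                  n_pairs: int = 2000, seed: int = 0) -> SiameseModel:
    """Train the 301-parameter head on same/different pairs.

    Branch weights are frozen and the branches run in inference mode, so the
    300-unit features of each window are computed once and the pair training
    operates on cached features — numerically identical to running the full
    twin forward pass every step.
    """
    rng = np.random.default_rng(seed)
    ia, ib, y = generate_pairs(ws, spec, rng, n_pairs)
    if len(ia) == 0:
        raise ValueError("empty pair stream")
    feats = model.features(ws.windows).astype(nn.DTYPE)
    loss = SigmoidBCE()
    head_params = [model.head.W, model.head.b]
    opt = nn.Adam(head_params)
    for epoch in range(spec.epochs):
        lr = spec.lr * (spec.lr_end / spec.lr) ** (
            epoch / max(1, spec.epochs - 1))
        perm = rng.permutation(len(ia))
        for start in range(0, len(ia), spec.batch_size):
            sel = perm[start:start + spec.batch_size]
            d = np.abs(feats[ia[sel]] - feats[ib[sel]])
            for p in head_params:
                p.grad[...] = 0
            logits = d @ model.head.W.value + model.head.b.value
            _, dlog = loss(logits, y[sel][:, None].astype(float))
            model.head.W.grad += d.T @ dlog
            model.head.b.grad += dlog.sum(axis=0)
            opt.step(lr)
    return model


@dataclass
class QueryBank:
    """q labeled query windows per combined class (default q = 5)."""

    queries: dict[str, np.ndarray]        # class -> (q, n_channels, window_len)
    q: int = 5

    def __post_init__(self):
        for c, w in self.queries.items():
            if len(w) != self.q:
                raise ValueError(f"class {c!r} has {len(w)} queries, expected {self.q}")


def build_query_bank(ws: WindowSet, taxonomy: LabelTaxonomy, q: int = 5,
                     rng: np.random.Generator | None = None) -> QueryBank:
    """First q windows of each combined class (or a seeded random draw)."""
    queries = {}
    labels = np.asarray(ws.labels)
    for c in taxonomy.combined_classes:
        idx = np.flatnonzero(labels == c)
        if len(idx) < q:
            raise ValueError(f"class {c!r} has only {len(idx)} windows for q={q}")
        take = idx[:q] if rng is None else rng.choice(idx, size=q, replace=False)
        queries[c] = ws.windows[take]
    return QueryBank(queries=queries, q=q)


def sia5_classify(model: SiameseModel, bank: QueryBank,
                  windows: np.ndarray, taxonomy: LabelTaxonomy,
                  mode: str = "mean_score") -> np.ndarray:
    """Classify windows against the query bank.

    ``mean_score``: per class, average the similarity scores over the q
    queries and pick the class with the smallest mean (0 = same convention).
    ``majority_vote``: each of the q query rounds votes for the class with
    the smallest score; most votes wins.  All ties break to the lowest class
    index.
    """
    if mode not in ("mean_score", "majority_vote"):
        raise ValueError(f"unknown mode {mode!r}")
    classes = taxonomy.combined_classes
    for c in classes:
        if c not in bank.queries:
            raise ValueError(f"query bank lacks class {c!r}")
    windows = np.asarray(windows)
    if windows.ndim == 2:
        windows = windows[None]
    fs = model.features(windows)                              # (n, 300)
    qf = {c: model.features(bank.queries[c]) for c in classes}  # (q, 300)
    n, q = len(windows), bank.q
    scores = np.empty((n, len(classes), q))
    for j, c in enumerate(classes):
        for k in range(q):
            scores[:, j, k] = model.score_features(fs, np.broadcast_to(
                qf[c][k], fs.shape))
    if mode == "mean_score":
        pred_idx = scores.mean(axis=2).argmin(axis=1)
    else:
        votes = np.zeros((n, len(classes)), dtype=int)
        round_winner = scores.argmin(axis=1)                  # (n, q)
        for k in range(q):
            np.add.at(votes, (np.arange(n), round_winner[:, k]), 1)
        pred_idx = votes.argmax(axis=1)
    return np.array([classes[i] for i in pred_idx], dtype=object)


def sia5_accuracy(model: SiameseModel, bank: QueryBank, ws: WindowSet,
                  taxonomy: LabelTaxonomy, mode: str = "mean_score") -> float:
    pred = sia5_classify(model, bank, ws.windows, taxonomy, mode)
    return float(np.mean(pred == np.asarray(ws.labels)))


# ---------------------------------------------------------------------------
# stage 3: FTnet

@dataclass
class FTnetModel:
    """Basic-class decoder with a fresh 6-unit sigmoid output layer."""

    net: Sequential
    classes: tuple[str, ...]          # combined-class vocabulary
    arch: object = None
    stage: int = 0
    history: list = field(default_factory=list)

    def set_stage(self, stage: int) -> None:
        """Stage 1: only the new output layer trains (306 parameters).
        Stage 2: additionally the 50-unit block — dense 300->50 and its batch
        norm (15,050 + 100 + 306 = 15,456 parameters).

        Locked sub-stacks run in inference mode during training (their
        dropout/RReLU noise and batch statistics would otherwise corrupt the
        features the small trainable head learns from).
        """
        if stage not in (1, 2):
            raise ValueError("stage must be 1 or 2")
        for p in self.net.params():
            p.trainable = False
        for p in self.net.layers[OUTPUT_DENSE].params():
            p.trainable = True
        first_live = OUTPUT_DENSE
        if stage == 2:
            for li in (DENSE300_50, BN50):
                for p in self.net.layers[li].params():
                    p.trainable = True
            first_live = DENSE300_50
        for i, layer in enumerate(self.net.layers):
            layer.mode_override = "eval" if i < first_live else None
        self.stage = stage


def build_ftnet(base: TrainedModel, taxonomy: LabelTaxonomy,
                n_target: int = 6,
                rng: np.random.Generator | None = None) -> FTnetModel:
    """Replace the output layer with a randomly initialized 6-unit sigmoid
    layer and apply the stage-1 freeze mask."""
    d2 = base.arch.head_dims[1]
    out = base.net.layers[OUTPUT_DENSE]
    if not isinstance(out, Dense) or out.n_in != d2:
        raise ValueError("base model head incompatible with fine-tuning")
    rng = rng or np.random.default_rng(0)
    net = copy.deepcopy(base.net)
    net.layers[OUTPUT_DENSE] = Dense(d2, n_target, rng, name="ft_output")
    model = FTnetModel(net=net, classes=tuple(taxonomy.combined_classes[:n_target]),
                       arch=base.arch)
    model.set_stage(1)
    return model


FT_STAGE1 = TrainConfig(epochs=400, batch_size=128, lr=1e-2, lr_end=2e-6,
                        patience=None)
FT_STAGE2 = TrainConfig(epochs=300, batch_size=128, lr=1e-4, patience=None)


def _batched(net: Sequential, X: np.ndarray, batch: int = 256) -> np.ndarray:
    return np.concatenate([net.forward(X[i:i + batch], train=False, rng=None)
                           for i in range(0, len(X), batch)], axis=0)


def train_ftnet(model: FTnetModel, target_ws: WindowSet,
                stage1: TrainConfig = FT_STAGE1,
                stage2: TrainConfig = FT_STAGE2) -> FTnetModel:
    """Two-stage fine-tuning on (about) one repetition of combined windows.

    One-hot targets under per-unit binary cross-entropy; stage 2 starts from
    the stage-1 weights.  Because the locked sub-stack below the trainable
    layers runs in inference mode, its representation of each window is fixed
    and is computed once; the stages then train only the live tail of the
    network on those cached representations (numerically identical to running
    the full forward pass every step).
    """
    if target_ws.n_windows == 0:
        raise ValueError("no target-domain training windows")
    present = set(target_ws.labels)
    missing = [c for c in model.classes if c not in present]
    if missing:
        raise ValueError(f"target windows missing combined classes {missing}")
    lut = {c: i for i, c in enumerate(model.classes)}
    y = np.eye(len(model.classes))[[lut[l] for l in target_ws.labels]]
    X = _as_input(target_ws.windows)
    loss = SigmoidBCE()
    z300 = _batched(model.net[0:DENSE300_50], X)       # input of the 50-block

    model.set_stage(1)
    z50 = _batched(model.net[DENSE300_50:OUTPUT_DENSE], z300)
    head = model.net[OUTPUT_DENSE:]
    cfg = stage1
    model.history.append(nn.fit(head, loss, z50, y, FitConfig(
        epochs=cfg.epochs, batch_size=cfg.batch_size, lr=cfg.lr,
        lr_end=cfg.lr_end, val_fraction=cfg.val_fraction,
        patience=cfg.patience, seed=cfg.seed)))

    model.set_stage(2)
    tail = model.net[DENSE300_50:]
    cfg = stage2
    model.history.append(nn.fit(tail, loss, z300, y, FitConfig(
        epochs=cfg.epochs, batch_size=cfg.batch_size, lr=cfg.lr,
        lr_end=cfg.lr_end, val_fraction=cfg.val_fraction,
        patience=cfg.patience, seed=cfg.seed)))
    return model


def predict_label_ftnet(model: FTnetModel, ws: WindowSet, batch: int = 256
                        ) -> np.ndarray:
    X = _as_input(ws.windows)
    logits = np.concatenate(
        [model.net.forward(X[i:i + batch], train=False, rng=None)
         for i in range(0, len(X), batch)], axis=0)
    idx = sigmoid(logits).argmax(axis=1)
    return np.array([model.classes[i] for i in idx], dtype=object)


def accuracy_ftnet(model: FTnetModel, ws: WindowSet) -> float:
    return float(np.mean(predict_label_ftnet(model, ws) == np.asarray(ws.labels)))
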