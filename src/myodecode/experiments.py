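"""Seeded desk-scale experiment harnesses.

These functions run the full pipeline — synthetic cohort simulation,
conditioning, windowing, training, evaluation — at problem sizes chosen for
interactive CPU use: one hand orientation, a handful of repetitions and
subjects, non-overlapping 512-sample windows, small convolution banks
(8/16/16 filters) and a few dozen training epochs.  The simulation schedule
itself (3 s rest, 2 s preparation, 5 s basic / 7 s combined movements at
2048 Hz over 10 channels) is the full acquisition protocol.

They power the directional transfer-learning checks: subject transfer with a
one-repetition target budget, and the three task-transfer stages against a
from-scratch baseline.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .cnn import (ArchitectureConfig, TrainConfig, accuracy_on, train_model)
from .core_data import WindowSet, concat_window_sets, default_taxonomy
from .preprocessing import (FilterConfig, OnsetConfig, WindowingConfig,
                            windows_from_recording)
from .subject_transfer import (accuracy_pfc, build_pfcnet,
                               restrict_to_repetitions, train_pfcnet)
from .synthetic import SimulationConfig, make_synergy_bank, simulate_recording
from .task_transfer import (PairSpec, accuracy_ftnet, build_ftnet,
                            build_query_bank, build_siamese, generate_pairs,
                            sia5_accuracy, syn0_evaluate, train_ftnet,
                            train_siamese)

# desk-scale decoder: small filter bank, same topology; non-overlapping windows
DESK_ARCH = ArchitectureConfig(variant="cnet1d", conv_filters=(4, 8, 8))
DESK_WINDOWING = WindowingConfig(window_len=512, stride=512)
DESK_TRAIN = TrainConfig(epochs=20, batch_size=32, lr=1e-3, patience=None)


def _simulate_windows(bank, cfg, taxonomy, subject_index, classes, reps,
                      orientation="sideway", stream_seed=0,
                      thin: int = 1) -> WindowSet:
    """Simulate one subject session and run the conditioning pipeline.

    ``orientation`` may be a single token or a list of orientations;
    ``thin`` keeps every thin-th extracted window — a data-volume knob for
    the desk-scale harness (windows of one trial are highly redundant).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 4000 + subject_index, stream_seed]))
    orients = [orientation] if isinstance(orientation, str) else list(orientation)
    cells = [(c, o, r) for o in orients for c in classes
             for r in range(1, reps + 1)]
    order = rng.permutation(len(cells))
    items = [cells[i] for i in order]
    rec = simulate_recording(bank, cfg, f"S{subject_index}", items, taxonomy,
                             subject_index=subject_index,
                             stream_seed=stream_seed)
    ws = windows_from_recording(rec, FilterConfig(), OnsetConfig(),
                                DESK_WINDOWING)
    if thin > 1:
        ws = ws.subset(np.arange(ws.n_windows) % thin == 0)
    return ws


def _split_reps(ws: WindowSet, train_reps: list[int]) -> tuple[WindowSet, WindowSet]:
    mask = np.isin(ws.repetition_ids, train_reps)
    return ws.subset(mask), ws.subset(~mask)


def subject_transfer_experiment(seed: int, n_sources: int = 4,
                                target_budget_reps: int = 1) -> dict:
    """PFCnet vs a target-only decoder with a limited target-data budget.

    A 1+n_sources-subject cohort shares one synergy bank; subjects differ by
    multiplicative channel-gain jitter.  The target subject contributes
    ``target_budget_reps`` training repetitions — a repetition spans all
    three hand orientations, i.e. three trials per movement class — and is
    tested on 2 held-out repetitions; each source subject contributes two
    repetitions (all orientations) to the source extractor — the sources,
    unlike the target, are not data-limited.
    """
    taxonomy = default_taxonomy()
    bank = make_synergy_bank(taxonomy, 10,
                             np.random.default_rng(
                                 np.random.SeedSequence([seed, 11])))
    cfg = SimulationConfig(seed=seed)
    basic = list(taxonomy.basic_classes)
    orients = ["upward", "sideway", "downward"]

    target_ws = _simulate_windows(bank, cfg, taxonomy, 0, basic, reps=3,
                                  orientation=orients, thin=4)
    target_train_full, target_test = _split_reps(target_ws, [1])
    target_train = restrict_to_repetitions(target_train_full, target_budget_reps)

    source_sets = [_simulate_windows(bank, cfg, taxonomy, s, basic, reps=2,
                                     orientation=orients, thin=4)
                   for s in range(1, n_sources + 1)]
    source_ws = concat_window_sets(source_sets)

    t_cfg = replace(DESK_TRAIN, seed=seed)
    target_model = train_model(DESK_ARCH, target_train, t_cfg,
                               classes=taxonomy.basic_classes)
    s_cfg = replace(DESK_TRAIN, epochs=12, lr=3e-3, seed=seed + 1)
    source_model = train_model(DESK_ARCH, source_ws, s_cfg,
                               classes=taxonomy.basic_classes)

    pfc = build_pfcnet(target_model, source_model,
                       rng=np.random.default_rng(
                           np.random.SeedSequence([seed, 13])))
    pfc = train_pfcnet(pfc, target_train, replace(DESK_TRAIN, seed=seed + 2))

    return {
        "target_only_acc": accuracy_on(target_model, target_test),
        "pfcnet_acc": accuracy_pfc(pfc, target_test),
        "n_target_train": target_train.n_windows,
        "n_test": target_test.n_windows,
    }


def task_transfer_experiment(seed: int, q: int = 5) -> dict:
    """All three task-transfer stages plus a from-scratch baseline.

    One subject; the basic-movement session (5 repetitions x 8 classes, the
    per-orientation protocol count) trains the source decoder; the
    combined-movement session provides one adaptation repetition and one
    held-out test repetition per class.
    """
    taxonomy = default_taxonomy()
    bank = make_synergy_bank(taxonomy, 10,
                             np.random.default_rng(
                                 np.random.SeedSequence([seed, 21])))
    cfg = SimulationConfig(seed=seed)

    basic_ws = _simulate_windows(bank, cfg, taxonomy, 0,
                                 list(taxonomy.basic_classes), reps=5, thin=2)
    combined_ws = _simulate_windows(bank, cfg, taxonomy, 0,
                                    list(taxonomy.combined_classes), reps=2,
                                    stream_seed=7)
    adapt_ws, test_ws = _split_reps(combined_ws, [1])

    base = train_model(DESK_ARCH, basic_ws, replace(DESK_TRAIN, seed=seed),
                       classes=taxonomy.basic_classes)
    base_acc = accuracy_on(base, _split_reps(basic_ws, [1, 2])[1])

    # stage 1: zero-shot synergy rule
    syn0 = syn0_evaluate(base, test_ws, taxonomy)

    # stage 2: Siamese few-shot
    siam = build_siamese(base, np.random.default_rng(
        np.random.SeedSequence([seed, 22])))
    spec = PairSpec()
    siam = train_siamese(siam, basic_ws, spec, n_pairs=2000, seed=seed + 3)
    bank5 = build_query_bank(adapt_ws, taxonomy, q=q)
    sia5_acc = sia5_accuracy(siam, bank5, test_ws, taxonomy, mode="mean_score")

    # held-out pair separation (same vs different basic-class pairs)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    ia, ib, y = generate_pairs(basic_ws, spec, rng, 600)
    scores = siam.score_features(siam.features(basic_ws.windows[ia]),
                                 siam.features(basic_ws.windows[ib]))
    same_mean = float(scores[y == 0].mean())
    diff_mean = float(scores[y == 1].mean())

    # stage 3: staged fine-tuning vs training from scratch
    ft = build_ftnet(base, taxonomy, rng=np.random.default_rng(
        np.random.SeedSequence([seed, 24])))
    ft = train_ftnet(
        ft, adapt_ws,
        stage1=TrainConfig(epochs=400, batch_size=32, lr=1e-2, lr_end=2e-6,
                           patience=None, seed=seed + 4),
        stage2=TrainConfig(epochs=300, batch_size=32, lr=1e-4,
                           patience=None, seed=seed + 5))
    ft_acc = accuracy_ftnet(ft, test_ws)

    scratch = train_model(DESK_ARCH, adapt_ws, replace(DESK_TRAIN, seed=seed + 6),
                          classes=taxonomy.combined_classes)
    scratch_acc = accuracy_on(scratch, test_ws)

    return {
        "base_acc": base_acc,
        "syn0_overall": syn0["overall"],
        "syn0_rotation": syn0["rotation"],
        "syn0_function": syn0["function"],
        "sia5_acc": sia5_acc,
        "siamese_same_mean": same_mean,
        "siamese_diff_mean": diff_mean,
        "ftnet_acc": ft_acc,
        "scratch_acc": scratch_acc,
        "n_adapt": adapt_ws.n_windows,
        "n_test": test_ws.n_windows,
    }


def run_seeds(fn, seeds) -> dict[str, np.ndarray]:
    """Run a seeded experiment over several seeds; stack results per key."""
    results = [fn(int(s)) for s in seeds]
    return {k: np.array([r[k] for r in results]) for k in results[0]}


# ---------------------------------------------------------------------------
# config-driven multi-method experiment

KNOWN_METHODS = ("knn", "svm", "mlp", "lda", "cnet1d", "cnet2d")


def run_experiment(config: dict, out_dir: str) -> dict:
    """Simulate a cohort, train the configured methods per subject, evaluate,
    compare, and write a report directory (accuracy table, confusions,
    comparison report, run log).  Reproducible from config + seed.
    """
    import json
    import os

    import pandas as pd

    from . import __version__
    from .evaluation import compare_methods, confusion
    from .features import (compute_feature_table, scale_features,
                           train_classical, predict_classical)

    required = [k for k in ("seed", "methods") if k not in config]
    if required:
        raise ValueError(f"experiment config missing fields: {required}")
    methods = list(config["methods"])
    unknown = [m for m in methods if m not in KNOWN_METHODS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}; choose from {KNOWN_METHODS}")
    seed = int(config["seed"])
    n_subjects = int(config.get("n_subjects", 2))
    n_reps = int(config.get("n_reps", 3))
    feature_set = config.get("feature_set", "TD")
    epochs = int(config.get("epochs", DESK_TRAIN.epochs))

    taxonomy = default_taxonomy()
    bank = make_synergy_bank(taxonomy, 10,
                             np.random.default_rng(
                                 np.random.SeedSequence([seed, 31])))
    cfg = SimulationConfig(seed=seed)
    os.makedirs(out_dir, exist_ok=True)
    acc: dict[str, dict[str, float]] = {}
    for s in range(n_subjects):
        ws = _simulate_windows(bank, cfg, taxonomy, s,
                               list(taxonomy.basic_classes), reps=n_reps,
                               thin=2)
        train_ws, test_ws = _split_reps(ws, list(range(1, n_reps)))
        row: dict[str, float] = {}
        tables = None
        for m in methods:
            if m in ("cnet1d", "cnet2d"):
                arch = replace(DESK_ARCH, variant=m)
                t_cfg = replace(DESK_TRAIN, epochs=epochs, seed=seed + s)
                model = train_model(arch, train_ws, t_cfg,
                                    classes=taxonomy.basic_classes)
                row[m] = accuracy_on(model, test_ws)
                from .cnn import predict_label
                pred = predict_label(model, test_ws)
            else:
                if tables is None:
                    tr = compute_feature_table(train_ws, feature_set)
                    te = compute_feature_table(test_ws, feature_set)
                    tables = scale_features(tr, te)
                from .features import ClassicalConfig
                knn_k = min(40, max(2, tables[0].values.shape[0] - 1))
                clf = train_classical(m, tables[0],
                                      ClassicalConfig(knn_k=knn_k,
                                                      seed=seed + s))
                pred = predict_classical(clf, tables[1])
                row[m] = float(np.mean(pred == np.asarray(test_ws.labels)))
            confusion(test_ws.labels, pred).to_csv(
                os.path.join(out_dir, f"confusion_S{s}_{m}.csv"))
        acc[f"S{s}"] = row
    acc_df = pd.DataFrame(acc).T[methods]
    acc_df.to_csv(os.path.join(out_dir, "accuracy.csv"))
    report = {}
    if len(methods) >= 2:
        cmp = compare_methods(acc_df, reference=methods[-1])
        report = {"reference": cmp.reference, "friedman_p": cmp.friedman_p,
                  "pairwise": [vars(r) for r in cmp.pairwise]}
        with open(os.path.join(out_dir, "comparison.json"), "w") as fh:
            json.dump(report, fh, indent=1)
    with open(os.path.join(out_dir, "runlog.json"), "w") as fh:
        json.dump({"config": config, "version": __version__,
                   "numpy": np.__version__}, fh, indent=1)
    return {"accuracy": acc_df, "comparison": report}
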