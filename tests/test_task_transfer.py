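import copy

import numpy as np
import pytest

from myodecode.cnn import OUTPUT_DENSE, TrainConfig
from myodecode.core_data import WindowSet
from myodecode.nn import count_trainable, sigmoid
from myodecode.task_transfer import (PairSpec, QueryBank, build_ftnet,
                                     build_query_bank, build_siamese,
                                     generate_pairs, sia5_classify,
                                     syn0_evaluate, syn0_predict, train_ftnet,
                                     train_siamese)
from conftest import gain_windows


class TestSyn0Predict:
    def test_forced_argmaxes(self, taxonomy):
        classes = taxonomy.basic_classes
        prob = np.zeros(8)
        prob[classes.index("pronation")] = 0.40
        prob[classes.index("supination")] = 0.05
        prob[classes.index("grip")] = 0.30
        prob[classes.index("pinch")] = 0.10
        prob[classes.index("lateral_pinch")] = 0.02
        assert syn0_predict(prob, taxonomy, classes) == "pronation+grip"

    def test_uniform_vector_tie_breaks_to_lowest_index(self, taxonomy):
        pred = syn0_predict(np.full(8, 1 / 8), taxonomy,
                            taxonomy.basic_classes)
        assert pred == "pronation+pinch"

    def test_mass_on_other_class_still_yields_combined(self, taxonomy):
        classes = taxonomy.basic_classes
        prob = np.full(8, 0.01)
        prob[classes.index("basic_6")] = 0.9
        prob[classes.index("supination")] = 0.02
        prob[classes.index("grip")] = 0.03
        assert syn0_predict(prob, taxonomy, classes) == "supination+grip"

    def test_every_random_vector_maps_to_valid_combined(self, taxonomy):
        rng = np.random.default_rng(0)
        for _ in range(300):
            pred = syn0_predict(rng.random(8), taxonomy,
                                taxonomy.basic_classes)
            assert pred in taxonomy.combined_classes


def _rigged_model(tiny_base_model, favored):
    """Copy of the base model whose output layer always favors ``favored``."""
    model = copy.deepcopy(tiny_base_model)
    out = model.net.layers[OUTPUT_DENSE]
    out.W.value[...] = 0
    out.b.value[...] = 0
    for c, v in favored.items():
        out.b.value[model.classes.index(c)] = v
    return model


def _combined_ws(label, n=10, seed=0):
    rng = np.random.default_rng(seed)
    return WindowSet(rng.standard_normal((n, 4, 128)),
                     np.full(n, label, dtype=object), np.ones(n),
                     np.full(n, "sideway", dtype=object),
                     np.full(n, "S0", dtype=object), 128, 128)


class TestSyn0Evaluate:
    def test_all_correct(self, taxonomy, tiny_base_model):
        model = _rigged_model(tiny_base_model,
                              {"pronation": 5.0, "grip": 4.0})
        res = syn0_evaluate(model, _combined_ws("pronation+grip"), taxonomy)
        assert res == {"overall": 1.0, "rotation": 1.0, "function": 1.0}

    def test_rotation_right_function_wrong(self, taxonomy, tiny_base_model):
        model = _rigged_model(tiny_base_model,
                              {"pronation": 5.0, "grip": 4.0})
        res = syn0_evaluate(model, _combined_ws("pronation+pinch"), taxonomy)
        assert res == {"overall": 0.0, "rotation": 1.0, "function": 0.0}

    def test_basic_labels_rejected(self, taxonomy, tiny_base_model):
        with pytest.raises(ValueError, match="not a combined"):
            syn0_evaluate(tiny_base_model, _combined_ws("grip"), taxonomy)


class TestSiameseConstruction:
    def test_trainable_parameters_are_301(self, tiny_base_model):
        siam = build_siamese(tiny_base_model)
        assert count_trainable(siam) == 301

    def test_identical_inputs_score_sigmoid_of_bias(self, tiny_base_model):
        siam = build_siamese(tiny_base_model, np.random.default_rng(1))
        x = np.random.default_rng(2).standard_normal((3, 4, 128))
        s = siam.score(x, x)
        np.testing.assert_allclose(s, sigmoid(siam.head.b.value)[0], atol=1e-6)

    def test_swap_symmetry(self, tiny_base_model):
        siam = build_siamese(tiny_base_model, np.random.default_rng(3))
        rng = np.random.default_rng(4)
        a = rng.standard_normal((5, 4, 128))
        b = rng.standard_normal((5, 4, 128))
        np.testing.assert_allclose(siam.score(a, b), siam.score(b, a),
                                   atol=1e-7)

    def test_scores_in_unit_interval(self, tiny_base_model):
        siam = build_siamese(tiny_base_model, np.random.default_rng(5))
        rng = np.random.default_rng(6)
        s = siam.score(rng.standard_normal((8, 4, 128)),
                       rng.standard_normal((8, 4, 128)))
        assert np.all((s > 0) & (s < 1))


class TestPairGeneration:
    def test_positive_count_exact(self, taxonomy, tiny_basic_windows):
        rng = np.random.default_rng(7)
        ia, ib, y = generate_pairs(tiny_basic_windows, PairSpec(), rng, 1000)
        assert int(np.sum(y == 0)) == 500
        labels = tiny_basic_windows.labels
        assert all(labels[a] == labels[b] for a, b in
                   zip(ia[y == 0], ib[y == 0]))

    def test_function_only_negatives(self, taxonomy, tiny_basic_windows):
        spec = PairSpec(negative_mix=(1.0, 0.0, 0.0))
        rng = np.random.default_rng(8)
        ia, ib, y = generate_pairs(tiny_basic_windows, spec, rng, 400)
        labels = tiny_basic_windows.labels
        functions = {"pinch", "lateral_pinch", "grip"}
        for a, b in zip(ia[y == 1], ib[y == 1]):
            assert {labels[a], labels[b]} <= functions

    def test_category_histogram_within_3_sigma(self, tiny_basic_windows):
        spec = PairSpec(negative_mix=(0.4, 0.4, 0.2))
        rng = np.random.default_rng(9)
        n = 10_000
        ia, ib, y = generate_pairs(tiny_basic_windows, spec, rng, n)
        labels = tiny_basic_windows.labels
        functions = {"pinch", "lateral_pinch", "grip"}
        rotations = {"pronation", "supination"}
        neg = np.flatnonzero(y == 1)
        counts = {"ff": 0, "rr": 0, "other": 0}
        for k in neg:
            pair = {labels[ia[k]], labels[ib[k]]}
            if pair <= functions:
                counts["ff"] += 1
            elif pair <= rotations:
                counts["rr"] += 1
            else:
                counts["other"] += 1
        n_neg = len(neg)
        for got, p in zip((counts["ff"], counts["rr"], counts["other"]),
                          spec.negative_mix):
            sigma = np.sqrt(n_neg * p * (1 - p))
            assert abs(got - n_neg * p) <= 3 * sigma

    def test_small_class_rejected(self, taxonomy):
        ws = gain_windows(["pronation", "supination"], 1, seed=41)
        with pytest.raises(ValueError, match="fewer than 2"):
            generate_pairs(ws, PairSpec(negative_mix=(0, 1, 0)),
                           np.random.default_rng(0), 10)


@pytest.fixture(scope="module")
def trained(tiny_base_model, tiny_basic_windows):
    siam = build_siamese(tiny_base_model, np.random.default_rng(10))
    frozen_before = [p.value.copy() for p in siam.branch.params()]
    spec = PairSpec(epochs=30)
    train_siamese(siam, tiny_basic_windows, spec, n_pairs=800, seed=3)
    return siam, frozen_before


class TestSiameseTraining:

    def test_branch_weights_bit_identical(self, trained):
        siam, before = trained
        for b, p in zip(before, siam.branch.params()):
            np.testing.assert_array_equal(b, p.value)

    def test_same_pairs_score_below_different_pairs(self, trained,
                                                    tiny_basic_windows):
        siam, _ = trained
        rng = np.random.default_rng(11)
        ia, ib, y = generate_pairs(tiny_basic_windows, PairSpec(), rng, 400)
        s = siam.score(tiny_basic_windows.windows[ia],
                       tiny_basic_windows.windows[ib])
        assert s[y == 0].mean() < s[y == 1].mean()

    def test_two_runs_same_seed_identical_head(self, tiny_base_model,
                                               tiny_basic_windows):
        heads = []
        for _ in range(2):
            siam = build_siamese(tiny_base_model, np.random.default_rng(12))
            train_siamese(siam, tiny_basic_windows, PairSpec(epochs=5),
                          n_pairs=200, seed=4)
            heads.append((siam.head.W.value.copy(), siam.head.b.value.copy()))
        np.testing.assert_array_equal(heads[0][0], heads[1][0])
        np.testing.assert_array_equal(heads[0][1], heads[1][1])


class TestSia5Classification:
    def test_matching_query_wins_both_modes(self, taxonomy, tiny_base_model):
        siam = build_siamese(tiny_base_model, np.random.default_rng(13))
        # large positive weights: any feature distance -> score near 1,
        # identical pair -> sigmoid(0) = 0.5
        siam.head.W.value[...] = 50.0
        siam.head.b.value[...] = 0.0
        rng = np.random.default_rng(14)
        sample = rng.standard_normal((4, 128))
        queries = {}
        for i, c in enumerate(taxonomy.combined_classes):
            q = rng.standard_normal((5, 4, 128))
            if c == "supination+pinch":
                q[:] = sample       # every round scores this class best
            queries[c] = q
        bank = QueryBank(queries=queries, q=5)
        for mode in ("mean_score", "majority_vote"):
            pred = sia5_classify(siam, bank, sample, taxonomy, mode=mode)
            assert pred[0] == "supination+pinch"

    def test_all_equal_scores_tie_break_lowest_index(self, taxonomy,
                                                     tiny_base_model):
        siam = build_siamese(tiny_base_model, np.random.default_rng(15))
        siam.head.W.value[...] = 0.0
        siam.head.b.value[...] = 0.0
        rng = np.random.default_rng(16)
        bank = QueryBank(queries={c: rng.standard_normal((5, 4, 128))
                                  for c in taxonomy.combined_classes}, q=5)
        pred = sia5_classify(siam, bank, rng.standard_normal((4, 128)),
                             taxonomy)
        assert pred[0] == taxonomy.combined_classes[0]

    def test_incomplete_bank_rejected(self, taxonomy, tiny_base_model):
        siam = build_siamese(tiny_base_model)
        bank = QueryBank(queries={taxonomy.combined_classes[0]:
                                  np.zeros((5, 4, 128))}, q=5)
        with pytest.raises(ValueError, match="lacks class"):
            sia5_classify(siam, bank, np.zeros((4, 128)), taxonomy)

    def test_query_bank_requires_q_per_class(self, taxonomy):
        ws = gain_windows(list(taxonomy.combined_classes), 3, seed=42)
        with pytest.raises(ValueError, match="only 3"):
            build_query_bank(ws, taxonomy, q=5)


class TestFTnet:
    def test_stage_parameter_counts(self, taxonomy, tiny_base_model):
        ft = build_ftnet(tiny_base_model, taxonomy)
        assert count_trainable(ft.net) == 306
        ft.set_stage(2)
        assert count_trainable(ft.net) == 15_456

    def test_stage1_freeze_audit(self, taxonomy, tiny_base_model):
        ft = build_ftnet(tiny_base_model, taxonomy,
                         rng=np.random.default_rng(17))
        before = [p.value.copy() for p in ft.net.params()]
        ws = gain_windows(list(taxonomy.combined_classes), 8, seed=43)
        cfg1 = TrainConfig(epochs=5, batch_size=16, lr=1e-2, patience=None)
        cfg2 = TrainConfig(epochs=0, batch_size=16, lr=1e-4, patience=None)
        ft.set_stage(1)
        from myodecode import nn
        from myodecode.cnn import _as_input
        lut = {c: i for i, c in enumerate(ft.classes)}
        y = np.eye(6)[[lut[l] for l in ws.labels]]
        head = ft.net[OUTPUT_DENSE:]
        from myodecode.task_transfer import _batched, DENSE300_50
        z300 = _batched(ft.net[0:DENSE300_50], _as_input(ws.windows))
        z50 = _batched(ft.net[DENSE300_50:OUTPUT_DENSE], z300)
        nn.fit(head, nn.SigmoidBCE(), z50, y,
               nn.FitConfig(epochs=5, batch_size=16, lr=1e-2, seed=0))
        after = [p.value for p in ft.net.params()]
        n_out_params = 2
        for b, a in zip(before[:-n_out_params], after[:-n_out_params]):
            np.testing.assert_array_equal(b, a)
        assert not np.array_equal(before[-2], after[-2])

    def test_two_stage_training_runs_and_records_history(self, taxonomy,
                                                         tiny_base_model):
        ft = build_ftnet(tiny_base_model, taxonomy,
                         rng=np.random.default_rng(18))
        ws = gain_windows(list(taxonomy.combined_classes), 8, seed=44)
        train_ftnet(ft, ws,
                    stage1=TrainConfig(epochs=5, batch_size=16, lr=1e-2,
                                       patience=None),
                    stage2=TrainConfig(epochs=5, batch_size=16, lr=1e-4,
                                       patience=None))
        assert len(ft.history) == 2
        assert ft.stage == 2

    def test_missing_class_rejected(self, taxonomy, tiny_base_model):
        ft = build_ftnet(tiny_base_model, taxonomy)
        ws = gain_windows(list(taxonomy.combined_classes[:4]), 8, seed=45)
        with pytest.raises(ValueError, match="missing combined classes"):
            train_ftnet(ft, ws)

    def test_empty_target_rejected(self, taxonomy, tiny_base_model):
        ft = build_ftnet(tiny_base_model, taxonomy)
        with pytest.raises(ValueError, match="no target-domain"):
            train_ftnet(ft, WindowSet.empty(4, 128))
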