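import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myodecode.core_data import WindowSet
from myodecode.features import (FEATURE_SETS, ClassicalConfig, FeatureConfig,
                                cepstral_coefficients, compute_feature,
                                compute_feature_table, hjorth_parameters,
                                predict_classical, sample_entropy,
                                scale_features, slope_sign_changes,
                                train_classical, zero_crossings)
from conftest import gain_windows
from _oracles import (cepstra_from_ar, sampen_bruteforce, ssc_bruteforce,
                      yule_walker_coeffs, zc_bruteforce)


class TestScalarFeatures:
    def test_constant_window_closed_forms(self):
        x = np.full(64, 3.0)
        cfg = FeatureConfig(zc_ssc_eps=0.0)
        assert compute_feature(x, "MAV", cfg) == 3.0
        assert compute_feature(x, "IEMG", cfg) == 64 * 3.0
        assert compute_feature(x, "RMS", cfg) == 3.0
        assert compute_feature(x, "WL", cfg) == 0.0
        assert compute_feature(x, "ZC", cfg) == 0.0
        assert compute_feature(x, "SSC", cfg) == 0.0
        with pytest.warns(UserWarning):
            assert compute_feature(x, "HP_A", cfg) == 0.0

    def test_sine_zero_crossings(self):
        # 8 full periods across 512 samples; the 1.5-sample phase offset puts
        # all 16 crossings strictly inside the window, none on a sample
        x = np.sin(2 * np.pi * 8 * (np.arange(512) + 1.5) / 512)
        assert compute_feature(x, "ZC", FeatureConfig(zc_ssc_eps=0.0)) == 16

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError, match="unknown feature"):
            compute_feature(np.ones(10), "XYZ")

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            compute_feature(np.ones(2), "MAV")


class TestSampleEntropy:
    def test_periodic_16_sample_series_matches_bruteforce(self):
        x = np.array([1, 2, 3, 1, 2, 3, 1, 2, 3, 1, 2, 3, 1, 2, 3, 1], float)
        expected = sampen_bruteforce(x, 2, 0.2)
        assert sample_entropy(x, 2, 0.2) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(n=st.integers(10, 64), seed=st.integers(0, 10_000))
    def test_matches_bruteforce_on_random_series(self, n, seed):
        x = np.random.default_rng(seed).standard_normal(n)
        assert sample_entropy(x, 2, 0.2) == pytest.approx(
            sampen_bruteforce(x, 2, 0.2), abs=1e-12)

    def test_zero_variance_sentinel(self):
        with pytest.warns(UserWarning):
            assert sample_entropy(np.ones(32), 2, 0.2) == 0.0


class TestZcSscOracle:
    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000), eps=st.floats(0.0, 0.5))
    def test_counts_match_sign_pattern_oracle(self, seed, eps):
        x = np.random.default_rng(seed).standard_normal(48)
        assert zero_crossings(x, eps) == zc_bruteforce(x, eps)
        assert slope_sign_changes(x, eps) == ssc_bruteforce(x, eps)


class TestHjorth:
    def test_white_noise_more_complex_than_sine(self):
        rng = np.random.default_rng(8)
        noise = rng.standard_normal(512)
        sine = np.sin(2 * np.pi * 10 * np.arange(512) / 512)
        assert hjorth_parameters(noise)[2] > hjorth_parameters(sine)[2]

    def test_activity_is_variance(self):
        x = np.random.default_rng(9).standard_normal(256)
        assert hjorth_parameters(x)[0] == pytest.approx(np.var(x))


class TestCepstral:
    def test_ar1_signal_cc1_matches_yule_walker(self):
        rng = np.random.default_rng(10)
        x = np.zeros(4096)
        for i in range(1, len(x)):           # AR(1), phi = 0.7
            x[i] = 0.7 * x[i - 1] + rng.standard_normal()
        a = yule_walker_coeffs(x, 4)
        expected = cepstra_from_ar(a)
        got = cepstral_coefficients(x, 4)
        np.testing.assert_allclose(got, expected, atol=5e-3)
        assert got[0] == pytest.approx(-a[0], abs=5e-3)
        assert got[0] == pytest.approx(0.7, abs=0.05)


class TestFeatureTables:
    @pytest.mark.parametrize("set_name,n_feats", [
        ("TD", 4), ("ITD", 9), ("CB", 7), ("Full", 15)])
    def test_column_counts(self, set_name, n_feats):
        assert len(FEATURE_SETS[set_name]) == n_feats
        ws = gain_windows(["a", "b"], 3, n_channels=10, window_len=64, seed=1)
        table = compute_feature_table(ws, set_name)
        assert table.frame.shape == (6, n_feats * 10)

    def test_unknown_set_rejected(self):
        ws = gain_windows(["a", "b"], 2, window_len=32)
        with pytest.raises(ValueError, match="unknown feature set"):
            compute_feature_table(ws, "XL")

    def test_channel_permutation_permutes_columns(self):
        ws = gain_windows(["a"], 4, n_channels=3, window_len=64, seed=2)
        perm = [2, 0, 1]
        ws_p = WindowSet(ws.windows[:, perm, :], ws.labels,
                         ws.repetition_ids, ws.orientations, ws.subject_ids,
                         ws.window_len, ws.stride)
        t = compute_feature_table(ws, "TD")
        tp = compute_feature_table(ws_p, "TD")
        for new_c, old_c in enumerate(perm):
            np.testing.assert_allclose(
                tp.frame[[f"{f}_ch{new_c}" for f in FEATURE_SETS["TD"]]].values,
                t.frame[[f"{f}_ch{old_c}" for f in FEATURE_SETS["TD"]]].values)


class TestScaling:
    def test_train_columns_standardized(self):
        ws = gain_windows(["a", "b"], 20, window_len=64, seed=3)
        table = compute_feature_table(ws, "TD")
        scaled, = scale_features(table)
        assert np.all(np.abs(scaled.frame.mean()) < 1e-9)
        # winsorization can only shrink the SD below 1 for clipped columns
        assert np.all(scaled.frame.std(ddof=0) < 1.0 + 1e-9)

    def test_identity_application(self):
        ws = gain_windows(["a", "b"], 10, window_len=64, seed=4)
        t = compute_feature_table(ws, "TD")
        s1, s2 = scale_features(t, t)
        np.testing.assert_allclose(s1.frame.values[np.abs(s1.frame.values) < 3],
                                   s2.frame.values[np.abs(s2.frame.values) < 3])

    def test_outlier_winsorized_before_statistics(self):
        import pandas as pd
        from myodecode.features import FeatureTable
        rng = np.random.default_rng(5)
        col = rng.standard_normal(200)
        col[0] = 10 * col.std() + col.mean()     # 10-SD outlier
        t = FeatureTable(pd.DataFrame({"f_ch0": col}),
                         np.zeros(200, dtype=object))
        scaled, = scale_features(t)
        # the outlier is clipped to the 3-SD boundary before z-scoring
        assert scaled.frame["f_ch0"].max() < 4.0

    def test_zero_sd_column_warns(self):
        import pandas as pd
        from myodecode.features import FeatureTable
        t = FeatureTable(pd.DataFrame({"f_ch0": np.ones(10)}),
                         np.zeros(10, dtype=object))
        with pytest.warns(UserWarning, match="zero-SD"):
            scaled, = scale_features(t)
        assert np.all(scaled.frame.values == 0)


class TestClassicalBaselines:
    @pytest.mark.parametrize("model", ["knn", "svm", "mlp", "lda"])
    def test_separable_clouds_fully_classified(self, model):
        ws = gain_windows(["a", "b"], 52, window_len=64, seed=6,
                          gain_lo=0.1, gain_hi=4.0)
        test_mask = np.arange(ws.n_windows) % 4 == 0
        ws_tr, ws_te = ws.subset(~test_mask), ws.subset(test_mask)
        tr = compute_feature_table(ws_tr, "TD")
        te = compute_feature_table(ws_te, "TD")
        tr, te = scale_features(tr, te)
        clf = train_classical(model, tr, ClassicalConfig(mlp_max_iter=800))
        assert np.mean(predict_classical(clf, te) == te.labels) == 1.0

    def test_single_class_rejected(self):
        ws = gain_windows(["a"], 50, window_len=64, seed=8)
        t, = scale_features(compute_feature_table(ws, "TD"))
        with pytest.raises(ValueError, match="2 classes"):
            train_classical("lda", t)

    def test_knn_needs_enough_rows(self):
        ws = gain_windows(["a", "b"], 10, window_len=64, seed=9)
        t, = scale_features(compute_feature_table(ws, "TD"))
        with pytest.raises(ValueError, match="reduce knn_k"):
            train_classical("knn", t)

    def test_label_permutation_is_chance_level(self):
        rng = np.random.default_rng(11)
        import pandas as pd
        from myodecode.features import FeatureTable
        n, k = 800, 8
        X = pd.DataFrame(rng.standard_normal((n, 6)),
                         columns=[f"f_ch{i}" for i in range(6)])
        y = np.array([f"c{i % k}" for i in range(n)], dtype=object)
        t = FeatureTable(X, rng.permutation(y))
        clf = train_classical("lda", t)
        acc = np.mean(predict_classical(clf, t) == t.labels)
        # permuted labels: in-sample accuracy stays near 1/8
        assert abs(acc - 1 / k) < 4 * np.sqrt((1 / k) * (1 - 1 / k) / n) + 0.02
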