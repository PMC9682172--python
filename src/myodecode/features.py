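"""Handcrafted per-window sEMG features and the classical baseline classifiers.

Fifteen time/frequency features are available, organized into four named sets:

========  ====================================================================
TD        MAV, ZC, SSC, WL                                       (4 features)
ITD       MAV, ZC, SSC, WL, RMS, IEMG, HP_A, HP_M, HP_C          (9)
CB        CC1, ZC, SSC, WL, HP_M, HP_C, SampEn                   (7)
Full      MAV, ZC, SSC, WL, HP_A, HP_M, HP_C, SampEn, CC1-4,
          RMS, IEMG, SKEW                                        (15)
========  ====================================================================

Features are computed per channel; a window set over C channels yields
``|set| * C`` columns named ``<feature>_ch<j>`` in channel-major order.

Cepstral coefficients derive from an order-4 autoregressive fit
(Levinson-Durbin on the biased autocorrelation): with prediction-error
coefficients a_k,  c_1 = -a_1  and  c_n = -a_n - sum_{k=1}^{n-1} (1-k/n) a_k
c_{n-k}.  Sample entropy uses template length m, tolerance r * SD(window) and
excludes self-matches.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .core_data import WindowSet

log = logging.getLogger(__name__)

FEATURE_NAMES = ("MAV", "IEMG", "RMS", "WL", "ZC", "SSC",
                 "HP_A", "HP_M", "HP_C", "SKEW", "SampEn",
                 "CC1", "CC2", "CC3", "CC4")

FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "TD": ("MAV", "ZC", "SSC", "WL"),
    "ITD": ("MAV", "ZC", "SSC", "WL", "RMS", "IEMG", "HP_A", "HP_M", "HP_C"),
    "CB": ("CC1", "ZC", "SSC", "WL", "HP_M", "HP_C", "SampEn"),
    "Full": ("MAV", "ZC", "SSC", "WL", "HP_A", "HP_M", "HP_C", "SampEn",
             "CC1", "CC2", "CC3", "CC4", "RMS", "IEMG", "SKEW"),
}


@dataclass(frozen=True)
class FeatureConfig:
    zc_ssc_eps: float | None = None   # None -> 0.01 * SD(window)
    sampen_m: int = 2
    sampen_r: float = 0.2             # fraction of window SD
    ar_order: int = 4

    def __post_init__(self):
        if self.sampen_m < 1 or not (0 < self.sampen_r < 1) or self.ar_order != 4:
            raise ValueError("invalid feature configuration")


def _eps_for(x: np.ndarray, cfg: FeatureConfig) -> float:
    return 0.01 * x.std() if cfg.zc_ssc_eps is None else cfg.zc_ssc_eps


def zero_crossings(x: np.ndarray, eps: float = 0.0) -> int:
    """Sign changes between consecutive samples whose step exceeds eps."""
    x = np.asarray(x, dtype=float)
    sign_change = x[:-1] * x[1:] < 0
    big_enough = np.abs(x[:-1] - x[1:]) >= eps
    return int(np.count_nonzero(sign_change & big_enough))


def slope_sign_changes(x: np.ndarray, eps: float = 0.0) -> int:
    """Slope-sign changes where both adjacent differences exceed eps."""
    x = np.asarray(x, dtype=float)
    d1 = x[1:-1] - x[:-2]
    d2 = x[1:-1] - x[2:]
    return int(np.count_nonzero((d1 * d2 > 0)
                                & (np.abs(d1) >= eps) & (np.abs(d2) >= eps)))


def hjorth_parameters(x: np.ndarray) -> tuple[float, float, float]:
    """(Activity, Mobility, Complexity) with first-difference derivatives.

    Zero-variance input yields the (0, 0, 0) sentinel with a warning.
    """
    x = np.asarray(x, dtype=float)
    var0 = x.var()
    if var0 == 0:
        warnings.warn("zero-variance window: Hjorth parameters undefined, returning 0")
        return 0.0, 0.0, 0.0
    d1 = np.diff(x)
    var1 = d1.var()
    mobility = np.sqrt(var1 / var0)
    d2 = np.diff(d1)
    if var1 == 0:
        return float(var0), float(mobility), 0.0
    complexity = np.sqrt(d2.var() / var1) / mobility
    return float(var0), float(mobility), float(complexity)


def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """SampEn(m, r): -ln(A/B) over Chebyshev template matches, no self-matches.

    ``r`` is a fraction of the window standard deviation.  Degenerate inputs
    (zero variance, or no matches at either length) return the 0 sentinel
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < m + 2:
        raise ValueError(f"series of length {n} too short for m={m}")
    sd = x.std()
    if sd == 0:
        warnings.warn("zero-variance window: SampEn undefined, returning 0")
        return 0.0
    tol = r * sd
    # restrict both template lengths to the n-m templates so that counts
    # are comparable (standard convention)
    nb = n - m
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[:nb]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:nb]
    b = a = 0
    for i in range(nb - 1):
        db = np.abs(tm[i + 1:] - tm[i]).max(axis=1)
        da = np.abs(tm1[i + 1:] - tm1[i]).max(axis=1)
        b += int(np.count_nonzero(db <= tol))
        a += int(np.count_nonzero(da <= tol))
    if b == 0 or a == 0:
        warnings.warn("no template matches: SampEn undefined, returning 0")
        return 0.0
    return float(-np.log(a / b))


def levinson_durbin(r: np.ndarray, order: int) -> np.ndarray:
    """Prediction-error filter coefficients a_1..a_p from autocorrelation r.

    Convention: A(z) = 1 + a_1 z^-1 + ... + a_p z^-p minimizes the forward
    prediction error, i.e. x_t ~ -sum_k a_k x_{t-k}.
    """
    a = np.zeros(order)
    err = r[0]
    if err == 0:
        return a
    for i in range(order):
        acc = r[i + 1] + a[:i] @ r[i:0:-1][:i]
        k = -acc / err
        a_new = a.copy()
        a_new[i] = k
        a_new[:i] = a[:i] + k * a[i - 1::-1][:i]
        a = a_new
        err *= (1 - k ** 2)
        if err <= 0:
            break
    return a


def cepstral_coefficients(x: np.ndarray, order: int = 4) -> np.ndarray:
    """CC1..CC_order from the AR(order) fit of the window."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    r = np.array([xc[:n - k] @ xc[k:] for k in range(order + 1)]) / n  # biased
    if r[0] == 0:
        warnings.warn("zero-variance window: cepstral coefficients undefined, returning 0")
        return np.zeros(order)
    a = levinson_durbin(r, order)
    c = np.zeros(order)
    c[0] = -a[0]
    for nn in range(2, order + 1):
        s = sum((1 - k / nn) * a[k - 1] * c[nn - k - 1] for k in range(1, nn))
        c[nn - 1] = -a[nn - 1] - s
    return c


def compute_feature(x: np.ndarray, name: str,
                    cfg: FeatureConfig = FeatureConfig()) -> float:
    """A single scalar feature of a single-channel window."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3 or not np.all(np.isfinite(x)):
        raise ValueError("window must be finite and have length >= 3")
    if name == "MAV":
        return float(np.mean(np.abs(x)))
    if name == "IEMG":
        return float(np.sum(np.abs(x)))
    if name == "RMS":
        return float(np.sqrt(np.mean(x ** 2)))
    if name == "WL":
        return float(np.sum(np.abs(np.diff(x))))
    if name == "ZC":
        return float(zero_crossings(x, _eps_for(x, cfg)))
    if name == "SSC":
        return float(slope_sign_changes(x, _eps_for(x, cfg)))
    if name in ("HP_A", "HP_M", "HP_C"):
        act, mob, comp = hjorth_parameters(x)
        return {"HP_A": act, "HP_M": mob, "HP_C": comp}[name]
    if name == "SKEW":
        if x.std() == 0:
            warnings.warn("zero-variance window: skewness undefined, returning 0")
            return 0.0
        return float(stats.skew(x, bias=False))
    if name == "SampEn":
        return sample_entropy(x, cfg.sampen_m, cfg.sampen_r)
    if name.startswith("CC"):
        k = int(name[2:])
        if not 1 <= k <= cfg.ar_order:
            raise ValueError(f"unknown feature {name!r}")
        return float(cepstral_coefficients(x, cfg.ar_order)[k - 1])
    raise ValueError(f"unknown feature {name!r}")


@dataclass
class FeatureTable:
    """Per-window feature matrix with aligned labels and scaling statistics."""

    frame: pd.DataFrame
    labels: np.ndarray
    scale_mean: pd.Series | None = None
    scale_std: pd.Series | None = None

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)


def compute_feature_table(ws: WindowSet, set_name: str = "Full",
                          cfg: FeatureConfig = FeatureConfig()) -> FeatureTable:
    """All features of a named set for every window/channel.

    Columns are channel-major: all features of channel 0, then channel 1, ...
    """
    if set_name not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {set_name!r}; "
                         f"choose from {sorted(FEATURE_SETS)}")
    feats = FEATURE_SETS[set_name]
    n, n_ch = ws.n_windows, ws.n_channels
    cols = [f"{f}_ch{c}" for c in range(n_ch) for f in feats]
    mat = np.zeros((n, len(cols)))
    needs_cc = any(f.startswith("CC") for f in feats)
    for i in range(n):
        j = 0
        for c in range(n_ch):
            x = ws.windows[i, c]
            cc = cepstral_coefficients(x, cfg.ar_order) if needs_cc else None
            for f in feats:
                if f.startswith("CC"):
                    mat[i, j] = cc[int(f[2:]) - 1]
                else:
                    mat[i, j] = compute_feature(x, f, cfg)
                j += 1
    return FeatureTable(pd.DataFrame(mat, columns=cols), np.asarray(ws.labels))


def scale_features(train: FeatureTable, *apply_to: FeatureTable,
                   winsor_sd: float = 3.0) -> tuple[FeatureTable, ...]:
    """Column z-scoring with train statistics; 3-SD winsorization first.

    Train values beyond ``winsor_sd`` standard deviations are clipped before
    the scaling mean/SD are computed (keeps row/label alignment, bounds the
    influence of outliers).  Test tables are transformed with the train
    statistics only.  Zero-SD columns are scaled by 1 with a warning.
    """
    if train.frame.empty:
        raise ValueError("empty training feature table")
    raw = train.frame
    mu0, sd0 = raw.mean(), raw.std(ddof=0)
    lo, hi = mu0 - winsor_sd * sd0, mu0 + winsor_sd * sd0
    wins = raw.clip(lo, hi, axis=1)
    n_clipped = int((raw.lt(lo, axis=1) | raw.gt(hi, axis=1)).to_numpy().sum())
    if n_clipped:
        log.info("winsorized %d feature values beyond %.1f SD", n_clipped, winsor_sd)
    mu, sd = wins.mean(), wins.std(ddof=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-SD feature columns scaled by 1")
        sd = sd.mask(zero, 1.0)
    out = []
    for t in (train,) + apply_to:
        scaled = (t.frame.clip(lo, hi, axis=1) if t is train else t.frame)
        scaled = (scaled - mu) / sd
        out.append(FeatureTable(scaled, t.labels, scale_mean=mu, scale_std=sd))
    return tuple(out)


@dataclass(frozen=True)
class ClassicalConfig:
    knn_k: int = 40
    svm_c: float = 1.0
    mlp_hidden: int = 300
    mlp_lr: float = 1e-4
    mlp_max_iter: int = 300
    seed: int = 0


CLASSICAL_MODELS = ("knn", "svm", "mlp", "lda")


def make_classical(name: str, cfg: ClassicalConfig = ClassicalConfig()):
    """Instantiate one of the four reference classifiers."""
    name = name.lower()
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=cfg.knn_k, metric="euclidean")
    if name == "svm":
        return SVC(kernel="linear", C=cfg.svm_c)
    if name == "mlp":
        return MLPClassifier(hidden_layer_sizes=(cfg.mlp_hidden,),
                             activation="tanh", learning_rate_init=cfg.mlp_lr,
                             max_iter=cfg.mlp_max_iter, random_state=cfg.seed)
    if name == "lda":
        return LinearDiscriminantAnalysis()
    raise ValueError(f"unknown classical model {name!r}")


def train_classical(name: str, table: FeatureTable,
                    cfg: ClassicalConfig = ClassicalConfig()):
    """Fit a reference classifier on a scaled feature table."""
    y = np.asarray(table.labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    if name.lower() == "knn" and len(y) < cfg.knn_k:
        raise ValueError(
            f"KNN with k={cfg.knn_k} needs >= {cfg.knn_k} training rows "
            f"(got {len(y)}); reduce knn_k")
    model = make_classical(name, cfg)
    model.fit(table.values, y)
    return model


def predict_classical(model, table: FeatureTable) -> np.ndarray:
    return model.predict(table.values)
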