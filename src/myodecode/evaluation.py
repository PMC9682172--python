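"""Accuracy metrics and the multi-method statistical comparison procedure.

Methods are compared across subjects with a Friedman rank test followed by
post-hoc pairwise Wilcoxon signed-rank tests of a reference method against
every other method, with Holm's step-down correction applied as adjusted
significance thresholds: after sorting the m pairwise p-values ascending, the
i-th smallest is tested against alpha / (m - i + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion


def accuracy(true_labels, predicted_labels) -> float:
    """Fraction of correct classifications."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if len(t) == 0 or len(t) != len(p):
        raise ValueError(f"label vectors must be nonempty and equal length "
                         f"({len(t)} vs {len(p)})")
    return float(np.mean(t == p))


def confusion(true_labels, predicted_labels,
              classes: list[str] | None = None) -> pd.DataFrame:
    """Row-per-true-class confusion counts."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if len(t) == 0 or len(t) != len(p):
        raise ValueError("label vectors must be nonempty and equal length")
    if classes is None:
        classes = sorted(set(t) | set(p))
    mat = _sk_confusion(t, p, labels=classes)
    return pd.DataFrame(mat, index=classes, columns=classes)


def holm_thresholds(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Adjusted thresholds alpha/(m-i+1) aligned with the input order.

    The smallest p-value gets alpha/m, the largest alpha/1.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    thr = np.empty(m)
    thr[order] = alpha / (m - np.arange(m))
    return thr


def holm_significant(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Step-down decisions: reject while p_(i) <= alpha/(m-i+1), then stop."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sig = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            sig[idx] = True
        else:
            break
    return sig


@dataclass
class PairwiseResult:
    method: str
    p_value: float
    holm_alpha: float
    significant: bool


@dataclass
class ComparisonReport:
    reference: str
    friedman_p: float
    pairwise: list[PairwiseResult]
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"method": r.method, "p_value": r.p_value,
                              "holm_alpha": r.holm_alpha,
                              "significant": r.significant}
                             for r in self.pairwise])


def _safe_wilcoxon(a: np.ndarray, b: np.ndarray) -> float:
    diff = a - b
    diff = diff[diff != 0]          # drop zero differences (standard convention)
    if len(diff) == 0:
        warnings.warn("all paired differences are zero; Wilcoxon p set to 1")
        return 1.0
    # exact distribution for small samples, normal approx with correction above
    method = "exact" if len(diff) <= 25 else "approx"
    try:
        res = stats.wilcoxon(diff, zero_method="wilcox", correction=True,
                             method=method)
    except ValueError as exc:
        warnings.warn(f"degenerate Wilcoxon comparison ({exc}); p set to 1")
        return 1.0
    return float(res.pvalue)


def compare_methods(acc: pd.DataFrame, reference: str,
                    alpha: float = 0.05) -> ComparisonReport:
    """Friedman across methods + reference-vs-others Wilcoxon with Holm.

    ``acc`` has one row per subject and one column per method, entries are
    test accuracies.
    """
    if reference not in acc.columns:
        raise ValueError(f"reference method {reference!r} not in accuracy table")
    if acc.shape[1] < 2:
        raise ValueError("need at least 2 methods to compare")
    if acc.isna().to_numpy().any():
        raise ValueError("accuracy table has missing entries")
    if acc.shape[0] < 5:
        warnings.warn("fewer than 5 subjects: rank tests have little power")
    if acc.shape[1] >= 3:
        friedman_p = float(stats.friedmanchisquare(
            *[acc[c].to_numpy() for c in acc.columns]).pvalue)
    else:
        friedman_p = _safe_wilcoxon(acc.iloc[:, 0].to_numpy(),
                                    acc.iloc[:, 1].to_numpy())
    others = [c for c in acc.columns if c != reference]
    ref = acc[reference].to_numpy()
    p_vals = np.array([_safe_wilcoxon(ref, acc[c].to_numpy()) for c in others])
    thr = holm_thresholds(p_vals, alpha)
    sig = holm_significant(p_vals, alpha)
    pairwise = [PairwiseResult(method=c, p_value=float(p), holm_alpha=float(t),
                               significant=bool(s))
                for c, p, t, s in zip(others, p_vals, thr, sig)]
    return ComparisonReport(reference=reference, friedman_p=friedman_p,
                            pairwise=pairwise, alpha=alpha)
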