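"""Statistical comparison machinery for classifier probes.

Three tools are used throughout the study:

* a dummy (modal-class) baseline accuracy,
* the 5x2cv paired t-test of Dietterich for comparing two classification
  procedures on the same data (five replicated 2-fold cross-validations;
  the statistic has 5 degrees of freedom),
* a plain one-sample t-test (used to check that 50% activation subsampling
  preserves the mean activation).

The tests are implemented from their defining formulas so they can be
cross-checked against scipy/statsmodels in the test-suite, and so the
degenerate zero-variance cases have an explicit, documented contract.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests


def dummy_accuracy(labels: Sequence) -> float:
    """Accuracy of the classifier that always predicts the modal class."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    _, counts = np.unique(labels, return_counts=True)
    return counts.max() / labels.size


class TTestResult(NamedTuple):
    t: float
    p: float
    degenerate: bool = False


def one_sample_ttest(values: Sequence[float], mu: float) -> TTestResult:
    """Two-sided one-sample t-test of ``mean(values) == mu``.

    Zero-spread conventions: if the sample standard deviation is zero the
    test is degenerate; ``t = 0, p = 1`` when the mean equals ``mu`` exactly
    and ``p = 0`` (with the degeneracy flag set) otherwise.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values")
    n = values.size
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0.0:
        if mean == mu:
            return TTestResult(0.0, 1.0, False)
        return TTestResult(np.inf if mean > mu else -np.inf, 0.0, True)
    t = (mean - mu) / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return TTestResult(float(t), float(p), False)


@dataclass
class PairedCVTestResult:
    """Outcome of the 5x2cv paired t-test (df = 5).

    ``diffs[r, f]`` is accuracy(A) - accuracy(B) for fold ``f`` of
    replication ``r``; ``accs_a``/``accs_b`` record the raw accuracies.
    """

    t_statistic: float
    p_value: float
    diffs: np.ndarray
    accs_a: np.ndarray
    accs_b: np.ndarray
    df: int = 5
    degenerate: bool = False

    def __post_init__(self) -> None:
        assert self.diffs.shape == (self.df, 2)


def _replication_seed(seed: int, r: int) -> int:
    # deterministic child seed < 2**31, order-independent in (seed, r)
    return int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31))


def _fit_predict_acc(proc, X_tr, y_tr, X_te, y_te) -> float:
    try:
        model = clone(proc)
    except TypeError:
        model = copy.deepcopy(proc)
    model.fit(X_tr, y_tr)
    return float(np.mean(model.predict(X_te) == y_te))


def ttest_5x2cv_from_accuracies(
    accs_a: np.ndarray, accs_b: np.ndarray
) -> tuple[float, float, bool]:
    """Statistic and p-value from two 5x2 accuracy tables.

    t = d_11 / sqrt((1/5) * sum_r s_r^2), with s_r^2 the variance of the two
    fold differences of replication r; two-sided p from t with 5 df.
    """
    accs_a = np.asarray(accs_a, dtype=float).reshape(5, 2)
    accs_b = np.asarray(accs_b, dtype=float).reshape(5, 2)
    d = accs_a - accs_b
    dbar = d.mean(axis=1, keepdims=True)
    s2 = ((d - dbar) ** 2).sum(axis=1)  # per-replication variance of the 2 diffs
    denom = np.sqrt(s2.mean())
    num = d[0, 0]
    if denom == 0.0:
        if num == 0.0:
            return 0.0, 1.0, False
        return (np.inf if num > 0 else -np.inf), 0.0, True
    t = num / denom
    p = 2.0 * sps.t.sf(abs(t), df=5)
    return float(t), float(p), False


def paired_5x2cv_ttest(
    procedure_a,
    procedure_b,
    features: np.ndarray,
    labels: Sequence,
    seed: int = 0,
) -> PairedCVTestResult:
    """Compare two fit/predict procedures with five seeded 2-fold CVs.

    Both procedures are trained and evaluated on identical splits. The
    numerator of the statistic is the first fold-difference of the first
    replication (replication order is determined by ``seed``).
    """
    X = np.asarray(features)
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 4:
        raise ValueError("need at least 2 samples per class in each half (>=4 total)")
    accs_a = np.empty((5, 2))
    accs_b = np.empty((5, 2))
    for r in range(5):
        skf = StratifiedKFold(n_splits=2, shuffle=True,
                              random_state=_replication_seed(seed, r))
        for f, (tr, te) in enumerate(skf.split(X, y)):
            accs_a[r, f] = _fit_predict_acc(procedure_a, X[tr], y[tr], X[te], y[te])
            accs_b[r, f] = _fit_predict_acc(procedure_b, X[tr], y[tr], X[te], y[te])
    t, p, degen = ttest_5x2cv_from_accuracies(accs_a, accs_b)
    return PairedCVTestResult(
        t_statistic=t,
        p_value=p,
        diffs=accs_a - accs_b,
        accs_a=accs_a,
        accs_b=accs_b,
        degenerate=degen,
    )


def comparison_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-layer test results, adding a Holm-corrected column.

    Each row dict must carry at least ``comparison``, ``layer``, ``t`` and
    ``p``. No correction is applied to ``p`` itself; ``p_holm`` is emitted
    alongside for transparency.
    """
    df = pd.DataFrame(rows)
    if len(df):
        df["p_holm"] = multipletests(df["p"].to_numpy(), method="holm")[1]
    else:
        df["p_holm"] = []
    return df
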