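"""Exhaustive feature-subset evaluation of the LOOCV classifier.

Every nonempty subset of the d features (2^d - 1 = 511 for d = 9) gets its
own leave-one-out cross-validation; a subset is flagged significant when its
correct-fold count reaches the exact two-sided sign-test threshold, and the
count of significant subsets is itself tested against Binomial(2^d - 1, 0.05).
Per-metric aggregation then summarizes the accuracy of every subset containing
a given metric (2^(d-1) subsets each).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import UndefinedStatisticError
from .svm import _loo_folds, loocv

__all__ = [
    "enumerate_subsets",
    "sign_test_p",
    "sign_test_threshold",
    "binomial_count_p",
    "SubsetEvaluation",
    "ExhaustiveResult",
    "run_exhaustive",
    "aggregate_by_metric",
    "compare_metric_accuracies",
    "accuracy_vs_chance",
]


def enumerate_subsets(d: int) -> np.ndarray:
    """All 2^d - 1 nonempty feature masks in binary-counter order.

    Row k (from 0) is the bit pattern of k+1, least-significant bit = first
    feature; deterministic and duplicate-free by construction.
    """
    if d < 1:
        raise ValueError("need at least one feature")
    codes = np.arange(1, 2**d, dtype=np.int64)
    return (codes[:, None] >> np.arange(d)) & 1 == 1


def sign_test_p(k: int, n: int) -> float:
    """Exact two-sided sign-test p-value: 2 * min(P(X<=k), P(X>=k)), capped at 1,
    for X ~ Binomial(n, 1/2)."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    lo = stats.binom.cdf(k, n, 0.5)
    hi = stats.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lo, hi)))


def sign_test_threshold(n: int, alpha: float = 0.05, rounding: str | None = "2dp") -> int:
    """Smallest correct-fold count judged significant by the two-sided sign test.

    ``rounding="2dp"`` compares the p-value rounded to two decimals against
    alpha (so e.g. p = 0.0501 at 22/32 counts as significant); ``rounding=None``
    uses the exact p.  Both policies are first-class because the boundary case
    differs between them.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    for k in range(int(np.ceil(n / 2)), n + 1):
        p = sign_test_p(k, n)
        if rounding == "2dp":
            p = round(p, 2)
        elif rounding is not None:
            raise ValueError(f"unknown rounding policy {rounding!r}")
        if p <= alpha:
            return k
    return n + 1  # no attainable count is significant


def binomial_count_p(count: int, n_tests: int, p0: float = 0.05) -> float:
    """Two-sided exact binomial test of a significant-subset count vs. p0."""
    lo = stats.binom.cdf(count, n_tests, p0)
    hi = stats.binom.sf(count - 1, n_tests, p0)
    return float(min(1.0, 2.0 * min(lo, hi)))


@dataclass
class SubsetEvaluation:
    """Cross-validation outcome for one feature subset."""

    mask: np.ndarray
    n_correct: int
    accuracy: float
    significant: bool

    @property
    def bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.mask)


@dataclass
class ExhaustiveResult:
    evaluations: list[SubsetEvaluation]
    threshold: int
    n_significant: int = field(init=False)
    binomial_p: float = field(init=False)

    def __post_init__(self):
        self.n_significant = sum(e.significant for e in self.evaluations)
        self.binomial_p = binomial_count_p(self.n_significant, len(self.evaluations))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subset": [e.bitstring for e in self.evaluations],
                "n_correct": [e.n_correct for e in self.evaluations],
                "accuracy": [e.accuracy for e in self.evaluations],
                "significant": [e.significant for e in self.evaluations],
            }
        )


def run_exhaustive(
    X,
    y,
    alpha: float = 0.05,
    scale: bool = True,
    rounding: str | None = "2dp",
    penalty_scale: float = 1.0,
) -> ExhaustiveResult:
    """LOOCV every nonempty feature subset and test the significant count.

    All subsets share one leave-one-out fold partition (and per-fold
    standardization, which is feature-wise and therefore mask-independent).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    d = X.shape[1]
    folds = _loo_folds(X, y, scale)
    thr = sign_test_threshold(len(y), alpha=alpha, rounding=rounding)
    evals = []
    for mask in enumerate_subsets(d):
        res = loocv(X, y, feature_mask=mask, scale=scale,
                    penalty_scale=penalty_scale, _folds=folds)
        evals.append(
            SubsetEvaluation(
                mask=mask.copy(),
                n_correct=res.n_correct,
                accuracy=res.accuracy,
                significant=res.n_correct >= thr,
            )
        )
    return ExhaustiveResult(evaluations=evals, threshold=thr)


def aggregate_by_metric(
    result: ExhaustiveResult | list[SubsetEvaluation],
    feature_names,
    mean_ranks=None,
) -> pd.DataFrame:
    """Per-metric summary over all subsets containing that metric.

    Returns mean/SD accuracy and significant-subset count over the 2^(d-1)
    subsets including each feature; optionally merges full-model mean
    feature-weight ranks (and their rank-of-means order).
    """
    evals = result.evaluations if isinstance(result, ExhaustiveResult) else result
    feature_names = list(feature_names)
    d = len(feature_names)
    if len(evals) != 2**d - 1:
        raise ValueError(
            f"expected a complete evaluation of {2**d - 1} subsets, got {len(evals)}"
        )
    masks = np.vstack([e.mask for e in evals])
    accs = np.array([e.accuracy for e in evals])
    sig = np.array([e.significant for e in evals])
    rows = []
    for j, name in enumerate(feature_names):
        inc = masks[:, j]
        rows.append(
            {
                "metric": name,
                "mean_accuracy": accs[inc].mean(),
                "sd_accuracy": accs[inc].std(ddof=1),
                "n_subsets": int(inc.sum()),
                "n_significant": int(sig[inc].sum()),
            }
        )
    frame = pd.DataFrame(rows).set_index("metric")
    if mean_ranks is not None:
        frame["mean_weight_rank"] = np.asarray(mean_ranks, dtype=float)
        frame["rank_of_mean_rank"] = (
            frame["mean_weight_rank"].rank(method="average").astype(float)
        )
    return frame


def compare_metric_accuracies(a, b, n_perm: int = 100_000, seed=None):
    """Permutation two-sample t-test between two accuracy lists.

    Shared contract with :func:`connectoclass.inference.permutation_t`.
    """
    from .inference import permutation_t

    return permutation_t(a, b, n_perm=n_perm, seed=seed)


def accuracy_vs_chance(accuracies, chance: float = 0.5) -> tuple[float, int, float]:
    """One-sample t-test of subset accuracies against chance; returns (t, df, p)."""
    accs = np.asarray(accuracies, dtype=float)
    if accs.size < 2:
        raise ValueError("need at least two accuracies")
    if np.ptp(accs) == 0:
        if accs[0] == chance:
            raise UndefinedStatisticError(
                "t statistic undefined: zero variance at the null value"
            )
        raise UndefinedStatisticError("t statistic undefined: zero variance")
    t, p = stats.ttest_1samp(accs, chance)
    return float(t), accs.size - 1, float(p)
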