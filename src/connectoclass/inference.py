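"""Permutation-based two-sample inference, FDR control and clinical correlations.

The group-comparison test shuffles the group labels ``n_perm`` times and
compares each shuffle's two-sample t-test p-value with the observed one; the
reported permutation p uses the add-one estimator
``(#{p_shuffle <= p_obs} + 1) / (n_perm + 1)`` (never exactly zero), with the
raw proportion available as an option.  With fixed group sizes this is
equivalent to comparing |t| values.  Multiplicity over metrics or regions is
handled by the Benjamini-Hochberg step-up procedure at q = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import UndefinedStatisticError
from .metrics import FEATURE_NAMES, degree_centrality

__all__ = [
    "PermutationTestResult",
    "permutation_t",
    "fdr_bh",
    "univariate_metric_tests",
    "regional_degree_tests",
    "clinical_correlations",
]


@dataclass
class PermutationTestResult:
    statistic: float  # observed two-sample t
    parametric_p: float  # p of the observed t under the t distribution
    p: float  # permutation p
    n_perm: int


def _t_columns(x_a: np.ndarray, x_b: np.ndarray, equal_var: bool) -> np.ndarray:
    """Two-sample t statistics column-wise; inputs (n_a, m) and (n_b, m)."""
    n_a, n_b = x_a.shape[0], x_b.shape[0]
    mean_diff = x_a.mean(axis=0) - x_b.mean(axis=0)
    va = x_a.var(axis=0, ddof=1)
    vb = x_b.var(axis=0, ddof=1)
    if equal_var:
        sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
        se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    else:
        se = np.sqrt(va / n_a + vb / n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        return mean_diff / se


def _perm_pvalues(
    values: np.ndarray,
    n_a: int,
    n_perm: int,
    rng: np.random.Generator,
    equal_var: bool,
    df: float,
) -> np.ndarray:
    """Two-sided t-test p-values for label shuffles of a (n, m) value matrix."""
    n, m = values.shape
    out = np.empty((n_perm, m))
    # vectorize over permutations in blocks to bound memory
    block = max(1, int(2_000_000 / max(n * m, 1)))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        idx = np.argsort(rng.random((b, n)), axis=1)  # b random permutations
        perm_a = values[idx[:, :n_a]]  # (b, n_a, m)
        perm_b = values[idx[:, n_a:]]
        n_b = n - n_a
        mean_diff = perm_a.mean(axis=1) - perm_b.mean(axis=1)
        va = perm_a.var(axis=1, ddof=1)
        vb = perm_b.var(axis=1, ddof=1)
        if equal_var:
            sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n - 2)
            se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
        else:
            se = np.sqrt(va / n_a + vb / n_b)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean_diff / se
        out[done : done + b] = 2.0 * stats.t.sf(np.abs(t), df)
        done += b
    return out


def permutation_t(
    x,
    y,
    n_perm: int = 100_000,
    seed=None,
    equal_var: bool = True,
    estimator: str = "add-one",
) -> PermutationTestResult:
    """Permutation two-sample two-tailed t-test of x vs. y.

    Parameters
    ----------
    n_perm : number of random label shuffles (default 100,000).
    estimator : ``"add-one"`` reports (count + 1)/(n_perm + 1);
        ``"proportion"`` reports count/n_perm.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if estimator not in ("add-one", "proportion"):
        raise ValueError(f"unknown estimator {estimator!r}")
    res = _permutation_t_columns(
        np.concatenate([x, y])[:, None], x.size, n_perm, seed, equal_var, estimator
    )
    return PermutationTestResult(
        statistic=float(res["t"][0]),
        parametric_p=float(res["parametric_p"][0]),
        p=float(res["p"][0]),
        n_perm=n_perm,
    )


def _permutation_t_columns(
    values: np.ndarray,
    n_a: int,
    n_perm: int,
    seed,
    equal_var: bool = True,
    estimator: str = "add-one",
) -> dict[str, np.ndarray]:
    """Shared-permutation version for an (n, m) matrix of m simultaneous tests."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = values.shape[0]
    n_b = n - n_a
    df = n - 2 if equal_var else None
    t_obs = _t_columns(values[:n_a], values[n_a:], equal_var)
    if not np.all(np.isfinite(t_obs)):
        raise UndefinedStatisticError(
            "t statistic undefined: zero pooled variance in some column"
        )
    if not equal_var:
        # Welch df per column, observed labels
        va = values[:n_a].var(axis=0, ddof=1) / n_a
        vb = values[n_a:].var(axis=0, ddof=1) / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p_obs = 2.0 * stats.t.sf(np.abs(t_obs), df)
    perm_p = _perm_pvalues(values, n_a, n_perm, rng, equal_var, df)
    count = np.nansum(perm_p <= p_obs[None, :], axis=0)
    if estimator == "add-one":
        p = (count + 1.0) / (n_perm + 1.0)
    else:
        p = count / float(n_perm)
    return {"t": t_obs, "parametric_p": p_obs, "p": p}


def fdr_bh(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at FDR level q.

    Sort ascending, find the largest rank i with p_(i) <= (i/m) q, flag all
    hypotheses with rank <= i.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) / m) * q
    flags = np.zeros(m, dtype=bool)
    if below.any():
        cutoff = int(np.max(np.nonzero(below)[0]))
        flags[order[: cutoff + 1]] = True
    return flags


def univariate_metric_tests(
    features: pd.DataFrame,
    y,
    n_perm: int = 100_000,
    seed=None,
    q: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Permutation t-test per global metric (control vs. patient) with BH-FDR.

    ``y`` uses +1 for controls, -1 for patients; the reported group columns
    follow that convention.
    """
    y = np.asarray(y)
    x = np.asarray(features, dtype=float)
    ctl = x[y == 1]
    mdd = x[y == -1]
    values = np.vstack([ctl, mdd])
    res = _permutation_t_columns(values, ctl.shape[0], n_perm, seed, equal_var)
    frame = pd.DataFrame(
        {
            "ctl_mean": ctl.mean(axis=0),
            "ctl_sd": ctl.std(axis=0, ddof=1),
            "mdd_mean": mdd.mean(axis=0),
            "mdd_sd": mdd.std(axis=0, ddof=1),
            "t": res["t"],
            "p": res["p"],
        },
        index=list(features.columns) if hasattr(features, "columns") else list(FEATURE_NAMES),
    )
    frame["fdr_significant"] = fdr_bh(frame["p"].to_numpy(), q=q)
    return frame


def regional_degree_tests(
    adjacency_stack,
    y,
    region_labels=None,
    n_perm: int = 100_000,
    seed=None,
    q: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-region degree-centrality group comparison (one test per node).

    Permutation t-test per region with BH-FDR over all regions; output rows
    are atlas-aligned with group means/SDs, p and the FDR flag.
    """
    stack = np.asarray(adjacency_stack)
    y = np.asarray(y)
    degrees = np.vstack([degree_centrality(a) for a in stack]).astype(float)
    ctl = degrees[y == 1]
    mdd = degrees[y == -1]
    values = np.vstack([ctl, mdd])
    res = _permutation_t_columns(values, ctl.shape[0], n_perm, seed, equal_var)
    if region_labels is None:
        region_labels = [f"node_{i:02d}" for i in range(stack.shape[-1])]
    frame = pd.DataFrame(
        {
            "region": list(region_labels),
            "ctl_mean": ctl.mean(axis=0),
            "ctl_sd": ctl.std(axis=0, ddof=1),
            "mdd_mean": mdd.mean(axis=0),
            "mdd_sd": mdd.std(axis=0, ddof=1),
            "t": res["t"],
            "p": res["p"],
        }
    )
    frame["fdr_significant"] = fdr_bh(frame["p"].to_numpy(), q=q)
    return frame


def clinical_correlations(values, covariates: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of a metric with each clinical covariate.

    Missing covariate entries are dropped pairwise; each correlation needs at
    least three paired observations.  Returns r, two-sided p and the pair
    count per covariate.
    """
    v = np.asarray(values, dtype=float)
    rows = []
    for col in covariates.columns:
        c = covariates[col].to_numpy(dtype=float)
        ok = np.isfinite(v) & np.isfinite(c)
        if ok.sum() < 3:
            raise ValueError(f"covariate {col!r}: fewer than 3 paired observations")
        if np.ptp(v[ok]) == 0 or np.ptp(c[ok]) == 0:
            raise UndefinedStatisticError(
                f"correlation with {col!r} undefined: zero variance"
            )
        r, p = stats.pearsonr(v[ok], c[ok])
        rows.append({"covariate": col, "r": float(r), "p": float(p), "n": int(ok.sum())})
    return pd.DataFrame(rows).set_index("covariate")
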