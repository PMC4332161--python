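"""Class-weighted soft-margin linear SVM with squared slack penalties.

The classifier solves

    min_{w, b, v}  1/2 <w, w> + sum_i D_i v_i^2
    s.t.           y_i (<w, x_i> + b) >= 1 - v_i,   v_i >= 0

with per-sample penalty ``D_i = N / (2 N_G(i))`` where ``N_G(i)`` is the size
of sample i's group, so each class contributes equal total penalty mass
(``sum over a class of D_i = N/2``).  Note the **squared** (L2) slack
penalty: most library defaults use the L1 hinge instead and are not
equivalent.

Because the slack enters squared, the nonnegativity constraint is slack at
the optimum and the problem is equivalent to the smooth unconstrained primal

    F(w, b) = 1/2 ||w||^2 + sum_i D_i max(0, 1 - y_i(<w, x_i> + b))^2,

a strictly convex piecewise-quadratic, minimized here by a finite active-set
Newton iteration (deterministic, no randomness in fitting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "penalty_weights",
    "ClassWeightedL2SVM",
    "fit_svm",
    "CVResult",
    "loocv",
    "feature_weight_ranks",
]


def penalty_weights(y: np.ndarray) -> np.ndarray:
    """Per-sample penalty D_i = N / (2 N_G(i)); requires both classes present."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.size}")
    n = y.size
    per_class = {c: n / (2.0 * k) for c, k in zip(classes, counts)}
    return np.array([per_class[v] for v in y])


def _objective(u, z, d):
    """F(u) and gradient for the smooth primal; u = (w, b), z_i = y_i (x_i, 1)."""
    margins = 1.0 - z @ u
    active = margins > 0
    w = u[:-1]
    f = 0.5 * w @ w + np.sum(d[active] * margins[active] ** 2)
    grad = np.append(w, 0.0) - 2.0 * z[active].T @ (d[active] * margins[active])
    return f, grad


class ClassWeightedL2SVM(ClassifierMixin, BaseEstimator):
    """Linear SVM with squared slack and group-size-balancing penalties.

    Parameters
    ----------
    penalty_scale : float, default 1.0
        Multiplier on every D_i.  1.0 reproduces the canonical weighting;
        large values approach the hard-margin (separable) limit.
    tol : float, default 1e-10
        Gradient tolerance used to verify optimality.
    max_iter : int, default 100
        Active-set iterations before falling back to L-BFGS.

    Attributes
    ----------
    coef_ : ndarray of shape (1, d)
        Hyperplane normal w.
    intercept_ : ndarray of shape (1,)
        Bias b.
    slack_ : ndarray of shape (n,)
        Optimal slack values max(0, 1 - y_i f_i).
    objective_ : float
        Attained primal objective value.
    classes_ : ndarray of shape (2,)
        Sorted class labels; the first maps to -1, the second to +1.
    """

    def __init__(self, penalty_scale: float = 1.0, tol: float = 1e-10, max_iter: int = 100):
        self.penalty_scale = penalty_scale
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("ClassWeightedL2SVM requires exactly two classes")
        y_pm = np.where(y == self.classes_[1], 1.0, -1.0)
        d = self.penalty_scale * penalty_weights(y_pm)
        z = y_pm[:, None] * np.column_stack([X, np.ones(len(y_pm))])
        n, p = z.shape

        u = np.zeros(p)
        active = np.ones(n, dtype=bool)  # start with every margin violated
        converged = False
        seen: set[bytes] = set()
        for it in range(self.max_iter):
            if not active.any():
                break  # cannot happen at a fixed point; fall back below
            za = z[active]
            da = d[active]
            h = 2.0 * (za.T * da) @ za
            h[np.arange(p - 1), np.arange(p - 1)] += 1.0
            rhs = 2.0 * za.T @ da
            u = np.linalg.solve(h, rhs)
            new_active = (1.0 - z @ u) > 0
            if np.array_equal(new_active, active):
                converged = True
                break
            key = new_active.tobytes()
            if key in seen:
                break  # cycle guard
            seen.add(key)
            active = new_active
        if not converged:
            res = optimize.minimize(
                _objective, u, args=(z, d), jac=True, method="L-BFGS-B",
                options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-12},
            )
            u = res.x
        f, grad = _objective(u, z, d)
        if not np.all(np.abs(grad) <= max(self.tol, 1e-8) * max(1.0, np.abs(f))):
            raise RuntimeError(
                f"SVM solver did not converge: ||grad||_inf = {np.abs(grad).max():.3e}"
            )
        self.coef_ = u[:-1][None, :]
        self.intercept_ = u[-1:]
        margins = 1.0 - z @ u
        self.slack_ = np.maximum(margins, 0.0)
        self.objective_ = float(f)
        self.n_iter_ = it + 1
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return X @ self.coef_[0] + self.intercept_[0]

    def predict(self, X):
        scores = self.decision_function(X)
        return np.where(scores >= 0, self.classes_[1], self.classes_[0])


def fit_svm(X, y, penalty_scale: float = 1.0, tol: float = 1e-10) -> ClassWeightedL2SVM:
    """Functional wrapper around :class:`ClassWeightedL2SVM`."""
    return ClassWeightedL2SVM(penalty_scale=penalty_scale, tol=tol).fit(X, y)


@dataclass
class CVResult:
    """Pooled leave-one-out cross-validation outcome.

    ``sensitivity`` is the correct fraction among the -1 (patient) class,
    ``specificity`` among the +1 (control) class.  ``fold_ranks`` holds, per
    fold, the |w|-based importance rank of each feature (1 = largest |w|).
    """

    y_true: np.ndarray
    y_pred: np.ndarray
    fold_ranks: np.ndarray  # (n_folds, d)
    mean_ranks: np.ndarray = field(init=False)
    n_correct: int = field(init=False)
    accuracy: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)

    def __post_init__(self):
        correct = self.y_true == self.y_pred
        self.n_correct = int(correct.sum())
        self.accuracy = float(correct.mean())
        neg = self.y_true == -1
        pos = self.y_true == 1
        self.sensitivity = float(correct[neg].mean()) if neg.any() else float("nan")
        self.specificity = float(correct[pos].mean()) if pos.any() else float("nan")
        self.mean_ranks = self.fold_ranks.mean(axis=0)


def _loo_folds(X: np.ndarray, y: np.ndarray, scale: bool):
    """Per-fold standardized (train, test) design matrices.

    Standardization statistics come from the training fold only, so the
    held-out subject never leaks into the scaling.  Features are z-scored
    per column; a zero-variance training column is left uncentered-unscaled.
    """
    n = len(y)
    folds = []
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        X_tr, X_te = X[tr], X[i : i + 1]
        if scale:
            mu = X_tr.mean(axis=0)
            sd = X_tr.std(axis=0)
            safe = np.where(sd > 0, sd, 1.0)
            X_tr = (X_tr - mu) / safe
            X_te = (X_te - mu) / safe
        folds.append((X_tr, y[tr], X_te))
    return folds


def _rank_abs_weights(w: np.ndarray) -> np.ndarray:
    """Rank features by |w| descending; rank 1 = largest, ties averaged."""
    return stats.rankdata(-np.abs(w), method="average")


def loocv(
    X,
    y,
    feature_mask=None,
    scale: bool = True,
    penalty_scale: float = 1.0,
    _folds=None,
) -> CVResult:
    """Leave-one-out cross-validation of the class-weighted L2 SVM.

    Each of the n folds trains on the other n-1 subjects (with per-fold
    feature standardization fitted on the training part only) and predicts
    the held-out subject; accuracy, sensitivity and specificity are pooled
    over folds.  ``feature_mask`` restricts the feature columns used.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) != 2 or min(np.bincount((y > 0).astype(int))) < 2:
        raise ValueError("LOOCV requires both classes with at least two members")
    folds = _folds if _folds is not None else _loo_folds(X, y, scale)
    if feature_mask is not None:
        mask = np.asarray(feature_mask, dtype=bool)
        if not mask.any():
            raise ValueError("feature mask must select at least one feature")
    else:
        mask = np.ones(X.shape[1], dtype=bool)
    preds = np.empty(len(y), dtype=y.dtype)
    ranks = np.empty((len(y), int(mask.sum())))
    clf = ClassWeightedL2SVM(penalty_scale=penalty_scale)
    for i, (X_tr, y_tr, X_te) in enumerate(folds):
        clf.fit(X_tr[:, mask], y_tr)
        preds[i] = clf.predict(X_te[:, mask])[0]
        ranks[i] = _rank_abs_weights(clf.coef_[0])
    return CVResult(y_true=y, y_pred=preds, fold_ranks=ranks)


def feature_weight_ranks(coefs) -> tuple[np.ndarray, np.ndarray]:
    """Per-fold |w| ranks (1 = most important) and their across-fold means."""
    coefs = np.atleast_2d(np.asarray(coefs, dtype=float))
    fold_ranks = np.vstack([_rank_abs_weights(w) for w in coefs])
    return fold_ranks, fold_ranks.mean(axis=0)
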