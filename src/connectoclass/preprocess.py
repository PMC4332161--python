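"""Weighted connectivity matrix -> binarized fixed-density graph.

Raw fiber-count matrices are (1) min-max normalized over the off-diagonal
cells, (2) sparsity-thresholded so that only the strongest fraction ``s`` of
edges survives (default 25%), and (3) binarized.  Because the retained edge
count is a fixed function of ``s`` and the node count, every subject of a
cohort ends up with the same number of connections, and the whole pipeline is
invariant to any strictly increasing rescaling of the raw weights.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DegenerateMatrixError
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "validate_connectivity",
    "minmax_normalize",
    "sparsity_threshold",
    "binarize",
    "preprocess",
    "preprocess_cohort",
    "density",
    "ConnectomePreprocessor",
]


def validate_connectivity(weights: np.ndarray) -> np.ndarray:
    """Check symmetry, zero diagonal, nonnegativity and finiteness."""
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"connectivity matrix must be square, got shape {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ValueError("connectivity matrix contains non-finite values")
    if np.any(w < 0):
        raise ValueError("connectivity matrix contains negative weights")
    if not np.allclose(w, w.T):
        raise ValueError("connectivity matrix is not symmetric")
    if np.any(np.diag(w) != 0):
        raise ValueError("connectivity matrix has nonzero diagonal entries")
    return w


def minmax_normalize(weights: np.ndarray) -> np.ndarray:
    """Affinely rescale off-diagonal weights to span [0, 1].

    The diagonal is left at zero.  A constant off-diagonal matrix admits no
    scale and raises :class:`DegenerateMatrixError`.
    """
    w = validate_connectivity(weights)
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = w[iu]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise DegenerateMatrixError(
            "constant off-diagonal matrix: min-max normalization is undefined"
        )
    out = (w - lo) / (hi - lo)
    np.fill_diagonal(out, 0.0)
    return out


def _edge_order(w: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle edges sorted by weight descending, ties broken by
    (lower node index, lower partner index) so thresholding is deterministic."""
    n = w.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    vals = w[ii, jj]
    # lexsort: last key is primary
    order = np.lexsort((jj, ii, -vals))
    return ii[order], jj[order], vals[order]


def sparsity_threshold(
    weights: np.ndarray, s: float = 0.25, basis: str = "possible"
) -> np.ndarray:
    """Retain the strongest edges, zeroing the rest.

    Parameters
    ----------
    s : fraction in (0, 1] of edges to keep.
    basis : ``"possible"`` keeps ``floor(s * n(n-1)/2)`` edges (fraction of all
        node pairs, the dominant convention for sparsity thresholds);
        ``"nonzero"`` keeps ``floor(s * #nonzero)`` edges instead.
    """
    if not (0 < s <= 1):
        raise ValueError(f"sparsity s must lie in (0, 1], got {s}")
    if basis not in ("possible", "nonzero"):
        raise ValueError(f"basis must be 'possible' or 'nonzero', got {basis!r}")
    w = validate_connectivity(weights)
    n = w.shape[0]
    ii, jj, vals = _edge_order(w)
    if basis == "possible":
        k = int(np.floor(s * n * (n - 1) / 2))
    else:
        k = int(np.floor(s * np.count_nonzero(vals)))
    out = np.zeros_like(w)
    keep_i, keep_j = ii[:k], jj[:k]
    out[keep_i, keep_j] = w[keep_i, keep_j]
    out[keep_j, keep_i] = w[keep_j, keep_i]
    return out


def binarize(weights: np.ndarray) -> np.ndarray:
    """0/1 adjacency: indicator of a nonzero (retained) weight."""
    w = validate_connectivity(weights)
    return (w > 0).astype(np.uint8)


def density(adjacency: np.ndarray) -> float:
    """Realized fraction of possible undirected edges."""
    a = np.asarray(adjacency)
    n = a.shape[0]
    return float(np.count_nonzero(np.triu(a, k=1)) / (n * (n - 1) / 2))


def preprocess(
    weights: np.ndarray, s: float = 0.25, basis: str = "possible"
) -> np.ndarray:
    """normalize -> threshold -> binarize; returns the 0/1 adjacency matrix."""
    return binarize(sparsity_threshold(minmax_normalize(weights), s=s, basis=basis))


def preprocess_cohort(
    matrices: np.ndarray, s: float = 0.25, basis: str = "possible"
) -> np.ndarray:
    """Apply :func:`preprocess` to a (n_subjects, p, p) stack."""
    stack = np.asarray(matrices, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a (n_subjects, p, p) stack of matrices")
    return np.stack([preprocess(m, s=s, basis=basis) for m in stack])


class ConnectomePreprocessor(TransformerMixin, BaseEstimator):
    """Stateless transformer form of :func:`preprocess_cohort`.

    ``transform`` maps a (n_subjects, p, p) stack of weighted symmetric
    connectivity matrices to the corresponding stack of 0/1 adjacency
    matrices at the configured sparsity.  Composes with sklearn pipelines.

    Parameters
    ----------
    sparsity : float, default 0.25
        Fraction of edges retained by the threshold.
    basis : {"possible", "nonzero"}, default "possible"
        Denominator convention for the retained-edge count.
    """

    def __init__(self, sparsity: float = 0.25, basis: str = "possible"):
        self.sparsity = sparsity
        self.basis = basis

    def fit(self, X, y=None):
        # stateless; fit only validates parameters
        if not (0 < self.sparsity <= 1):
            raise ValueError(f"sparsity must lie in (0, 1], got {self.sparsity}")
        self.n_features_in_ = np.asarray(X).shape[-1]
        return self

    def transform(self, X):
        return preprocess_cohort(X, s=self.sparsity, basis=self.basis)
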