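"""Global graph metrics and nodal degree on binarized undirected graphs.

The nine global metrics form the classifier feature space, in fixed order:
assortativity, global flow coefficient, global total flow, global betweenness,
global efficiency, modularity, characteristic path length, transitivity and
small-worldness.  All are computed on simple 0/1 adjacency matrices.

Conventions
-----------
* Betweenness is unnormalized and counts **ordered** source-target pairs
  (the Brain Connectivity Toolbox convention), so for a connected graph the
  mean node betweenness equals ``(n - 1) * (L - 1)`` where ``L`` is the
  characteristic path length.
* The flow coefficient of a node with degree ``k >= 2`` is the fraction of its
  neighbor pairs that are *not* directly linked, i.e. pairs whose length-two
  route through the node is a genuine shortest path; nodes with ``k < 2`` have
  flow 0 by convention.  The total flow of a node is the count of such pairs.
* Modularity is the mean achieved Newman modularity over ``n_iter`` runs of a
  stochastic Louvain optimizer with randomized node order.
* Small-worldness normalizes transitivity and characteristic path length by
  the *means* over ``n_null`` degree-preserving (double-edge-swap) null
  graphs: ``S = (T / <T_null>) / (L / <L_null>)``.
"""

from __future__ import annotations

import warnings
from collections import deque

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import UndefinedMetricError

__all__ = [
    "FEATURE_NAMES",
    "degree_centrality",
    "assortativity",
    "flow_coefficients",
    "betweenness",
    "shortest_path_matrix",
    "global_efficiency",
    "characteristic_path_length",
    "partition_modularity",
    "louvain_communities",
    "modularity",
    "transitivity",
    "randomize_degree_preserving",
    "small_worldness",
    "compute_features",
    "compute_feature_table",
    "GraphMetricExtractor",
]

FEATURE_NAMES: tuple[str, ...] = (
    "assortativity",
    "global_flow_coefficient",
    "global_total_flow",
    "global_betweenness",
    "global_efficiency",
    "modularity",
    "characteristic_path_length",
    "transitivity",
    "small_worldness",
)


def _as_adjacency(a: np.ndarray) -> np.ndarray:
    adj = np.asarray(a)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {adj.shape}")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(adj) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    if not np.isin(adj, (0, 1)).all():
        raise ValueError("adjacency entries must be 0 or 1")
    return adj.astype(bool)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def degree_centrality(a: np.ndarray) -> np.ndarray:
    """Number of neighbors of each node."""
    return _as_adjacency(a).sum(axis=1).astype(int)


def assortativity(a: np.ndarray) -> float:
    """Pearson correlation between degrees at opposite ends of every edge.

    Each undirected edge contributes both orientations.  Undefined (raises)
    when the graph has no edges or the end-degrees have zero variance
    (e.g. any regular graph).
    """
    adj = _as_adjacency(a)
    deg = adj.sum(axis=1)
    ii, jj = np.nonzero(np.triu(adj, k=1))
    if ii.size == 0:
        raise UndefinedMetricError("assortativity undefined: graph has no edges")
    x = np.concatenate([deg[ii], deg[jj]]).astype(float)
    y = np.concatenate([deg[jj], deg[ii]]).astype(float)
    if np.ptp(x) == 0:
        raise UndefinedMetricError(
            "assortativity undefined: zero variance of edge-end degrees"
        )
    return float(np.corrcoef(x, y)[0, 1])


def flow_coefficients(a: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Per-node flow coefficient, global flow coefficient, global total flow.

    Returns ``(flow, mean(flow), mean(count))`` where for each node ``v`` with
    degree ``k_v >= 2``, ``count_v`` is the number of unordered neighbor pairs
    of ``v`` with no direct edge between them and
    ``flow_v = count_v / (k_v (k_v - 1) / 2)``.
    """
    adj = _as_adjacency(a)
    af = adj.astype(float)
    deg = adj.sum(axis=1)
    pairs = deg * (deg - 1) / 2.0
    tri_through = np.einsum("ij,jk,ki->i", af, af, af) / 2.0  # triangles at v
    count = np.where(pairs > 0, pairs - tri_through, 0.0)
    flow = np.divide(count, pairs, out=np.zeros_like(count), where=pairs > 0)
    return flow, float(flow.mean()), float(count.mean())


def betweenness(a: np.ndarray) -> tuple[np.ndarray, float]:
    """Unnormalized betweenness centrality (Brandes) and its node mean.

    Ordered pairs: each unordered source-target pair contributes in both
    directions, so values run up to ``(n - 1)(n - 2)``.
    """
    adj = _as_adjacency(a)
    n = adj.shape[0]
    nbrs = [np.flatnonzero(adj[v]).tolist() for v in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        stack: list[int] = []
        pred: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        q = deque([s])
        while q:
            v = q.popleft()
            stack.append(v)
            dv1 = dist[v] + 1
            for w in nbrs[v]:
                if dist[w] < 0:
                    dist[w] = dv1
                    q.append(w)
                if dist[w] == dv1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = np.zeros(n)
        for w in reversed(stack):
            coeff = (1.0 + delta[w]) / sigma[w]
            for v in pred[w]:
                delta[v] += sigma[v] * coeff
            if w != s:
                bc[w] += delta[w]
    return bc, float(bc.mean())


def shortest_path_matrix(a: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths by simultaneous BFS; inf = unreachable."""
    adj = _as_adjacency(a)
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = reached.copy()
    d = 0
    while frontier.any():
        d += 1
        frontier = (frontier @ adj) & ~reached
        dist[frontier] = d
        reached |= frontier
    return dist


def global_efficiency(a: np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs (1/inf = 0)."""
    dist = shortest_path_matrix(a)
    n = dist.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist[off]
    return float(np.mean(np.where(np.isfinite(inv), inv, 0.0)))


def characteristic_path_length(a: np.ndarray) -> float:
    """Mean shortest-path distance over reachable ordered node pairs.

    Disconnected graphs average over finite pairs only, with a warning.
    """
    dist = shortest_path_matrix(a)
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = dist[off]
    finite = np.isfinite(vals)
    if not finite.any():
        raise UndefinedMetricError("path length undefined: graph has no edges")
    if not finite.all():
        warnings.warn(
            "graph is disconnected; characteristic path length averages over "
            "reachable pairs only",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(vals[finite].mean())


# ---------------------------------------------------------------------------
# Modularity (stochastic Louvain)
# ---------------------------------------------------------------------------


def partition_modularity(a: np.ndarray, labels: np.ndarray) -> float:
    """Newman modularity Q = sum_c [e_c/m - (d_c/2m)^2] of a node partition."""
    w = np.asarray(a, dtype=float)
    labels = np.asarray(labels)
    m2 = w.sum()  # 2m
    if m2 == 0:
        raise UndefinedMetricError("modularity undefined: graph has no edges")
    q = 0.0
    deg = w.sum(axis=1)
    for c in np.unique(labels):
        mask = labels == c
        intra = w[np.ix_(mask, mask)].sum()  # ordered internal pairs = 2 e_c
        d_c = deg[mask].sum()
        q += intra / m2 - (d_c / m2) ** 2
    return float(q)


def _louvain_one_level(w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Louvain local-move phase on a weighted graph (diagonal = twice the
    self-loop weight, so row sums are degrees).  Returns community labels."""
    n = w.shape[0]
    deg = w.sum(axis=1)
    m2 = deg.sum()
    comm = np.arange(n)
    tot = deg.copy()
    moved = True
    while moved:
        moved = False
        for i in rng.permutation(n):
            ci = comm[i]
            row = w[i].copy()
            row[i] = 0.0
            links = np.bincount(comm, weights=row, minlength=n)
            tot[ci] -= deg[i]
            comm[i] = -1
            # candidate communities: those of neighbors, plus the old one
            cands = np.flatnonzero(links > 0)
            if ci not in cands:
                cands = np.append(cands, ci)
            gains = links[cands] - tot[cands] * deg[i] / m2
            best = cands[int(np.argmax(gains))]
            if gains.max() <= 0:
                best = ci  # no strictly positive gain: stay
            if best != ci:
                moved = True
            comm[i] = best
            tot[best] += deg[i]
    return comm


def louvain_communities(a: np.ndarray, seed=None) -> np.ndarray:
    """Community labels from multi-level Louvain with randomized node order."""
    adj = _as_adjacency(a)
    if not adj.any():
        raise UndefinedMetricError("modularity undefined: graph has no edges")
    rng = _as_rng(seed)
    w = adj.astype(float)
    node_comm = np.arange(w.shape[0])  # original node -> current community id
    q_prev = -np.inf
    while True:
        level = _louvain_one_level(w, rng)
        _, level = np.unique(level, return_inverse=True)
        node_comm = level[node_comm]
        q = partition_modularity(adj.astype(float), node_comm)
        if q <= q_prev + 1e-12:
            break
        q_prev = q
        # aggregate: C^T W C with one-hot C; diagonal then holds 2x internal
        nc = level.max() + 1
        one_hot = np.zeros((w.shape[0], nc))
        one_hot[np.arange(w.shape[0]), level] = 1.0
        w = one_hot.T @ w @ one_hot
        if nc == w.shape[0] == 1:
            break
    _, node_comm = np.unique(node_comm, return_inverse=True)
    return node_comm


def modularity(a: np.ndarray, n_iter: int = 10, seed=None) -> float:
    """Mean achieved modularity over ``n_iter`` stochastic Louvain runs."""
    adj = _as_adjacency(a)
    if not adj.any():
        raise UndefinedMetricError("modularity undefined: graph has no edges")
    rng = _as_rng(seed)
    w = adj.astype(float)
    qs = [partition_modularity(w, louvain_communities(adj, rng)) for _ in range(n_iter)]
    return float(np.mean(qs))


def transitivity(a: np.ndarray) -> float:
    """3 x triangles / connected triplets (sum_v k_v(k_v-1)/2)."""
    adj = _as_adjacency(a)
    af = adj.astype(float)
    deg = adj.sum(axis=1)
    triplets = float((deg * (deg - 1) / 2.0).sum())
    if triplets == 0:
        raise UndefinedMetricError("transitivity undefined: no connected triplets")
    triangles = np.einsum("ij,jk,ki->", af, af, af) / 6.0
    return float(3.0 * triangles / triplets)


def randomize_degree_preserving(
    a: np.ndarray, seed=None, swap_factor: int = 10
) -> np.ndarray:
    """Degree-preserving randomization by repeated double-edge swaps.

    Attempts ``swap_factor * |E|`` swaps; each picks two edges (a,b), (c,d)
    and rewires to (a,d), (c,b) when that creates no self-loop or duplicate
    edge.  Graphs admitting no successful swap (e.g. stars) are returned
    unchanged with a warning.
    """
    adj = _as_adjacency(a).copy()
    rng = _as_rng(seed)
    ii, jj = np.nonzero(np.triu(adj, k=1))
    n_edges = ii.size
    if n_edges < 2:
        warnings.warn("fewer than two edges: no swap possible", RuntimeWarning)
        return adj.astype(np.uint8)
    edges = np.column_stack([ii, jj])
    n_attempts = swap_factor * n_edges
    successes = 0
    # draw all randomness up front; the rejection loop itself is cheap
    pair_draws = rng.integers(0, n_edges, size=(n_attempts, 2))
    flip_draws = rng.random(n_attempts) < 0.5
    for t in range(n_attempts):
        e1, e2 = pair_draws[t]
        if e1 == e2:
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if flip_draws[t]:
            x, y = y, x
        # propose (u, x), (v, y)
        if u == x or v == y:
            continue
        if adj[u, x] or adj[v, y]:
            continue
        adj[u, v] = adj[v, u] = False
        adj[x, y] = adj[y, x] = False
        adj[u, x] = adj[x, u] = True
        adj[v, y] = adj[y, v] = True
        edges[e1] = (u, x)
        edges[e2] = (v, y)
        successes += 1
    if successes == 0:
        warnings.warn(
            "degree-preserving randomization found no valid swap; "
            "returning the input graph",
            RuntimeWarning,
        )
    return adj.astype(np.uint8)


def small_worldness(
    a: np.ndarray, n_null: int = 10, seed=None, swap_factor: int = 10
) -> float:
    """Normalized-transitivity / normalized-path-length ratio.

    ``S = (T / <T_null>) / (L / <L_null>)`` with means over ``n_null``
    independent degree-preserving randomizations.
    """
    adj = _as_adjacency(a)
    rng = _as_rng(seed)
    t_obs = transitivity(adj)
    l_obs = characteristic_path_length(adj)
    t_null = np.empty(n_null)
    l_null = np.empty(n_null)
    for i in range(n_null):
        null = randomize_degree_preserving(adj, rng, swap_factor=swap_factor)
        t_null[i] = transitivity(null)
        l_null[i] = characteristic_path_length(null)
    if t_null.mean() == 0:
        raise UndefinedMetricError(
            "small-worldness undefined: null graphs have zero transitivity"
        )
    return float((t_obs / t_null.mean()) / (l_obs / l_null.mean()))


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------


def compute_features(
    a: np.ndarray,
    n_modularity_iter: int = 10,
    n_null: int = 10,
    seed=None,
    swap_factor: int = 10,
) -> dict[str, float]:
    """All nine global metrics of one graph; undefined metrics come back NaN."""
    adj = _as_adjacency(a)
    rng = _as_rng(seed)
    out: dict[str, float] = {}

    def safe(name, fn):
        try:
            out[name] = fn()
        except UndefinedMetricError:
            out[name] = float("nan")

    flow, gflow, gtot = flow_coefficients(adj)
    _, gbet = betweenness(adj)
    safe("assortativity", lambda: assortativity(adj))
    out["global_flow_coefficient"] = gflow
    out["global_total_flow"] = gtot
    out["global_betweenness"] = gbet
    out["global_efficiency"] = global_efficiency(adj)
    safe("modularity", lambda: modularity(adj, n_iter=n_modularity_iter, seed=rng))
    safe("characteristic_path_length", lambda: characteristic_path_length(adj))
    safe("transitivity", lambda: transitivity(adj))
    safe(
        "small_worldness",
        lambda: small_worldness(adj, n_null=n_null, seed=rng, swap_factor=swap_factor),
    )
    return {name: out[name] for name in FEATURE_NAMES}


def compute_feature_table(
    adjacency_stack: np.ndarray,
    n_modularity_iter: int = 10,
    n_null: int = 10,
    seed=None,
    swap_factor: int = 10,
    subject_ids=None,
) -> pd.DataFrame:
    """Nine-metric feature table, one row per subject.

    Per-subject random streams are derived deterministically from ``seed`` so
    the table is reproducible and independent of evaluation order.
    """
    stack = np.asarray(adjacency_stack)
    if stack.ndim != 3:
        raise ValueError("expected a (n_subjects, p, p) adjacency stack")
    n = stack.shape[0]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n)
    rows = [
        compute_features(
            stack[i],
            n_modularity_iter=n_modularity_iter,
            n_null=n_null,
            seed=np.random.default_rng(children[i]),
            swap_factor=swap_factor,
        )
        for i in range(n)
    ]
    index = subject_ids if subject_ids is not None else range(n)
    return pd.DataFrame(rows, index=index, columns=list(FEATURE_NAMES))


class GraphMetricExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping an adjacency stack to the nine-metric feature table.

    Parameters
    ----------
    n_modularity_iter : int, default 10
        Louvain runs averaged for the modularity feature.
    n_null : int, default 10
        Degree-preserving null graphs for small-worldness normalization.
    swap_factor : int, default 10
        Attempted double-edge swaps per edge when randomizing.
    random_state : int or None
        Seed for the stochastic metrics (modularity, small-worldness).
    """

    def __init__(
        self,
        n_modularity_iter: int = 10,
        n_null: int = 10,
        swap_factor: int = 10,
        random_state=None,
    ):
        self.n_modularity_iter = n_modularity_iter
        self.n_null = n_null
        self.swap_factor = swap_factor
        self.random_state = random_state

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[-1]
        return self

    def transform(self, X) -> pd.DataFrame:
        return compute_feature_table(
            X,
            n_modularity_iter=self.n_modularity_iter,
            n_null=self.n_null,
            seed=self.random_state,
            swap_factor=self.swap_factor,
        )

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
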