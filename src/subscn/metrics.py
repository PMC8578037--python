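"""Topological properties of binary covariance networks.

Global: clustering coefficient C, characteristic path length L, global
efficiency E_global; their random-null normalizations gamma = C/C_rand and
lambda = L/L_rand from degree-preserving rewired reference graphs; the
small-world index sigma = gamma/lambda (sigma > 1 = small-world); Newman
modularity Q maximized by a randomized greedy optimizer; an exponentially
truncated power-law fit of the cumulative degree distribution; and a
random-failure resilience curve.  Nodal: degree, clustering, betweenness.

Path lengths are defined only on connected graphs (the density sweep's
minimum-density rule is meant to guarantee connectivity); efficiency uses
the 1/inf = 0 convention and therefore accepts disconnected graphs.

Hot-path computations run on dense numpy adjacency matrices (BFS distances
via ``scipy.sparse.csgraph``); betweenness delegates to networkx's Brandes
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.sparse.csgraph import connected_components, shortest_path

from ._rng import substream
from .network import BinaryNetwork

__all__ = [
    "GlobalMetrics",
    "SmallWorldResult",
    "DegreeFit",
    "ResilienceCurve",
    "MetricError",
    "DisconnectedGraphError",
    "clustering",
    "characteristic_path_length",
    "global_efficiency",
    "betweenness",
    "rewire_degree_preserving",
    "normalized_small_world",
    "modularity_q",
    "modularity_optimal",
    "fit_truncated_power_law",
    "random_failure",
    "global_metrics",
    "nodal_metrics",
]


class MetricError(ValueError):
    """Raised for inputs on which a metric is undefined."""


class DisconnectedGraphError(MetricError):
    """Path length requested on a fragmented graph."""


def _as_adjacency(net) -> np.ndarray:
    if isinstance(net, BinaryNetwork):
        return net.adjacency
    a = np.asarray(net)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise MetricError("adjacency must be square")
    return a.astype(np.uint8)


def _bfs_all_pairs_py(a):
    """Unweighted all-pairs distances by BFS on a dense adjacency matrix."""
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    queue = np.empty(n, dtype=np.int64)
    for s in range(n):
        dist[s, s] = 0.0
        queue[0] = s
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[s, u]
            for v in range(n):
                if a[u, v] and dist[s, v] == np.inf:
                    dist[s, v] = du + 1.0
                    queue[tail] = v
                    tail += 1
    return dist


try:
    from numba import njit as _njit_bfs

    _bfs_all_pairs = _njit_bfs(cache=False)(_bfs_all_pairs_py)
except ImportError:  # pragma: no cover
    _bfs_all_pairs = None


def _distances(a: np.ndarray) -> np.ndarray:
    if _bfs_all_pairs is not None:
        return _bfs_all_pairs(np.ascontiguousarray(a, dtype=np.uint8))
    return shortest_path(a, method="D", unweighted=True, directed=False)


def _connected(a: np.ndarray) -> bool:
    if _bfs_all_pairs is not None:
        return bool(np.isfinite(_bfs_all_pairs(np.ascontiguousarray(a, np.uint8))[0]).all())
    return connected_components(a, directed=False, return_labels=False) == 1


# ---------------------------------------------------------------------------
# basic global metrics


def clustering(net) -> tuple[np.ndarray, float]:
    """Watts-Strogatz local clustering per node and its mean.

    c_i = triangles(i) / (k_i (k_i - 1) / 2); nodes of degree < 2
    contribute 0.  The mean runs over all nodes.
    """
    a = _as_adjacency(net).astype(float)
    k = a.sum(axis=0)
    tri = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return c, float(c.mean())


def characteristic_path_length(net) -> float:
    """Mean shortest-path length over all ordered node pairs (connected only)."""
    a = _as_adjacency(net)
    if a.shape[0] < 2:
        raise MetricError("path length needs at least 2 nodes")
    d = _distances(a)
    off = d[~np.eye(len(d), dtype=bool)]
    if np.isinf(off).any():
        raise DisconnectedGraphError("graph is fragmented; path length undefined")
    return float(off.mean())


def global_efficiency(net) -> float:
    """Mean inverse shortest-path length; disconnected pairs contribute 0."""
    a = _as_adjacency(net)
    n = a.shape[0]
    if n < 2:
        return 0.0
    d = _distances(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[np.isinf(d)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def betweenness(net) -> np.ndarray:
    """Brandes betweenness centrality, normalized by (N-1)(N-2)/2."""
    import networkx as nx

    a = _as_adjacency(net)
    g = nx.from_numpy_array(a)
    bc = nx.betweenness_centrality(g, normalized=True)
    return np.array([bc[i] for i in range(a.shape[0])])


def nodal_metrics(net):
    """Degree, clustering and betweenness per node as a DataFrame."""
    import pandas as pd

    a = _as_adjacency(net)
    labels = net.node_labels if isinstance(net, BinaryNetwork) else list(range(a.shape[0]))
    c, _ = clustering(a)
    return pd.DataFrame(
        {"degree": a.sum(axis=0).astype(int), "clustering": c, "betweenness": betweenness(a)},
        index=labels,
    )


# ---------------------------------------------------------------------------
# degree-preserving null model


def _edge_list(a: np.ndarray) -> np.ndarray:
    iu, ju = np.nonzero(np.triu(a, k=1))
    return np.column_stack([iu, ju]).astype(np.int64)


def _swap_kernel_py(a, edges, pick, flip):
    for t in range(len(pick)):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if flip[t]:
            x, y = y, x
        if u == x or v == y or a[u, x] or a[v, y]:
            continue
        a[u, v] = a[v, u] = 0
        a[x, y] = a[y, x] = 0
        a[u, x] = a[x, u] = 1
        a[v, y] = a[y, v] = 1
        edges[e1, 0], edges[e1, 1] = u, x
        edges[e2, 0], edges[e2, 1] = v, y


try:  # JIT the swap loop when numba is available; identical semantics
    from numba import njit as _njit

    _swap_kernel = _njit(cache=False)(_swap_kernel_py)
except ImportError:  # pragma: no cover
    _swap_kernel = _swap_kernel_py


def rewire_degree_preserving(
    net,
    n_swaps: int | None = None,
    seed: int = 0,
    *,
    require_connected: bool = True,
    max_restarts: int = 20,
) -> np.ndarray | BinaryNetwork:
    """Randomize a graph by double-edge swaps, preserving every degree.

    ``n_swaps`` is the number of swap attempts (default 10x the edge
    count); attempts creating self-loops or multi-edges are discarded.
    When ``require_connected`` and the input is connected, the whole
    randomization is redrawn (fresh substream) until the result is
    connected again, up to ``max_restarts`` times; the last draw is
    returned regardless, so degenerate inputs still terminate.
    """
    a0 = _as_adjacency(net)
    edges0 = _edge_list(a0)
    n_edges = len(edges0)
    if n_edges < 2:
        raise MetricError("rewiring needs at least 2 edges")
    attempts = 10 * n_edges if n_swaps is None else int(n_swaps)
    want_connected = require_connected and _connected(a0)

    result = None
    for restart in range(max_restarts):
        rng = substream(seed, f"rewire:{restart}")
        a = a0.copy()
        edges = edges0.copy()
        pick = rng.integers(0, n_edges, size=(attempts, 2))
        flip = rng.random(attempts) < 0.5
        _swap_kernel(a, edges, pick, flip)
        result = a
        if not want_connected or _connected(a):
            break
    if isinstance(net, BinaryNetwork):
        return BinaryNetwork(result, net.density, net.node_labels,
                             connected=_connected(result))
    return result


def _rewired_ensemble(a0: np.ndarray, n_random: int, rng: np.random.Generator,
                      max_restarts: int = 20):
    """Degree-preserving rewired references sharing one random stream
    (hot-path variant of :func:`rewire_degree_preserving`)."""
    edges0 = _edge_list(a0)
    n_edges = len(edges0)
    attempts = 10 * n_edges
    want_connected = _connected(a0)
    for _ in range(n_random):
        for _ in range(max_restarts):
            a = a0.copy()
            edges = edges0.copy()
            pick = rng.integers(0, n_edges, size=(attempts, 2))
            flip = rng.random(attempts) < 0.5
            _swap_kernel(a, edges, pick, flip)
            if not want_connected or _connected(a):
                break
        yield a


@dataclass(frozen=True)
class SmallWorldResult:
    gamma: float
    lambda_: float
    sigma: float
    C: float
    L: float
    C_random: float
    L_random: float
    n_random: int


def normalized_small_world(net, n_random: int = 20, seed: int = 0) -> SmallWorldResult:
    """gamma, lambda and sigma against degree-preserving rewired references.

    gamma = C / mean C of ``n_random`` rewired graphs, lambda likewise for
    L, sigma = gamma / lambda.  References that come back fragmented
    (possible for near-degenerate degree sequences) contribute to C but
    are skipped for L.
    """
    a = _as_adjacency(net)
    c_obs = clustering(a)[1]
    l_obs = characteristic_path_length(a)
    c_rand, l_rand = [], []
    rng = substream(seed % (2**31), "smallworld-null")
    for ar in _rewired_ensemble(a, n_random, rng):
        c_rand.append(clustering(ar)[1])
        try:
            l_rand.append(characteristic_path_length(ar))
        except DisconnectedGraphError:
            pass
    c_bar = float(np.mean(c_rand))
    if c_bar == 0:
        raise MetricError("random reference clustering is 0; gamma undefined")
    if not l_rand:
        raise MetricError("no connected random reference; lambda undefined")
    l_bar = float(np.mean(l_rand))
    gamma = c_obs / c_bar
    lam = l_obs / l_bar
    return SmallWorldResult(gamma, lam, gamma / lam, c_obs, l_obs, c_bar, l_bar, n_random)


# ---------------------------------------------------------------------------
# modularity


def modularity_q(net, labels: np.ndarray) -> float:
    """Newman modularity of a given partition: sum_c (e_cc - a_c^2)."""
    a = _as_adjacency(net).astype(float)
    m2 = a.sum()
    if m2 == 0:
        raise MetricError("modularity undefined on an edgeless graph")
    labels = np.asarray(labels)
    cats = np.unique(labels)
    h = (labels[:, None] == cats[None, :]).astype(float)
    e = h.T @ a @ h / m2
    deg = a.sum(axis=0)
    a_c = h.T @ deg / m2
    return float(np.trace(e) - (a_c**2).sum())


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    _, canon = np.unique(labels, return_inverse=True)
    return canon


def _greedy_agglomerate(a: np.ndarray, rng: np.random.Generator, top_k: int):
    """One randomized greedy agglomerative run.

    Communities start as singletons and are merged pairwise; each step
    picks uniformly among the ``top_k`` connected pairs with the largest
    modularity gain (top_k = 1 is pure greedy with random tie-breaking).
    Merging continues to a single community; the best partition along the
    trajectory is returned.
    """
    n = a.shape[0]
    m2 = a.sum()
    e = a.astype(float) / m2                     # e[i, j]: edge fraction between comms
    ac = a.sum(axis=0).astype(float) / m2        # degree fraction per community
    active = np.ones(n, dtype=bool)
    node_comm = np.arange(n)
    q = -float((ac**2).sum())                    # singleton partition (no self-loops)
    best_q, best_labels = q, node_comm.copy()

    while active.sum() > 1:
        idx = np.nonzero(active)[0]
        sub_e = e[np.ix_(idx, idx)]
        gain = 2.0 * (sub_e - np.outer(ac[idx], ac[idx]))
        iu, ju = np.triu_indices(len(idx), k=1)
        conn = sub_e[iu, ju] > 0
        if conn.any():
            cand_gain = gain[iu[conn], ju[conn]]
            order = np.argsort(-cand_gain, kind="stable")
            top = order[: max(1, min(top_k, len(order)))]
            # include exact ties with the worst admitted gain
            cutoff = cand_gain[top[-1]]
            pool = np.nonzero(cand_gain >= cutoff - 1e-15)[0]
            choice = rng.choice(pool)
            ci, cj = idx[iu[conn][choice]], idx[ju[conn][choice]]
            q += float(cand_gain[choice])
        else:  # only disconnected communities left; merging cannot help Q
            break
        e[ci, :] += e[cj, :]
        e[:, ci] += e[:, cj]
        e[cj, :] = 0.0
        e[:, cj] = 0.0
        ac[ci] += ac[cj]
        active[cj] = False
        node_comm[node_comm == cj] = ci
        if q > best_q + 1e-15:
            best_q, best_labels = q, node_comm.copy()
    return best_q, _canonical_labels(best_labels)


def _refine_node_moves(a: np.ndarray, labels: np.ndarray, rng: np.random.Generator,
                       max_passes: int = 30) -> tuple[float, np.ndarray]:
    """Single-node moves to adjacent communities while modularity improves."""
    labels = labels.copy()
    m2 = a.sum()
    deg = a.sum(axis=0).astype(float)
    n = a.shape[0]
    for _ in range(max_passes):
        improved = False
        for u in rng.permutation(n):
            cu = labels[u]
            neigh = np.nonzero(a[u])[0]
            if len(neigh) == 0:
                continue
            cand = np.unique(labels[neigh])
            # links from u to each community and community total degrees
            k_uc = {c: float(a[u, labels == c].sum()) for c in set(cand) | {cu}}
            d_tot = {c: float(deg[labels == c].sum()) for c in set(cand) | {cu}}
            base = k_uc[cu] / m2 * 2 - 2 * deg[u] * (d_tot[cu] - deg[u]) / m2**2
            best_gain, best_c = 0.0, cu
            for c in cand:
                if c == cu:
                    continue
                gain = (k_uc[c] / m2 * 2 - 2 * deg[u] * d_tot[c] / m2**2) - base
                if gain > best_gain + 1e-15:
                    best_gain, best_c = gain, c
            if best_c != cu:
                labels[u] = best_c
                improved = True
        if not improved:
            break
    return modularity_q(a, labels), _canonical_labels(labels)


def modularity_optimal(net, n_iter: int = 1000, seed: int = 0,
                       top_k: int = 3) -> tuple[float, np.ndarray, int]:
    """Maximize Newman modularity over randomized-restart greedy runs.

    Each of ``n_iter`` restarts runs a randomized greedy agglomeration
    (uniform choice among the ``top_k`` best connected merges, pure greedy
    on the first restart) followed by single-node-move refinement; the
    best (Q, partition) over restarts is returned, together with its
    module count.  Q never falls below the single-community baseline of 0.
    """
    a = _as_adjacency(net).astype(float)
    if a.sum() == 0:
        raise MetricError("modularity optimization needs at least one edge")
    rng = substream(seed, "modularity")
    best_q, best_labels = -np.inf, None
    for it in range(n_iter):
        q, labels = _greedy_agglomerate(a, rng, top_k=1 if it == 0 else top_k)
        q, labels = _refine_node_moves(a, labels, rng)
        if q > best_q:
            best_q, best_labels = q, labels
    if best_q < 0.0:  # single community is always admissible
        best_q, best_labels = 0.0, np.zeros(a.shape[0], dtype=int)
    n_modules = int(len(np.unique(best_labels)))
    return float(best_q), best_labels, n_modules


# ---------------------------------------------------------------------------
# degree distribution


@dataclass(frozen=True)
class DegreeFit:
    """Exponentially truncated power-law fit of the cumulative degree curve.

    P(K >= k) ~ k^(a-1) * exp(-k/b): ``a`` is the power-law exponent,
    ``b`` the exponential cut-off degree, ``r_squared`` the goodness of
    fit on the cumulative curve.  ``scale`` is the fitted multiplicative
    constant (reported for completeness; the shape parameters are a, b).
    """

    a: float
    b: float
    r_squared: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise MetricError("cut-off degree must be positive")


def _survival_curve(degrees: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ks = np.unique(degrees[degrees > 0])
    surv = np.array([(degrees >= k).mean() for k in ks], float)
    return ks.astype(float), surv


def fit_truncated_power_law(net_or_degrees, *, min_distinct: int = 5) -> DegreeFit:
    """Nonlinear least-squares fit of P(K >= k) = c * k^(a-1) * exp(-k/b)."""
    if isinstance(net_or_degrees, BinaryNetwork):
        degrees = net_or_degrees.degrees()
    else:
        arr = np.asarray(net_or_degrees)
        degrees = arr.sum(axis=0).astype(int) if arr.ndim == 2 else arr.astype(int)
    ks, surv = _survival_curve(degrees)
    if len(ks) < min_distinct:
        raise MetricError(
            f"degree distribution has {len(ks)} distinct positive values; "
            f"need at least {min_distinct}"
        )

    # linearized initialization: log y = log c + (a-1) log k - k/b
    x = np.column_stack([np.ones_like(ks), np.log(ks), ks])
    coef, *_ = np.linalg.lstsq(x, np.log(surv), rcond=None)
    a0 = coef[1] + 1.0
    b0 = -1.0 / coef[2] if coef[2] < 0 else ks.max()
    c0 = float(np.exp(coef[0]))

    def model(k, c, a, b):
        return c * k ** (a - 1.0) * np.exp(-k / b)

    try:
        popt, _ = optimize.curve_fit(
            model, ks, surv, p0=[c0, a0, b0],
            bounds=([1e-12, -20.0, 1e-9], [1e6, 20.0, 1e9]), maxfev=20000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise MetricError(f"truncated power-law fit did not converge: {exc}") from exc
    c, a, b = (float(v) for v in popt)
    resid = surv - model(ks, c, a, b)
    ss_tot = float(((surv - surv.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else np.nan
    return DegreeFit(a=a, b=b, r_squared=r2, scale=c)


# ---------------------------------------------------------------------------
# resilience


@dataclass(frozen=True)
class ResilienceCurve:
    """Mean relative largest-component size after random node failure."""

    fractions_removed: np.ndarray
    relative_lcc: np.ndarray
    reps: int


def random_failure(net, fractions=None, reps: int = 100, seed: int = 0) -> ResilienceCurve:
    """Remove a random share of nodes, record largest-component size / N."""
    a = _as_adjacency(net)
    n = a.shape[0]
    if fractions is None:
        fractions = np.round(np.arange(0.0, 1.0, 0.05), 10)
    fractions = np.asarray(fractions, float)
    if (fractions < 0).any() or (fractions >= 1).any():
        raise MetricError("failure fractions must lie in [0, 1)")
    rng = substream(seed, "random-failure")
    means = np.empty_like(fractions)
    for fi, f in enumerate(fractions):
        n_remove = int(round(f * n))
        if n_remove == 0:
            means[fi] = (
                1.0 if connected_components(a, directed=False, return_labels=False) == 1
                else _lcc_size(a) / n
            )
            continue
        sizes = np.empty(reps)
        for rep in range(reps):
            keep = rng.permutation(n)[n_remove:]
            sizes[rep] = _lcc_size(a[np.ix_(keep, keep)])
        means[fi] = sizes.mean() / n
    return ResilienceCurve(fractions, means, reps)


def _lcc_size(a: np.ndarray) -> int:
    if a.shape[0] == 0:
        return 0
    _, labels = connected_components(a, directed=False)
    return int(np.bincount(labels).max())


# ---------------------------------------------------------------------------
# bundle


@dataclass(frozen=True)
class GlobalMetrics:
    """All global topological properties of one binary network."""

    C: float
    L: float
    E_global: float
    gamma: float
    lambda_: float
    sigma: float
    Q: float
    n_modules: int


def global_metrics(
    net,
    n_random: int = 20,
    modularity_restarts: int = 100,
    seed: int = 0,
) -> GlobalMetrics:
    """Convenience bundle: C, L, E_global, gamma/lambda/sigma, Q, module count."""
    c = clustering(net)[1]
    length = characteristic_path_length(net)
    eff = global_efficiency(net)
    sw = normalized_small_world(net, n_random=n_random, seed=seed)
    q, _, n_mod = modularity_optimal(net, n_iter=modularity_restarts, seed=seed)
    return GlobalMetrics(
        C=c, L=length, E_global=eff,
        gamma=sw.gamma, lambda_=sw.lambda_, sigma=sw.sigma,
        Q=q, n_modules=n_mod,
    )
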