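import logging

import numpy as np
import pytest

from subscn import generate_cohort, residualize, tiny_spec

logging.getLogger("subscn").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tiny_cohort():
    """One small three-group cohort (30/30/30, 20 ROIs), reused read-only."""
    spec = tiny_spec(seed=7)
    records, table = generate_cohort(spec)
    return spec, records, table


@pytest.fixture(scope="session")
def tiny_residuals(tiny_cohort):
    _, _, table = tiny_cohort
    return residualize(table, fit_scope="pooled_all")


# ---------------------------------------------------------------------------
# brute-force graph oracles (independent of the implementations under test)


def oracle_clustering(a: np.ndarray) -> tuple[np.ndarray, float]:
    """Local clustering by explicit enumeration of neighbor pairs."""
    n = len(a)
    c = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        closed = sum(
            1 for x in range(k) for y in range(x + 1, k) if a[nbrs[x], nbrs[y]]
        )
        c[i] = closed / (k * (k - 1) / 2)
    return c, float(c.mean())


def oracle_distances(a: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by Floyd-Warshall."""
    n = len(a)
    d = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def oracle_path_length(a: np.ndarray) -> float:
    d = oracle_distances(a)
    off = d[~np.eye(len(a), dtype=bool)]
    assert np.isfinite(off).all(), "oracle_path_length needs a connected graph"
    return float(off.mean())


def oracle_efficiency(a: np.ndarray) -> float:
    d = oracle_distances(a)
    off = d[~np.eye(len(a), dtype=bool)]
    with np.errstate(divide="ignore"):
        inv = 1.0 / off
    inv[np.isinf(off)] = 0.0
    return float(inv.mean())


def oracle_betweenness(a: np.ndarray) -> np.ndarray:
    """Betweenness via distances + shortest-path counting (pair summation,
    fractional credit), normalized by (n-1)(n-2)/2."""
    n = len(a)
    d = oracle_distances(a)
    # count shortest paths by dynamic programming over distance
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = np.argsort(d[s])
        for v in order:
            if v == s or np.isinf(d[s, v]):
                continue
            sigma[s, v] = sum(
                sigma[s, u] for u in range(n) if a[u, v] and d[s, u] == d[s, v] - 1
            )
    bc = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t or np.isinf(d[s, t]) or sigma[s, t] == 0:
                continue
            on_path = d[s, :] + d[:, t] == d[s, t]
            on_path[[s, t]] = False
            bc[on_path] += sigma[s, on_path] * sigma[on_path, t] / sigma[s, t]
    bc /= 2.0  # each unordered pair counted twice
    if n < 3:
        return np.zeros(n)
    return bc / ((n - 1) * (n - 2) / 2)


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def oracle_best_modularity(a: np.ndarray) -> float:
    """Exhaustive maximum of Newman modularity over all node partitions."""
    n = len(a)
    m2 = a.sum()
    deg = a.sum(axis=0)
    best = -np.inf
    for part in set_partitions(list(range(n))):
        q = 0.0
        for block in part:
            idx = np.array(block)
            q += a[np.ix_(idx, idx)].sum() / m2 - (deg[idx].sum() / m2) ** 2
        best = max(best, q)
    return best
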