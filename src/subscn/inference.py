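"""Permutation inference on topological properties across the density sweep.

For a pair of groups, covariate-corrected volumes are pooled and
repeatedly relabelled into two random groups of the original sizes; every
topological property is recomputed for every relabelling at every density,
giving a permutation null for the between-group difference curve.
Per-density two-tailed p-values use the add-one percentile rule
p = (1 + #{|null| >= |observed|}) / (n_perm + 1).  The across-threshold
(functional-data-analysis style) statistic is the signed area between the
two metric curves — the sum of per-density differences — tested against
its own permutation distribution by the same rule.  One permutation
schedule is shared by all metrics of a comparison.

Networks that fragment at a low density inside a replicate leave that
replicate's path length missing at that density; per-density p-values then
use complete-pairs counting and the FDA statistic sums over the densities
observed for that replicate (logged loudly in the result).

Nodal (per-ROI) degree/clustering/betweenness curves get per-node FDA
p-values with Benjamini-Hochberg correction across nodes, per metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .adjustment import ResidualTable
from .metrics import (
    _distances,
    betweenness as _betweenness_nodes,
    clustering,
    modularity_optimal,
    normalized_small_world,
)
from .network import association_matrix, default_density_grid

logger = logging.getLogger(__name__)

__all__ = [
    "MetricCurve",
    "PermutationResult",
    "NodalTestResult",
    "GLOBAL_METRICS",
    "NODAL_METRICS",
    "metric_curves",
    "permute_groups",
    "permutation_test",
    "compare_groups",
    "nodal_tests",
    "fdr_bh",
]

GLOBAL_METRICS = ("C", "L", "E_global", "gamma", "lambda", "sigma", "Q")
NODAL_METRICS = ("degree", "clustering", "betweenness")


@dataclass
class MetricCurve:
    """One metric across the density grid (scalar per density, or
    node x density for nodal metrics)."""

    metric_name: str
    densities: np.ndarray
    values: np.ndarray
    group: str | None = None


@dataclass
class PermutationResult:
    """Observed difference curve, permutation null and p-values for one metric."""

    metric_name: str
    densities: np.ndarray
    observed_group1: np.ndarray
    observed_group2: np.ndarray
    observed_diff: np.ndarray
    null_diffs: np.ndarray            # n_perm x n_densities
    p_per_density: np.ndarray
    fda_statistic: float
    fda_p: float
    n_perm: int
    seed: int
    n_missing_null: int = 0           # null cells lost to fragmentation


@dataclass
class NodalTestResult:
    """Per-node FDA p-values with BH-FDR decisions for one nodal metric."""

    metric_name: str
    node_labels: list[str]
    fda_statistic: np.ndarray
    p_raw: np.ndarray
    p_fdr: np.ndarray
    reject_raw: np.ndarray
    reject_fdr: np.ndarray
    q: float


# ---------------------------------------------------------------------------
# fast per-split curve computation


def _global_curves_for_matrix(
    x: np.ndarray,
    densities: np.ndarray,
    metrics: tuple[str, ...],
    *,
    n_random: int,
    modularity_restarts: int,
    seed: int,
) -> dict[str, np.ndarray]:
    """All requested global metric curves for one group's residual matrix.

    Metrics are computed on the incremental top-k edge sets of the ranked
    correlation pairs; L and the normalized metrics are NaN at densities
    where the graph fragments.
    """
    assoc = association_matrix(x)
    n = assoc.n_nodes
    m = n * (n - 1) // 2
    ranked = assoc.ranked_pairs()
    out = {name: np.full(len(densities), np.nan) for name in metrics}
    a = np.zeros((n, n), dtype=np.uint8)
    prev_k = 0
    need_sw = any(name in metrics for name in ("gamma", "lambda", "sigma"))
    for di, d in enumerate(densities):
        k = int(np.floor(d * m))
        if k > prev_k:
            seg = ranked[prev_k:k]
            a[seg[:, 0], seg[:, 1]] = 1
            a[seg[:, 1], seg[:, 0]] = 1
            prev_k = k
        dmat = _distances(a)
        connected = bool(np.isfinite(dmat[0]).all())
        if "C" in metrics:
            out["C"][di] = clustering(a)[1]
        if "L" in metrics or "E_global" in metrics:
            off = dmat[~np.eye(n, dtype=bool)]
            if "L" in metrics and connected:
                out["L"][di] = off.mean()
            if "E_global" in metrics:
                with np.errstate(divide="ignore"):
                    inv = 1.0 / off
                inv[np.isinf(off)] = 0.0
                out["E_global"][di] = inv.mean()
        if need_sw and connected:
            try:
                sw = normalized_small_world(a, n_random=n_random, seed=seed * 977 + di)
                if "gamma" in metrics:
                    out["gamma"][di] = sw.gamma
                if "lambda" in metrics:
                    out["lambda"][di] = sw.lambda_
                if "sigma" in metrics:
                    out["sigma"][di] = sw.sigma
            except Exception:
                pass
        if "Q" in metrics:
            q, _, _ = modularity_optimal(a, n_iter=modularity_restarts, seed=seed * 977 + di)
            out["Q"][di] = q
    return out


def _nodal_curves_for_matrix(x: np.ndarray, densities: np.ndarray) -> dict[str, np.ndarray]:
    """Degree/clustering/betweenness (node x density) for one residual matrix."""
    assoc = association_matrix(x)
    n = assoc.n_nodes
    m = n * (n - 1) // 2
    ranked = assoc.ranked_pairs()
    out = {name: np.zeros((n, len(densities))) for name in NODAL_METRICS}
    a = np.zeros((n, n), dtype=np.uint8)
    prev_k = 0
    for di, d in enumerate(densities):
        k = int(np.floor(d * m))
        if k > prev_k:
            seg = ranked[prev_k:k]
            a[seg[:, 0], seg[:, 1]] = 1
            a[seg[:, 1], seg[:, 0]] = 1
            prev_k = k
        out["degree"][:, di] = a.sum(axis=0)
        out["clustering"][:, di] = clustering(a)[0]
        out["betweenness"][:, di] = _betweenness_nodes(a)
    return out


# ---------------------------------------------------------------------------
# public operations


def metric_curves(
    residuals: ResidualTable,
    group: str,
    *,
    densities: np.ndarray | None = None,
    metrics: tuple[str, ...] = GLOBAL_METRICS,
    n_random: int = 20,
    modularity_restarts: int = 100,
    seed: int = 0,
    nodal: bool = False,
) -> dict[str, MetricCurve]:
    """Global (and optionally nodal) metric curves for one group."""
    if densities is None:
        densities = default_density_grid()
    x = residuals.group_matrix(group)
    if x.shape[0] == 0:
        raise ValueError(f"group {group!r} not present in residual table")
    curves = _global_curves_for_matrix(
        x, densities, metrics,
        n_random=n_random, modularity_restarts=modularity_restarts, seed=seed,
    )
    result = {
        name: MetricCurve(name, densities, vals, group=group) for name, vals in curves.items()
    }
    if nodal:
        for name, vals in _nodal_curves_for_matrix(x, densities).items():
            result[name] = MetricCurve(name, densities, vals, group=group)
    return result


def permute_groups(
    n1: int, n2: int, n_perm: int = 1000, seed: int = 0
) -> np.ndarray:
    """Permutation schedule: each row is a shuffled index vector of the
    pooled sample; the first ``n1`` entries form pseudo-group 1.

    Every repetition is a uniformly random partition of the pooled
    participants into the original sizes.
    """
    total = n1 + n2
    if total < 8:
        logger.warning("pooled sample of %d is small; permutation null is coarse", total)
    rng = substream(seed, "permutation-schedule")
    return np.array([rng.permutation(total) for _ in range(n_perm)])


def _percentile_p(observed: float, null: np.ndarray, tails: str = "two-sided") -> float:
    """Add-one percentile p; never 0, minimum 1/(n+1)."""
    null = null[~np.isnan(null)]
    if tails == "greater":
        extreme = null >= observed
    elif tails == "less":
        extreme = null <= observed
    else:
        extreme = np.abs(null) >= abs(observed)
    return float((1 + extreme.sum()) / (len(null) + 1))


def permutation_test(
    observed1: np.ndarray,
    observed2: np.ndarray,
    null_diffs: np.ndarray,
    *,
    metric_name: str = "",
    densities: np.ndarray | None = None,
    n_perm: int | None = None,
    seed: int = 0,
    tails: str = "two-sided",
) -> PermutationResult:
    """Percentile p-values for one metric from observed curves and a null.

    ``null_diffs`` is (n_perm x n_densities) of pseudo-group differences on
    the same grid as the observed curves.  NaNs (fragmented replicates) are
    skipped by complete-pairs counting.  ``tails`` is "two-sided" (default),
    "greater" or "less".
    """
    observed1 = np.asarray(observed1, float)
    observed2 = np.asarray(observed2, float)
    null_diffs = np.atleast_2d(np.asarray(null_diffs, float))
    if observed1.shape != observed2.shape or null_diffs.shape[1] != observed1.shape[0]:
        raise ValueError("observed curves and null grid shapes do not match")
    if densities is None:
        densities = np.arange(observed1.shape[0], dtype=float)
    diff = observed1 - observed2
    p_density = np.array(
        [_percentile_p(diff[di], null_diffs[:, di], tails)
         if np.isfinite(diff[di]) else np.nan
         for di in range(len(diff))]
    )
    # FDA: signed area between curves, over the densities observed per replicate
    valid = np.isfinite(diff)
    fda_obs = float(np.nansum(diff[valid]))
    null_valid = null_diffs[:, valid]
    fda_null = np.nansum(null_valid, axis=1)
    fda_null[np.all(np.isnan(null_valid), axis=1)] = np.nan
    fda_p = _percentile_p(fda_obs, fda_null, tails)
    n_missing = int(np.isnan(null_diffs).sum())
    if n_missing:
        logger.warning(
            "%s: %d null curve cells missing (fragmented replicates); "
            "complete-pairs counting used", metric_name, n_missing,
        )
    return PermutationResult(
        metric_name=metric_name,
        densities=np.asarray(densities, float),
        observed_group1=observed1,
        observed_group2=observed2,
        observed_diff=diff,
        null_diffs=null_diffs,
        p_per_density=p_density,
        fda_statistic=fda_obs,
        fda_p=fda_p,
        n_perm=n_perm if n_perm is not None else null_diffs.shape[0],
        seed=seed,
    )


def compare_groups(
    residuals: ResidualTable,
    group1: str,
    group2: str,
    *,
    metrics: tuple[str, ...] = GLOBAL_METRICS,
    densities: np.ndarray | None = None,
    n_perm: int = 1000,
    n_random: int = 20,
    modularity_restarts: int = 100,
    seed: int = 0,
    nodal: bool = False,
    q: float = 0.05,
) -> dict[str, PermutationResult | NodalTestResult]:
    """Full permutation comparison of two groups over the density sweep.

    One permutation schedule drives every metric.  Residuals are expected
    to be covariate-corrected already (correction precedes and is held
    fixed across permutations).  Returns one PermutationResult per global
    metric and, with ``nodal=True``, one NodalTestResult per nodal metric.
    """
    if densities is None:
        densities = default_density_grid()
    mask1 = (residuals.participants["group"] == group1).to_numpy()
    mask2 = (residuals.participants["group"] == group2).to_numpy()
    x1 = residuals.residuals.to_numpy(float)[mask1]
    x2 = residuals.residuals.to_numpy(float)[mask2]
    n1, n2 = x1.shape[0], x2.shape[0]
    pooled = np.vstack([x1, x2])
    schedule = permute_groups(n1, n2, n_perm=n_perm, seed=seed)

    def curves_for(x: np.ndarray, tag: int) -> tuple[dict, dict]:
        g = _global_curves_for_matrix(
            x, densities, metrics,
            n_random=n_random, modularity_restarts=modularity_restarts, seed=seed + tag,
        )
        nd = _nodal_curves_for_matrix(x, densities) if nodal else {}
        return g, nd

    obs1, nodal1 = curves_for(x1, tag=1)
    obs2, nodal2 = curves_for(x2, tag=2)

    null_global = {name: np.full((n_perm, len(densities)), np.nan) for name in metrics}
    null_nodal = (
        {name: np.full((n_perm, pooled.shape[1], len(densities)), np.nan)
         for name in NODAL_METRICS}
        if nodal else {}
    )
    for pi in range(n_perm):
        idx = schedule[pi]
        g1, nd1 = curves_for(pooled[idx[:n1]], tag=3 + 2 * pi)
        g2, nd2 = curves_for(pooled[idx[n1:]], tag=4 + 2 * pi)
        for name in metrics:
            null_global[name][pi] = g1[name] - g2[name]
        for name in null_nodal:
            null_nodal[name][pi] = nd1[name] - nd2[name]

    results: dict[str, PermutationResult | NodalTestResult] = {}
    for name in metrics:
        results[name] = permutation_test(
            obs1[name], obs2[name], null_global[name],
            metric_name=name, densities=densities, n_perm=n_perm, seed=seed,
        )
    if nodal:
        for name in NODAL_METRICS:
            results[name] = _nodal_result(
                name, residuals.roi_names,
                nodal1[name], nodal2[name], null_nodal[name], q=q,
            )
    return results


def _nodal_result(
    name: str,
    labels: list[str],
    obs1: np.ndarray,
    obs2: np.ndarray,
    null: np.ndarray,
    q: float,
) -> NodalTestResult:
    diff = obs1 - obs2                      # node x density
    fda_obs = diff.sum(axis=1)
    fda_null = null.sum(axis=2)             # n_perm x node
    p_raw = np.array(
        [_percentile_p(fda_obs[i], fda_null[:, i]) for i in range(len(labels))]
    )
    p_fdr, reject = fdr_bh(p_raw, q=q)
    return NodalTestResult(
        metric_name=name,
        node_labels=list(labels),
        fda_statistic=fda_obs,
        p_raw=p_raw,
        p_fdr=p_fdr,
        reject_raw=p_raw < q,
        reject_fdr=reject,
        q=q,
    )


def nodal_tests(
    residuals: ResidualTable,
    group1: str,
    group2: str,
    *,
    densities: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    q: float = 0.05,
) -> dict[str, NodalTestResult]:
    """Per-node FDA permutation tests with BH-FDR across nodes, per metric."""
    out = compare_groups(
        residuals, group1, group2,
        metrics=(), densities=densities, n_perm=n_perm, seed=seed, nodal=True, q=q,
    )
    return {k: v for k, v in out.items() if isinstance(v, NodalTestResult)}


def fdr_bh(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and rejection mask."""
    pvals = np.asarray(pvals, float)
    if pvals.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.nanmin(pvals) < 0 or np.nanmax(pvals) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return p_adj, reject
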