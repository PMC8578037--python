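"""Structural covariance network construction.

A group's association matrix is the ROI-by-ROI Pearson correlation of
covariate-adjusted volumes across that group's participants.  Binary
networks are obtained by density thresholding: at density ``d`` the
floor(d * N(N-1)/2) node pairs with the largest signed correlation become
edges.  The analysis sweep covers densities 0.17-0.45 in steps of 0.02
(15 networks per group), and a minimum-density utility reports the lowest
grid density at which the thresholded graph is a single component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

__all__ = [
    "AssociationMatrix",
    "BinaryNetwork",
    "DensitySweep",
    "NetworkError",
    "association_matrix",
    "binarize_at_density",
    "minimum_connected_density",
    "build_sweep",
    "default_density_grid",
]


class NetworkError(ValueError):
    """Raised for undefined correlations or infeasible densities."""


@dataclass
class AssociationMatrix:
    """Symmetric Pearson correlation matrix with zeroed diagonal."""

    r: np.ndarray
    node_labels: list[str]
    group: str | None = None
    n_participants: int = 0
    #: node-pair order by decreasing signed r (ties: lexicographic i, j);
    #: cached so a density sweep ranks once
    _order: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.r, float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise NetworkError("association matrix must be square")
        if not np.allclose(r, r.T, atol=1e-12):
            raise NetworkError("association matrix must be symmetric")
        off = r[~np.eye(len(r), dtype=bool)]
        if off.size and (np.abs(off) > 1 + 1e-12).any():
            raise NetworkError("correlations must lie in [-1, 1]")
        np.fill_diagonal(r, 0.0)
        self.r = r

    @property
    def n_nodes(self) -> int:
        return self.r.shape[0]

    def ranked_pairs(self, *, absolute: bool = False) -> np.ndarray:
        """Upper-triangle pair indices (m x 2) sorted by decreasing r
        (or |r| with ``absolute=True``).

        Ties are broken by lexicographic (i, j) order — np.argsort with a
        stable kind on row-major upper-triangle indices guarantees that.
        """
        if absolute:
            iu, ju = np.triu_indices(self.n_nodes, k=1)
            vals = np.abs(self.r[iu, ju])
            order = np.argsort(-vals, kind="stable")
            return np.column_stack([iu[order], ju[order]])
        if self._order is None:
            iu, ju = np.triu_indices(self.n_nodes, k=1)
            vals = self.r[iu, ju]
            order = np.argsort(-vals, kind="stable")
            self._order = np.column_stack([iu[order], ju[order]])
        return self._order


@dataclass
class BinaryNetwork:
    """Undirected, unweighted graph at one density."""

    adjacency: np.ndarray
    density: float
    node_labels: list[str]
    connected: bool = True

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T):
            raise NetworkError("adjacency must be symmetric")
        if a.diagonal().any():
            raise NetworkError("adjacency must have no self-loops")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)

    def to_networkx(self):
        import networkx as nx

        g = nx.from_numpy_array(self.adjacency)
        nx.relabel_nodes(g, dict(enumerate(self.node_labels)), copy=False)
        for _, _, d in g.edges(data=True):
            d.clear()
        return g


@dataclass
class DensitySweep:
    """One binary network per density of a strictly increasing grid."""

    densities: np.ndarray
    networks: list[BinaryNetwork]
    group: str | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.densities, float)
        if len(d) != len(self.networks):
            raise NetworkError("density grid and network list differ in length")
        if len(d) > 1 and not np.all(np.diff(d) > 0):
            raise NetworkError("density grid must be strictly increasing")
        self.densities = d

    def __iter__(self):
        return iter(self.networks)

    def __len__(self) -> int:
        return len(self.networks)

    @property
    def flagged(self) -> list[float]:
        """Densities at which the network is not a single component."""
        return [float(d) for d, net in zip(self.densities, self.networks) if not net.connected]


def default_density_grid(
    d_min: float = 0.17, d_max: float = 0.45, step: float = 0.02
) -> np.ndarray:
    n = int(round((d_max - d_min) / step)) + 1
    return np.round(d_min + step * np.arange(n), 10)


def association_matrix(
    residuals, group: str | None = None, *, node_labels: list[str] | None = None
) -> AssociationMatrix:
    """Pearson correlation matrix of residuals across a group's participants.

    ``residuals`` is a ResidualTable (with ``group`` naming the subgroup)
    or a plain (participants x ROIs) array.
    """
    if hasattr(residuals, "group_matrix"):
        if group is None:
            x = residuals.residuals.to_numpy(float)
        else:
            x = residuals.group_matrix(group)
        labels = residuals.roi_names
    else:
        x = np.asarray(residuals, float)
        labels = node_labels or [f"node{i}" for i in range(x.shape[1])]
    if x.shape[0] < 4:
        raise NetworkError("need at least 4 participants to correlate")
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = [labels[i] for i in np.nonzero(sd == 0)[0]]
        raise NetworkError(f"zero-variance ROIs (correlation undefined): {bad}")
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 0.0)
    return AssociationMatrix(r, list(labels), group=group, n_participants=x.shape[0])


def _adjacency_from_pairs(n: int, pairs: np.ndarray) -> np.ndarray:
    a = np.zeros((n, n), dtype=np.uint8)
    if len(pairs):
        a[pairs[:, 0], pairs[:, 1]] = 1
        a[pairs[:, 1], pairs[:, 0]] = 1
    return a


def _is_connected(a: np.ndarray) -> bool:
    return connected_components(a, directed=False, return_labels=False) == 1


def binarize_at_density(
    assoc: AssociationMatrix, density: float, *, rank_by: str = "signed"
) -> BinaryNetwork:
    """Top-k thresholding: keep the floor(density * N(N-1)/2) strongest pairs.

    ``rank_by`` selects signed r (default: the positive-covariance
    convention) or absolute |r|.
    """
    n = assoc.n_nodes
    m = n * (n - 1) // 2
    if not 0 < density <= 1:
        raise NetworkError("density must lie in (0, 1]")
    if rank_by not in ("signed", "absolute"):
        raise NetworkError("rank_by must be 'signed' or 'absolute'")
    k = int(np.floor(density * m))
    if k == 0:
        raise NetworkError(f"density {density} yields zero edges for N={n}")
    pairs = assoc.ranked_pairs(absolute=rank_by == "absolute")[:k]
    a = _adjacency_from_pairs(n, pairs)
    return BinaryNetwork(a, density=k / m, node_labels=assoc.node_labels,
                         connected=_is_connected(a))


def minimum_connected_density(assoc: AssociationMatrix, grid_step: float = 0.01) -> float:
    """Smallest grid density at which the thresholded graph is one component.

    Edges are added in rank order; connectivity first holds at some edge
    count k*, and the answer is k* / m rounded up to the grid.
    """
    n = assoc.n_nodes
    m = n * (n - 1) // 2
    pairs = assoc.ranked_pairs()
    # incremental union-find over ranked edges
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    n_comp = n
    k_star = None
    for k, (i, j) in enumerate(pairs, start=1):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[ri] = rj
            n_comp -= 1
            if n_comp == 1:
                k_star = k
                break
    if k_star is None:
        raise NetworkError("graph not connected even with every pair as an edge")
    return float(np.ceil(k_star / m / grid_step - 1e-12) * grid_step)


def build_sweep(
    assoc: AssociationMatrix,
    d_min: float = 0.17,
    d_max: float = 0.45,
    step: float = 0.02,
) -> DensitySweep:
    """Binarize across the density grid; disconnected entries are flagged,
    not fatal (path-length computations refuse flagged networks)."""
    if d_min > d_max:
        raise NetworkError("d_min must not exceed d_max")
    grid = default_density_grid(d_min, d_max, step)
    nets = [binarize_at_density(assoc, float(d)) for d in grid]
    return DensitySweep(grid, nets, group=assoc.group)
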