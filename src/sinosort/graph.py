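"""Neighborhood graph and geodesic distances between projection features.

The Fourier vectors of projections of a fixed object sweep out a closed
curve as the view angle varies, so Euclidean (L2) distances are only
trustworthy locally.  Distances below a threshold ``T`` define a weighted
neighbor graph; shortest paths in that graph approximate the on-manifold
(geodesic) distances that the spherical embedding consumes.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree, shortest_path
from scipy.spatial.distance import pdist, squareform

from .features import FeatureMatrix

__all__ = [
    "NeighborGraph",
    "DisconnectedGraphError",
    "pairwise_l2",
    "auto_threshold",
    "build_graph",
    "geodesic_distances",
    "merge_duplicate_rows",
]

log = logging.getLogger(__name__)


class DisconnectedGraphError(ValueError):
    """Raised when the threshold graph splits into several components."""

    def __init__(self, component_sizes: list[int], suggested_threshold: float):
        self.component_sizes = component_sizes
        self.suggested_threshold = suggested_threshold
        super().__init__(
            f"neighbor graph is disconnected (component sizes "
            f"{component_sizes}); the smallest connecting threshold is about "
            f"{suggested_threshold / 1.1:.6g} — use auto_threshold, e.g. "
            f"T={suggested_threshold:.6g}")


def pairwise_l2(features: FeatureMatrix | np.ndarray,
                weights: np.ndarray | None = None) -> np.ndarray:
    """Dense matrix of weighted L2 distances between feature rows.

    ``d_ij = sqrt(sum_k w_k |F_i(k) - F_j(k)|^2)`` with the bin-multiplicity
    weights carried by the feature matrix (unit weights for a bare array).
    """
    if isinstance(features, FeatureMatrix):
        vectors, weights = features.vectors, features.weights
    else:
        vectors = np.asarray(features)
        if weights is None:
            weights = np.ones(vectors.shape[1])
    if vectors.shape[0] < 3:
        raise ValueError("need at least 3 feature rows")
    scaled = vectors * np.sqrt(weights)
    if np.iscomplexobj(scaled):
        scaled = np.hstack([scaled.real, scaled.imag])
    return squareform(pdist(scaled))


def merge_duplicate_rows(dm: np.ndarray, tol: float = 0.0,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Group rows at pairwise distance <= tol into single nodes.

    Returns ``(representatives, membership)`` where ``representatives`` are
    the original indices kept (one per group, ascending) and
    ``membership[i]`` is the reduced-node index of original row ``i``.
    Duplicate projections would otherwise create zero-weight edges, which
    the strict ``d < T`` rule excludes from the graph.
    """
    n = dm.shape[0]
    close = dm <= tol
    np.fill_diagonal(close, True)
    n_groups, labels = connected_components(csr_matrix(close), directed=False)
    representatives = np.array(
        [np.flatnonzero(labels == g)[0] for g in range(n_groups)])
    order = np.argsort(representatives)
    representatives = representatives[order]
    remap = np.empty(n_groups, dtype=int)
    remap[order] = np.arange(n_groups)
    return representatives, remap[labels]


def auto_threshold(dm: np.ndarray, safety: float = 1.1) -> float:
    """Smallest threshold that connects the graph, times a safety factor.

    The minimax connecting distance is the largest edge of the minimum
    spanning tree of the complete distance graph; any ``T`` strictly above
    it yields a connected ``d < T`` graph.
    """
    if dm.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if safety < 1.0:
        raise ValueError("safety factor must be >= 1")
    mst = minimum_spanning_tree(np.asarray(dm, dtype=float))
    if mst.nnz == 0:
        raise ValueError("distance matrix has no positive entries")
    return safety * float(mst.data.max())


@dataclasses.dataclass
class NeighborGraph:
    """Undirected threshold graph with L2 edge weights."""

    adjacency: csr_matrix    # symmetric, zero diagonal
    threshold: float
    n_edges: int


def build_graph(dm: np.ndarray, threshold: float) -> NeighborGraph:
    """Connect every pair with ``0 < d_ij < threshold`` (strict).

    Raises :class:`DisconnectedGraphError` with the component sizes and a
    workable threshold when the graph falls apart.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    dm = np.asarray(dm, dtype=float)
    adjacency = csr_matrix(np.where((dm > 0) & (dm < threshold), dm, 0.0))
    n_components, labels = connected_components(adjacency, directed=False)
    if n_components > 1:
        sizes = sorted(np.bincount(labels).tolist(), reverse=True)
        raise DisconnectedGraphError(sizes, auto_threshold(dm))
    n_edges = adjacency.nnz // 2
    log.info("neighbor graph: T=%.6g, %d edges on %d nodes",
             threshold, n_edges, dm.shape[0])
    return NeighborGraph(adjacency=adjacency, threshold=threshold,
                         n_edges=n_edges)


def geodesic_distances(graph: NeighborGraph) -> np.ndarray:
    """All-pairs shortest-path distances (Dijkstra) in the neighbor graph."""
    dist = shortest_path(graph.adjacency, method="D", directed=False)
    if not np.all(np.isfinite(dist)):
        raise ValueError("graph is disconnected; geodesics are infinite")
    dist = 0.5 * (dist + dist.T)
    np.fill_diagonal(dist, 0.0)
    return dist
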