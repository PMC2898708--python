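"""View angles from circle-embedded projections.

The embedded point of projection ``i`` is a unit vector ``(X_i, Y_i)``;
its polar angle ``atan2(Y_i, X_i)`` (two-argument form, so the quadrant is
preserved) is the raw view-angle estimate.  Because the true angles are
drawn uniformly, sorting the raw angles and redistributing them uniformly
along the circle sharpens the estimates; the refinement preserves circular
order and can be disabled for non-uniform designs.

With magnitude features, projections at ``theta`` and ``theta + pi`` are
indistinguishable, so the embedded circle is traversed twice per turn of
the true angle: the estimates then parameterize the view angle modulo
``pi`` and are spread over the half turn ``[0, pi)``.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .config import PipelineConfig
from .features import fft_features
from .graph import (auto_threshold, build_graph, geodesic_distances,
                    merge_duplicate_rows, pairwise_l2)
from .phantoms import Sinogram
from .smds import CircleEmbedding, embed_circle, estimate_radius, gram_operator

__all__ = [
    "AngleAssignment",
    "wrap_angle",
    "wrap_signed",
    "angles_from_embedding",
    "refine_uniform",
    "estimate_view_angles",
]

log = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi


def wrap_angle(angle: np.ndarray | float, period: float = TWO_PI):
    """Wrap into ``[0, period)``."""
    return np.mod(angle, period)


def wrap_signed(angle: np.ndarray | float, period: float = TWO_PI):
    """Wrap into ``[-period/2, period/2)``."""
    return np.mod(np.asarray(angle, dtype=float) + period / 2, period) - period / 2


@dataclasses.dataclass
class AngleAssignment:
    """Estimated view angle for every projection.

    ``order`` is the permutation sorting ``raw_angles`` ascending (stable,
    ties broken by original index); ``refined_angles`` places the k-th
    smallest raw angle at ``period * k / N``.  ``period`` is ``2*pi`` for
    complex features and ``pi`` for magnitude features (half-turn
    degeneracy).
    """

    raw_angles: np.ndarray
    order: np.ndarray
    refined_angles: np.ndarray
    period: float = TWO_PI

    def __post_init__(self) -> None:
        n = len(self.raw_angles)
        if sorted(self.order.tolist()) != list(range(n)):
            raise ValueError("order must be a permutation of 0..N-1")
        if len(self.refined_angles) != n:
            raise ValueError("refined_angles length mismatch")

    @property
    def n(self) -> int:
        return len(self.raw_angles)


def angles_from_embedding(embedding: CircleEmbedding) -> np.ndarray:
    """Polar angles of the embedded unit vectors, in ``[0, 2*pi)``."""
    pts = embedding.points
    return wrap_angle(np.arctan2(pts[:, 1], pts[:, 0]))


def refine_uniform(raw_angles: np.ndarray, period: float = TWO_PI,
                   refine: bool = True) -> AngleAssignment:
    """Sort raw angles and redistribute them uniformly on the circle.

    With ``refine=False`` the raw angles are kept (the sorting permutation
    is still reported).
    """
    raw_angles = np.asarray(raw_angles, dtype=float)
    n = raw_angles.size
    if n < 2:
        raise ValueError("need at least 2 angles")
    order = np.argsort(raw_angles, kind="stable")
    if refine:
        refined = np.empty(n)
        refined[order] = period * np.arange(n) / n
    else:
        refined = wrap_angle(raw_angles, period)
    return AngleAssignment(raw_angles=raw_angles, order=order,
                           refined_angles=refined, period=period)


def estimate_view_angles(sino: Sinogram, config: PipelineConfig | None = None,
                         ) -> AngleAssignment:
    """Full angle-recovery pipeline on an unordered sinogram.

    Stages: Fourier features -> pairwise L2 distances -> threshold
    neighbor graph -> Dijkstra geodesics -> spherical MDS circle embedding
    -> arctangent angles -> uniform refinement.  Deterministic given the
    sinogram and configuration; never reads ``hidden_angles``.

    Structural failures (disconnected graph, degenerate embedding) are
    raised as the structured errors of their stage.
    """
    config = config or PipelineConfig()
    n = sino.n_projections
    if n < 8:
        raise ValueError(f"need at least 8 projections, got {n}")

    feats = fft_features(sino, mode=config.feature_mode,
                         band_fraction=config.band_fraction)
    distances = pairwise_l2(feats)

    # exact duplicates would create zero-weight edges; collapse them and
    # re-expand after the embedding
    reps, membership = merge_duplicate_rows(distances)
    reduced = distances[np.ix_(reps, reps)]
    if reduced.shape[0] < 3:
        raise ValueError("fewer than 3 distinct projections")

    threshold = (config.threshold if config.threshold is not None
                 else auto_threshold(reduced, config.threshold_safety))
    log.info("estimate_view_angles: N=%d (%d distinct), T=%.6g", n,
             reduced.shape[0], threshold)
    graph = build_graph(reduced, threshold)
    geodesics = geodesic_distances(graph)
    radius = estimate_radius(geodesics)
    log.info("estimate_view_angles: sphere radius r=%.6g", radius)
    embedding = embed_circle(gram_operator(geodesics, radius))

    embedded = angles_from_embedding(embedding)[membership]
    if config.feature_mode == "magnitude":
        # the embedded circle winds twice per object turn: angles are
        # recovered modulo pi and spread over the half turn
        log.warning("magnitude features: view angles recovered modulo pi; "
                    "assignment uses the half-turn convention [0, pi)")
        return refine_uniform(embedded / 2.0, period=np.pi,
                              refine=config.refine)
    return refine_uniform(embedded, period=TWO_PI, refine=config.refine)
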