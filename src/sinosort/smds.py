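"""Spherical multidimensional scaling onto the unit circle.

Classical MDS embeds points in a flat space, but projection features of a
2D object are intrinsically parameterized by a single angle: they live on
a circle.  Spherical MDS replaces the flat double-centering step with the
dot-product (Gram) form appropriate to a sphere of radius ``r``: two
points at geodesic distance ``g`` on that sphere have dot product
``r^2 * cos(g / r)``.  The top two eigenvectors of this Gram matrix,
scaled by the square roots of their eigenvalues and normalized per point,
are the circle coordinates of the embedded projections.

The embedding is identifiable only up to a global rotation and a global
reflection of the circle; downstream consumers must quotient both out.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

__all__ = [
    "CircleEmbedding",
    "DegenerateEmbeddingError",
    "estimate_radius",
    "gram_operator",
    "embed_circle",
]

log = logging.getLogger(__name__)


class DegenerateEmbeddingError(ValueError):
    """The Gram spectrum has no usable second direction.

    Typical causes: a (nearly) symmetric object whose projections coincide,
    or a threshold so small that the geodesics degenerate.
    """


@dataclasses.dataclass
class CircleEmbedding:
    """Unit-circle coordinates of the embedded projections."""

    points: np.ndarray        # N x 2, rows of unit norm
    eigenvalues: tuple[float, float]
    raw_eigvecs: np.ndarray   # N x 2 selected eigenvectors, pre-normalization


def estimate_radius(geodesics: np.ndarray) -> float:
    """Sphere radius from the largest geodesic distance.

    The two most distant projections are taken to be antipodal on the
    circle, i.e. ``max(M) = pi * r``.  Graph detours can only overestimate
    geodesics, which shrinks cosine arguments mildly; the arccos clamp in
    :func:`gram_operator` guards the opposite error.
    """
    largest = float(np.max(geodesics))
    if largest <= 0:
        raise ValueError("all geodesic distances are zero: projections "
                         "are indistinguishable")
    return largest / np.pi


def gram_operator(geodesics: np.ndarray, radius: float) -> np.ndarray:
    """Dot-product form of the geodesic distance matrix on a sphere.

    ``Gamma_ij = r^2 * cos(min(M_ij / r, pi))`` with an exact ``r^2``
    diagonal.  On an exact circle this matrix has rank 2 and its top two
    eigenvectors carry the cosines and sines of the point angles.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    geodesics = np.asarray(geodesics, dtype=float)
    gram = radius ** 2 * np.cos(np.minimum(geodesics / radius, np.pi))
    gram = 0.5 * (gram + gram.T)
    np.fill_diagonal(gram, radius ** 2)
    return gram


def _is_admissible(eigvec: np.ndarray, cv_tol: float = 1e-6) -> bool:
    # skip (near-)constant-magnitude patterns: they carry no angular
    # information and can appear under uneven angular sampling
    magnitudes = np.abs(eigvec)
    mean = magnitudes.mean()
    return mean > 0 and magnitudes.std() / mean >= cv_tol


def embed_circle(gram: np.ndarray, radius: float | None = None,
                 ) -> CircleEmbedding:
    """Embed points on the unit circle from a spherical Gram matrix.

    Eigendecomposes ``gram``, selects the two admissible eigenvectors of
    largest eigenvalue, scales each by the square root of its eigenvalue
    (so unequal eigenvalues do not bias angles), and normalizes each
    per-point pair to a unit vector.

    Raises
    ------
    DegenerateEmbeddingError
        If the second eigenvalue is not positive or is below ``1e-10``
        of the first — the signature of a symmetric object or a collapsed
        geodesic structure.
    """
    gram = np.asarray(gram, dtype=float)
    if gram.ndim != 2 or gram.shape[0] != gram.shape[1]:
        raise ValueError("gram matrix must be square")
    if not np.allclose(gram, gram.T, atol=1e-9 * max(1.0, np.abs(gram).max())):
        raise ValueError("gram matrix must be symmetric")
    eigvals, eigvecs = np.linalg.eigh(gram)
    selected: list[int] = []
    for j in np.argsort(eigvals)[::-1]:
        if _is_admissible(eigvecs[:, j]):
            selected.append(j)
        if len(selected) == 2:
            break
    if len(selected) < 2:
        raise DegenerateEmbeddingError("fewer than two informative eigenvectors")
    lam1, lam2 = float(eigvals[selected[0]]), float(eigvals[selected[1]])
    if lam2 <= 0 or lam2 <= 1e-10 * lam1:
        raise DegenerateEmbeddingError(
            f"degenerate embedding: eigenvalues ({lam1:.3g}, {lam2:.3g}) — "
            "symmetric object or too-small threshold")
    log.info("circle embedding: top eigenvalues %.6g, %.6g", lam1, lam2)

    raw = eigvecs[:, selected].copy()
    for k in range(2):  # deterministic sign: largest-magnitude entry positive
        col = raw[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            raw[:, k] = -col
    scaled = raw * np.sqrt([lam1, lam2])
    norms = np.linalg.norm(scaled, axis=1)
    tiny = np.flatnonzero(norms < 1e-12)
    if tiny.size:
        raise DegenerateEmbeddingError(
            f"point {tiny[0]} has no direction in the embedding plane")
    return CircleEmbedding(points=scaled / norms[:, None],
                           eigenvalues=(lam1, lam2), raw_eigvecs=raw)
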