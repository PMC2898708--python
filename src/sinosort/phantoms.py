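"""Synthetic phantoms and parallel-beam projection simulation.

The object lives on the square ``[-1, 1]^2`` and is assumed to vanish
outside the inscribed unit disk, so that every parallel-beam projection is
fully captured on the detector interval ``t in [-1, 1]``.  A projection at
view angle ``theta`` is the set of line integrals along lines perpendicular
to the direction ``(cos(theta), sin(theta))``; collecting one projection
per (unknown) angle as the rows of a matrix yields a sinogram whose rows
may be arbitrarily shuffled.

This module provides piecewise-constant ellipse phantoms, a certified
line-integral projector, uniform random view angles, and additive Gaussian
noise at a prescribed SNR in dB.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

__all__ = [
    "Ellipse",
    "Sinogram",
    "make_ellipse_phantom",
    "random_asymmetric_phantom",
    "radon_project",
    "sample_random_angles",
    "uniform_shuffled_angles",
    "add_noise",
    "pixel_centers",
]

TWO_PI = 2.0 * np.pi


@dataclasses.dataclass(frozen=True)
class Ellipse:
    """A filled ellipse contributing a constant additive intensity.

    Parameters
    ----------
    center
        ``(x0, y0)`` in object coordinates, i.e. inside ``[-1, 1]^2``.
    semi_axes
        ``(a, b)``, both strictly positive.
    rotation
        Counter-clockwise rotation of the ``a`` axis, in radians.
    intensity
        Additive value inside the ellipse (summed over overlapping
        ellipses and clipped to ``[0, 1]`` at the end).
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float = 0.0
    intensity: float = 1.0

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a > 0 and b > 0):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")

    def fits_in_unit_disk(self) -> bool:
        # conservative bound: farthest ellipse point is within
        # |center| + max(a, b) of the origin
        x0, y0 = self.center
        return math.hypot(x0, y0) + max(self.semi_axes) <= 1.0

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean membership mask for points ``(x, y)``."""
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        dx, dy = x - self.center[0], y - self.center[1]
        u = dx * c + dy * s
        v = -dx * s + dy * c
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


@dataclasses.dataclass
class Sinogram:
    """A stack of parallel-beam projections, one per row.

    ``rows[i, j]`` is the line integral at detector offset
    ``detector_coords[j]`` for the i-th (possibly unknown) view angle.
    ``hidden_angles`` stores the true angles when the sinogram was
    simulated; it is reserved for evaluation and is never consumed by the
    angle-estimation pipeline.
    """

    rows: np.ndarray
    detector_coords: np.ndarray
    hidden_angles: np.ndarray | None = None
    noise_snr_db: float | None = None

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        self.detector_coords = np.asarray(self.detector_coords, dtype=float)
        if self.rows.ndim != 2:
            raise ValueError("sinogram rows must form a 2D matrix")
        n, s = self.rows.shape
        if s < 3 or s % 2 == 0:
            raise ValueError(f"detector sample count S={s} must be odd and >= 3")
        if self.detector_coords.shape != (s,):
            raise ValueError("detector_coords length must match row length")
        if not np.all(np.isfinite(self.rows)):
            raise ValueError("sinogram contains non-finite entries")
        if self.hidden_angles is not None:
            self.hidden_angles = np.asarray(self.hidden_angles, dtype=float)
            if self.hidden_angles.shape != (n,):
                raise ValueError("hidden_angles length must match projection count")
            if np.any(self.hidden_angles < 0) or np.any(self.hidden_angles >= TWO_PI):
                raise ValueError("hidden_angles must lie in [0, 2*pi)")

    @property
    def n_projections(self) -> int:
        return self.rows.shape[0]

    @property
    def n_samples(self) -> int:
        return self.rows.shape[1]

    @property
    def detector_spacing(self) -> float:
        return 2.0 / (self.n_samples - 1)


def pixel_centers(grid_size: int) -> np.ndarray:
    """Centers of the pixels along one axis of the ``[-1, 1]^2`` grid."""
    step = 2.0 / grid_size
    return -1.0 + step * (np.arange(grid_size) + 0.5)


def make_ellipse_phantom(ellipses: list[Ellipse], grid_size: int) -> np.ndarray:
    """Rasterize a list of ellipses onto a ``grid_size x grid_size`` image.

    Pixel value = clip(sum of intensities of ellipses containing the pixel
    center, 0, 1).  Every ellipse must fit inside the unit disk inscribed
    in the image, so its projections are fully captured on ``[-1, 1]``.
    """
    if grid_size < 32:
        raise ValueError(f"grid_size must be >= 32, got {grid_size}")
    for e in ellipses:
        if not e.fits_in_unit_disk():
            raise ValueError(f"ellipse extends outside the unit disk: {e!r}")
    xs = pixel_centers(grid_size)
    x = xs[None, :]
    y = xs[:, None]
    image = np.zeros((grid_size, grid_size))
    for e in ellipses:
        image += e.intensity * e.contains(x, y)
    return np.clip(image, 0.0, 1.0)


def _mirror_difference_fraction(image: np.ndarray, other: np.ndarray,
                                tol: float = 1e-3) -> float:
    return float(np.mean(np.abs(image - other) > tol))


def _is_asymmetric(image: np.ndarray, min_fraction: float = 0.01) -> bool:
    """True if the image differs from all its mirror/rotation copies.

    Checks left-right and up-down mirrors plus 90 and 180 degree rotations;
    each must differ at more than ``min_fraction`` of the pixels.
    """
    candidates = [
        image[:, ::-1],
        image[::-1, :],
        np.rot90(image),
        np.rot90(image, 2),
    ]
    return all(_mirror_difference_fraction(image, c) > min_fraction
               for c in candidates)


def random_asymmetric_phantom(seed: int, grid_size: int = 128,
                              n_ellipses: int = 6,
                              max_attempts: int = 100) -> np.ndarray:
    """Reproducible random phantom guaranteed to lack mirror/rotation symmetry.

    Symmetric objects produce indistinguishable projections from distinct
    view angles, which makes angle recovery ill-posed; the generator
    resamples until the image fails every symmetry it tests for.
    """
    if n_ellipses < 3:
        raise ValueError("need at least 3 ellipses for a useful phantom")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        ellipses = []
        for _ in range(n_ellipses):
            a = rng.uniform(0.08, 0.35)
            b = rng.uniform(0.08, 0.35)
            margin = 1.0 - max(a, b) - 0.02
            rad = rng.uniform(0.0, max(margin, 0.0))
            ang = rng.uniform(0.0, TWO_PI)
            ellipses.append(Ellipse(
                center=(rad * math.cos(ang), rad * math.sin(ang)),
                semi_axes=(a, b),
                rotation=rng.uniform(0.0, math.pi),
                intensity=rng.uniform(0.2, 1.0),
            ))
        image = make_ellipse_phantom(ellipses, grid_size)
        if image.sum() > 0 and _is_asymmetric(image):
            return image
    raise RuntimeError(
        f"could not draw an asymmetric phantom in {max_attempts} attempts")


def sample_random_angles(n: int, seed: int) -> np.ndarray:
    """``n`` i.i.d. view angles, uniform on ``[0, 2*pi)``."""
    if n < 2:
        raise ValueError("need at least 2 view angles")
    return np.random.default_rng(seed).uniform(0.0, TWO_PI, size=n)


def uniform_shuffled_angles(n: int, seed: int) -> np.ndarray:
    """``n`` exactly uniform view angles ``2*pi*k/n`` in random order.

    The acquisition protocol of the quantitative experiments: projections
    are generated uniformly around the circle and then shuffled, so the
    orderless sinogram still samples every direction evenly.
    """
    if n < 2:
        raise ValueError("need at least 2 view angles")
    grid = TWO_PI * np.arange(n) / n
    return np.random.default_rng(seed).permutation(grid)


def radon_project(image: np.ndarray, angles: np.ndarray, n_samples: int = 299,
                  ) -> Sinogram:
    """Parallel-beam line-integral projections of ``image``.

    Row ``i``, sample ``j`` is the integral of the image along the line at
    signed distance ``t_j`` from the origin, perpendicular to the direction
    ``(cos(theta_i), sin(theta_i))``.  Integration samples the image with
    bilinear interpolation at a step of half a pixel; samples outside the
    grid contribute zero.  The true angles are recorded as
    ``hidden_angles`` for evaluation.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be a square 2D grid")
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.size == 0:
        raise ValueError("angle list must be nonempty")
    if np.any(angles < 0) or np.any(angles >= TWO_PI):
        raise ValueError("angles must lie in [0, 2*pi)")
    if n_samples < 3 or n_samples % 2 == 0:
        raise ValueError(f"n_samples must be odd and >= 3, got {n_samples}")

    grid_size = image.shape[0]
    t = np.linspace(-1.0, 1.0, n_samples)
    step = 1.0 / grid_size  # half a pixel
    s = np.arange(-1.0, 1.0 + 0.5 * step, step)
    rows = np.empty((angles.size, n_samples))
    # object coordinate -> fractional pixel index (pixel centers at
    # -1 + (i + 0.5) * 2/P)
    to_index = lambda c: (c + 1.0) * (grid_size / 2.0) - 0.5
    for i, theta in enumerate(angles):
        c, sn = math.cos(theta), math.sin(theta)
        x = t[:, None] * c - s[None, :] * sn
        y = t[:, None] * sn + s[None, :] * c
        vals = ndimage.map_coordinates(
            image, np.stack([to_index(y).ravel(), to_index(x).ravel()]),
            order=1, mode="constant", cval=0.0)
        rows[i] = vals.reshape(n_samples, -1).sum(axis=1) * step
    return Sinogram(rows=rows, detector_coords=t, hidden_angles=angles)


def add_noise(sino: Sinogram, snr_db: float, seed: int) -> Sinogram:
    """Add zero-mean Gaussian noise at the prescribed SNR (in dB).

    The noise variance is set from the variance of all noiseless sinogram
    entries jointly: ``sigma^2 = Var(rows) / 10**(snr_db / 10)``, so that
    ``10*log10(Var(signal)/Var(noise)) = snr_db``.  ``snr_db = +inf``
    leaves the data untouched.
    """
    if snr_db == np.inf:
        return dataclasses.replace(sino, rows=sino.rows.copy(),
                                   noise_snr_db=np.inf)
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite or +inf")
    signal_var = float(sino.rows.var())
    if signal_var == 0.0:
        raise ValueError("cannot set a finite SNR on a zero-variance sinogram")
    sigma = math.sqrt(signal_var / 10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(seed)
    noisy = sino.rows + rng.normal(0.0, sigma, size=sino.rows.shape)
    return dataclasses.replace(sino, rows=noisy, noise_snr_db=float(snr_db))
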