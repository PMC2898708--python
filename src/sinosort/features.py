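"""Fourier-domain features of projections.

By the Fourier slice theorem, the 1D Fourier transform of a projection at
angle ``theta`` is the central slice of the object's 2D Fourier transform
along direction ``theta``.  Distances between projections are therefore
computed between their Fourier transforms, which allows band truncation
(noise robustness: high frequencies are buried first) and a magnitude-only
mode (invariance to detector shifts, at the price of collapsing ``theta``
and ``theta + pi``).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .phantoms import Sinogram

__all__ = ["FeatureMatrix", "fft_features"]

MODES = ("complex", "magnitude")


@dataclasses.dataclass
class FeatureMatrix:
    """Band-limited Fourier features, one row per projection.

    ``weights`` carries the conjugate-symmetry multiplicity of each
    retained bin (1 for DC, 2 for the others with odd sample counts), so
    that weighted L2 distances between feature rows reproduce
    ``sqrt(S)`` times the time-domain L2 distance at full band.
    """

    vectors: np.ndarray          # N x B, complex or nonnegative real
    mode: str
    band: tuple[int, int]        # (lo, hi) retained frequency bin indices
    weights: np.ndarray          # B bin multiplicities

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        lo, hi = self.band
        if hi - lo + 1 < 2:
            raise ValueError("need at least 2 frequency bins")
        if self.vectors.shape[1] != hi - lo + 1:
            raise ValueError("band width inconsistent with vector length")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("feature matrix contains non-finite entries")
        if self.mode == "magnitude" and (
                np.iscomplexobj(self.vectors) or np.any(self.vectors < 0)):
            raise ValueError("magnitude features must be real and >= 0")

    @property
    def n_bins(self) -> int:
        return self.vectors.shape[1]


def fft_features(sino: Sinogram, mode: str = "complex",
                 band_fraction: float = 1.0) -> FeatureMatrix:
    """Transform every projection row into its (band-limited) Fourier vector.

    Parameters
    ----------
    mode
        ``"complex"`` keeps the complex spectrum (distinguishes ``theta``
        from ``theta + pi``); ``"magnitude"`` takes the modulus
        (shift-invariant, but folds the circle of view angles in half).
    band_fraction
        Fraction of the non-redundant frequency range to retain, counted
        from DC upward; ``0.5`` is the recommended noisy-data setting and
        ``1.0`` keeps everything.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if not 0.0 < band_fraction <= 1.0:
        raise ValueError("band_fraction must be in (0, 1]")
    bad = np.flatnonzero(~np.isfinite(sino.rows).all(axis=1))
    if bad.size:
        raise ValueError(f"projection row {bad[0]} contains non-finite values")

    n_samples = sino.n_samples
    n_bins = n_samples // 2 + 1  # non-redundant half spectrum (real input)
    keep = min(n_bins, max(2, math.ceil(band_fraction * n_bins)))
    spectrum = np.fft.rfft(sino.rows, axis=1)[:, :keep]
    weights = np.full(keep, 2.0)
    weights[0] = 1.0
    if n_samples % 2 == 0 and keep == n_bins:  # unpaired Nyquist bin
        weights[-1] = 1.0
    if mode == "magnitude":
        vectors: np.ndarray = np.abs(spectrum)
    else:
        vectors = spectrum
    return FeatureMatrix(vectors=vectors, mode=mode, band=(0, keep - 1),
                         weights=weights)
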