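"""Filtered back-projection (inverse Radon transform).

Each projection is ramp-filtered in the frequency domain and smeared back
across the image along its view direction.  Angles in ``[pi, 2*pi)`` are
folded onto ``[0, pi)`` by reversing the detector samples (a projection at
``theta + pi`` is the sample-reversal of the one at ``theta``), which
handles full-circle assignments and half-turn (magnitude-mode)
assignments with one code path.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np

from .phantoms import Sinogram, pixel_centers

__all__ = ["ReconstructedImage", "fbp_reconstruct"]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class ReconstructedImage:
    pixels: np.ndarray
    angles_used: np.ndarray


def _ramp_filter(n_pad: int, spacing: float, window: str) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_pad, d=spacing)
    ramp = np.abs(freqs)
    if window == "hann":
        ramp = ramp * 0.5 * (1.0 + np.cos(np.pi * freqs / freqs.max()))
    elif window != "ramp":
        raise ValueError("window must be 'ramp' or 'hann'")
    return ramp


def fbp_reconstruct(sino: Sinogram, angles: np.ndarray, grid_size: int,
                    window: str = "ramp", clip_negative: bool = True,
                    ) -> ReconstructedImage:
    """Reconstruct a ``grid_size``-square image from angle-assigned rows.

    Parameters
    ----------
    sino
        Projections; row ``i`` was (believed to be) acquired at
        ``angles[i]``.
    angles
        View angle per row, in ``[0, 2*pi)``.  Rows at ``theta >= pi``
        are folded to ``theta - pi`` with sample reversal before
        filtering; duplicate folded angles are averaged (with a warning).
    window
        ``"ramp"`` is the plain Ram-Lak filter; ``"hann"`` apodizes it for
        noisy data.
    clip_negative
        Clip the result at zero (the object is nonnegative).  Disable to
        obtain the raw linear reconstruction.
    """
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.size != sino.n_projections:
        raise ValueError("one angle per projection row is required")
    if angles.size < 8:
        raise ValueError("need at least 8 projections to reconstruct")

    folded = np.mod(angles, 2.0 * np.pi)
    rows = sino.rows.copy()
    flip = folded >= np.pi
    rows[flip] = rows[flip, ::-1]
    folded[flip] -= np.pi

    # average rows whose folded angles coincide
    keys = np.round(folded / 1e-9).astype(np.int64)
    uniq, inverse, counts = np.unique(keys, return_inverse=True,
                                      return_counts=True)
    if np.any(counts > 1):
        warnings.warn("duplicate view angles after folding; averaging rows",
                      stacklevel=2)
        merged = np.zeros((uniq.size, sino.n_samples))
        np.add.at(merged, inverse, rows)
        merged /= counts[:, None]
        merged_angles = uniq * 1e-9
    else:
        merged, merged_angles = rows, folded

    spacing = sino.detector_spacing
    n_pad = 1 << max(int(np.ceil(np.log2(2 * sino.n_samples))), 1)
    ramp = _ramp_filter(n_pad, spacing, window)
    filtered = np.fft.irfft(np.fft.rfft(merged, n_pad, axis=1) * ramp,
                            n_pad, axis=1)[:, :sino.n_samples]

    xs = pixel_centers(grid_size)
    x = xs[None, :]
    y = xs[:, None]
    t = sino.detector_coords
    image = np.zeros((grid_size, grid_size))
    for q, theta in zip(filtered, merged_angles):
        positions = x * np.cos(theta) + y * np.sin(theta)
        image += np.interp(positions, t, q, left=0.0, right=0.0)
    image *= np.pi / merged.shape[0]
    if clip_negative:
        image = np.clip(image, 0.0, None)
    log.info("fbp_reconstruct: %d distinct angles onto %dx%d grid",
             merged.shape[0], grid_size, grid_size)
    return ReconstructedImage(pixels=image, angles_used=angles)
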