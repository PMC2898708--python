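"""Evaluation: registration modulo the global rotation/reflection, MSE,
PSNR, and angle-recovery scores.

Unknown-view-angle reconstruction is identifiable only up to rotating the
whole image and mirroring it, so every comparison against a reference
first quotients those out.  Images are compared on ``[0, 1]`` intensity
scale; PSNR uses ``MAX = 1`` so that ``PSNR = 10*log10(1/MSE)``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, optimize

from .angles import AngleAssignment, wrap_signed
from .phantoms import pixel_centers

__all__ = [
    "EvalReport",
    "mse",
    "psnr",
    "disk_mask",
    "rotate_image",
    "register_rotation",
    "angle_metrics",
    "evaluate_reconstruction",
]

TWO_PI = 2.0 * np.pi


@dataclasses.dataclass
class EvalReport:
    mse: float
    psnr_db: float
    rotation_offset: float
    reflected: bool
    mean_abs_angle_error: float | None = None
    circular_order_agreement: float | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def disk_mask(grid_size: int, radius: float = 1.0) -> np.ndarray:
    """Boolean mask of the disk inscribed in the ``[-1, 1]^2`` grid."""
    xs = pixel_centers(grid_size)
    return xs[None, :] ** 2 + xs[:, None] ** 2 <= radius ** 2


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")


def mse(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Mean squared difference over all pixels (or over ``mask``)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    _check_shapes(a, b)
    diff = (a - b) ** 2
    return float(diff[mask].mean() if mask is not None else diff.mean())


def psnr(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Peak signal-to-noise ratio in dB for ``[0, 1]``-scaled images."""
    err = mse(a, b, mask)
    return np.inf if err == 0 else float(10.0 * np.log10(1.0 / err))


def rotate_image(image: np.ndarray, angle: float) -> np.ndarray:
    """Rotate image content by ``angle`` radians about the grid center.

    Positive angles rotate the object the same way as adding ``angle`` to
    every view angle before back-projection (see the rotation-covariance
    tests); bilinear interpolation, zero fill outside.
    """
    return ndimage.rotate(np.asarray(image, dtype=float),
                          -np.degrees(angle), reshape=False, order=1,
                          mode="constant", cval=0.0)


def register_rotation(recon: np.ndarray, reference: np.ndarray,
                      n_candidates: int = 360,
                      mask: np.ndarray | None = None,
                      ) -> tuple[np.ndarray, float, bool]:
    """Align ``recon`` to ``reference`` over rotations and mirroring.

    Scans ``n_candidates`` equispaced rotations for both the identity and
    the mirrored image, keeps the minimum-MSE candidate, then refines the
    angle with a bounded scalar search.  MSE is evaluated on the inscribed
    disk (border pixels rotate out of frame) unless ``mask`` is given.

    Returns ``(aligned, rotation_offset, reflected)`` where
    ``rotation_offset`` is the angle by which ``recon`` appeared rotated
    relative to ``reference`` (i.e. ``aligned = rotate(mirror?(recon),
    -rotation_offset)``).
    """
    recon = np.asarray(recon, dtype=float)
    reference = np.asarray(reference, dtype=float)
    _check_shapes(recon, reference)
    if mask is None:
        mask = disk_mask(recon.shape[0])

    candidates = TWO_PI * np.arange(n_candidates) / n_candidates
    best = (np.inf, 0.0, False)
    for reflected in (False, True):
        base = recon[:, ::-1] if reflected else recon
        for alpha in candidates:
            err = mse(rotate_image(base, -alpha), reference, mask)
            if err < best[0]:
                best = (err, float(alpha), reflected)
    err0, alpha0, reflected = best
    base = recon[:, ::-1] if reflected else recon

    span = TWO_PI / n_candidates
    result = optimize.minimize_scalar(
        lambda a: mse(rotate_image(base, -a), reference, mask),
        bounds=(alpha0 - span, alpha0 + span), method="bounded",
        options={"xatol": 1e-4})
    alpha = float(result.x) if result.fun < err0 else alpha0
    aligned = rotate_image(base, -alpha)
    return aligned, float(np.mod(alpha, TWO_PI)), reflected


def angle_metrics(estimated: AngleAssignment | np.ndarray,
                  true_angles: np.ndarray,
                  period: float | None = None) -> tuple[float, float]:
    """Score estimated against true view angles modulo rotation/reflection.

    Returns ``(mean_abs_angle_error, circular_order_agreement)``:

    * the error is ``min`` over global reflection ``s`` and rotation
      ``alpha`` of ``mean_i |wrap(s*est_i + alpha - true_i)|``, wrapped on
      the circle of the assignment's period (``pi`` for magnitude-mode
      half-turn assignments, else ``2*pi``);
    * the agreement walks the distinct true circular positions in order
      and counts the fraction of adjacent pairs that remain adjacent in
      the estimated cyclic order (forward rank step of at most 3, which
      tolerates duplicate projections and half-turn twins but rejects the
      multiple-winding collapse of symmetric objects), maximizes over
      reflection, and rescales to ``[-1, 1]`` (1: perfect order, -1:
      unrelated order).
    """
    if isinstance(estimated, AngleAssignment):
        if period is None:
            period = estimated.period
        estimated = estimated.refined_angles
    est = np.asarray(estimated, dtype=float)
    true_angles = np.asarray(true_angles, dtype=float)
    if est.shape != true_angles.shape:
        raise ValueError("estimated and true angle lists differ in length")
    period = TWO_PI if period is None else float(period)
    true_wrapped = np.mod(true_angles, period)

    best_err = np.inf
    for sign in (1.0, -1.0):
        delta = wrap_signed(sign * est - true_wrapped, period)
        # the optimal global rotation makes one residual exactly zero
        shifted = wrap_signed(delta[None, :] - delta[:, None], period)
        best_err = min(best_err, float(np.abs(shifted).mean(axis=1).min()))

    n = est.size
    ranks = np.empty(n, dtype=int)
    ranks[np.argsort(est, kind="stable")] = np.arange(n)
    # one representative per distinct true position (exact ties, e.g. the
    # theta/theta+pi twins of a half-turn folding, carry no order signal)
    order = np.argsort(true_wrapped, kind="stable")
    distinct = np.concatenate(
        [[True], np.diff(true_wrapped[order]) > 1e-9])
    reps = order[distinct]
    if reps.size < 2:
        raise ValueError("all true angles coincide; circular order undefined")
    succ = np.roll(reps, -1)
    window = 3  # forward rank slack: skips twins, rejects multi-winding
    best_frac = 0.0
    for reflected_ranks in (ranks, n - 1 - ranks):
        step = np.mod(reflected_ranks[succ] - reflected_ranks[reps], n)
        frac = float(np.mean((step >= 1) & (step <= window)))
        best_frac = max(best_frac, frac)
    return best_err, 2.0 * best_frac - 1.0


def evaluate_reconstruction(recon: np.ndarray, reference: np.ndarray,
                            assignment: AngleAssignment | None = None,
                            true_angles: np.ndarray | None = None,
                            n_candidates: int = 360) -> EvalReport:
    """Registered MSE/PSNR plus angle scores when the truth is available.

    The reconstruction is clipped to ``[0, 1]`` (its amplitude scale is
    calibrated by the projector/FBP pair) rather than min-max stretched,
    so a single hot pixel cannot deflate the error.
    """
    recon = np.clip(np.asarray(recon, dtype=float), 0.0, 1.0)
    reference = np.asarray(reference, dtype=float)
    aligned, offset, reflected = register_rotation(recon, reference,
                                                   n_candidates=n_candidates)
    mask = disk_mask(reference.shape[0])
    err = mse(aligned, reference, mask)
    report = EvalReport(mse=err, psnr_db=psnr(aligned, reference, mask),
                        rotation_offset=offset, reflected=reflected)
    if assignment is not None and true_angles is not None:
        ang_err, agreement = angle_metrics(assignment, true_angles)
        report.mean_abs_angle_error = ang_err
        report.circular_order_agreement = agreement
    return report
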