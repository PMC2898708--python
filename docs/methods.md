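# Methods

## Model and assumptions

The object is a nonnegative density `f(x, y)` supported on the unit disk
inscribed in `[-1, 1]²`. A parallel-beam projection at view angle `θ` is
the line integral of `f` along lines perpendicular to `(cos θ, sin θ)`,
sampled at `S` equally spaced detector offsets `t ∈ [-1, 1]` (S odd, so a
`t = 0` sample exists; spacing `2/(S−1)`). Restricting support to the
inscribed disk guarantees complete detector coverage, without which the
Radon transform is not invertible from these data.

The estimation problem: given the `N × S` matrix of projections in
arbitrary row order, assign a view angle to every row. By the Fourier
slice theorem the 1D spectra of the rows are central slices of the 2D
spectrum of `f`, so as `θ` sweeps the circle the spectra trace a closed
curve in `C^B`. Sorting rows is equivalent to parameterizing this curve
by its circular coordinate, which is done by spherical MDS on graph
geodesics (an ISOMAP-style construction with a sphere-aware Gram step):

* **Distances.** Weighted L2 between half-spectra, the conjugate-symmetry
  weights (1 for DC, 2 elsewhere for odd S) chosen so that the full-band
  complex distance equals `√S ×` the time-domain L2 distance (Parseval).
* **Graph.** Edges where `0 < d < T` (strict, so exact duplicates never
  form zero-weight edges — duplicates are merged into one node first and
  re-expanded after the embedding). The default `T` is the minimax
  connectivity threshold — the largest edge of the minimum spanning tree
  of the complete distance graph — times a safety factor 1.1: the
  smallest neighborhood scale that keeps the manifold in one piece.
* **Geodesics.** All-pairs Dijkstra on the threshold graph.
* **Spherical Gram step.** On a sphere of radius `r`, geodesic distance
  `g` corresponds to dot product `r² cos(g/r)`; with `r = max(M)/π` (the
  farthest pair is assumed antipodal) the matrix
  `Γ(M) = r² cos(min(M/r, π))` of an exact circle has rank 2, and its
  top two eigenvectors scaled by `√λ` recover the point angles exactly up
  to rotation/reflection (verified to machine precision by the
  exact-circle oracle in the tests; the `√λ` scaling is what removes the
  elliptical bias when the two eigenvalues differ). No double-centering
  is applied: sphere points are already centered on the origin.
  Near-constant-magnitude eigenvectors (coefficient of variation of
  |entries| below 1e-6) are skipped as carrying no angular information;
  eigenvector signs are fixed by making the largest-magnitude entry
  positive, so the output is deterministic.
* **Angles.** `φ = atan2(V₂-, V₁-coordinate)` — the two-argument form is
  required to cover all four quadrants — then a stable ascending sort and
  uniform redistribution `2πk/N`. The refinement assumes the true angles
  sample the circle uniformly; `refine=False` keeps the raw angles for
  non-uniform designs.

Identifiability is only up to a global rotation and reflection; every
comparison against ground truth minimizes over both.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `N` (projections) | 360 | manifold methods need dense sampling; ≥ ~256 recommended |
| `S` (detector samples) | 299 | odd; projection bandwidth comfortably above a 128² grid's content |
| `P` (grid) | 128 | phantom/reconstruction resolution; desk-scale runtimes |
| `feature_mode` | `complex` | magnitude is shift-invariant but cannot distinguish `θ` from `θ+π` (the modulus is invariant to sample reversal); full-circle experiments therefore need complex features |
| `band_fraction` | 1.0 | fraction of the half-spectrum kept; 0.5 recommended with noise (high frequencies drown first) |
| `T` | auto | minimax connectivity × 1.1; must shrink as `N` grows |
| `angle_sampling` | `random` | `uniform` = exactly uniform shuffled angles, the protocol of the quantitative experiments (see below) |
| `filter_window` | `ramp` | Ram-Lak; `hann` apodizes for noisy data |

With magnitude features the embedded circle winds once as the view angle
sweeps half a turn, so angles are recovered modulo `π`, spread over
`[0, π)`, and the reconstruction uses the half-turn sinogram convention.
This is logged loudly; for an asymmetric object it averages the image
with its 180°-rotation, so complex mode is the default.

## Synthetic data: what it emulates, what it does not

`random_asymmetric_phantom` draws 6 ellipses (semi-axes 0.08–0.35,
intensities 0.2–1, clipped to [0, 1]) and resamples until the image
differs from its left-right/up-down mirrors and 90°/180° rotations at
more than 1% of pixels — symmetric objects make distinct view angles
produce identical projections and the problem unidentifiable, which the
suite asserts separately as the expected failure mode.

Two angle protocols are provided. `sample_random_angles` draws i.i.d.
uniform angles; `uniform_shuffled_angles` permutes an exactly uniform
grid. The quantitative experiments use the latter: with i.i.d. draws the
largest angular gap (≈ `2π ln N / N`) forces a large connectivity
threshold that admits shortcut edges between accidentally-similar distant
views, and even a perfectly ordered uniform refinement differs from the
i.i.d. truth by an order-statistics fluctuation of ~`2π·0.3/√N` radians.
Both effects are properties of the angle design, not of the estimator.

The projector integrates the pixel image with bilinear interpolation at
half-pixel steps; it is certified against the analytic chord length of a
disk (≤ 3% at mid-band) and conserves mass at every angle to 2%. A
rasterized disk is not exactly rotation invariant, so projections of the
*pixelized* disk at different angles agree only to the same few-percent
level — a property of the raster, not of the quadrature (the discrepancy
is unchanged at 2×, 4×, 8× finer steps). Rows at `θ` and `θ+π` are exact
sample reversals (identical quadrature points), to 1e-15.

Noise is additive i.i.d. Gaussian with
`σ² = Var(all sinogram entries) / 10^(SNR_dB/10)` — the variance is taken
over all entries jointly; a per-row variant is not provided because the
joint convention is what the SNR sweep in the tests calibrates against.

What the phantoms do *not* emulate: the rich, textured spectra of real
MR/EM images. The ellipse phantoms have sparse spectra and a small
magnitude-feature manifold, which matters for the noise results below.
Passing tests therefore certify the geometry of the method, not its
noise performance on richly textured real data.

## Numerical choices

* FBP: frequency-domain ramp filter with zero-padding to the next power
  of two ≥ 2S, sampled at `rfftfreq(n_pad, Δt)` so the output amplitude is
  calibrated (the known-angle disk round trip reaches 33 dB PSNR at
  N=360 without any rescaling); rows at `θ ≥ π` folded by sample
  reversal; duplicate folded angles averaged with a warning; final scale
  `π / (#distinct folded angles)`; negatives clipped (disable via
  `clip_negative=False`, under which the operator is linear to 1e-9).
* Registration: exhaustive scan over 360 rotations × {identity, mirror}
  scored by MSE on the inscribed disk (border pixels rotate out of
  frame), then a bounded scalar refinement; the identity is always a
  candidate so alignment never degrades the MSE.
* MSE/PSNR: plain per-pixel on [0, 1] images, `PSNR = 10·log₁₀(1/MSE)`
  (the convention is confirmed by its internal consistency check in the
  tests); reconstructions are clipped to [0, 1], not min-max stretched,
  so an outlier pixel cannot deflate the error. Registered comparisons
  use the inscribed-disk mask by default; `mse`/`psnr` accept any mask.
* Angle scores: mean absolute circular error minimized over global
  rotation and reflection (the optimal rotation makes one residual
  vanish, so the exact minimizer is found by scanning the N candidate
  shifts); circular order agreement counts true-adjacent pairs of
  distinct true positions whose estimated cyclic ranks advance by at
  most 3 (tolerating duplicates and half-turn twins), maximized over
  reflection and rescaled to [-1, 1] — a multiply-wound embedding (the
  symmetric-object collapse) scores low even though it preserves local
  step directions. For half-turn (magnitude) assignments both scores are
  computed on the circle of period π.
* Degeneracy guards: `estimate_radius` rejects an all-zero geodesic
  matrix; `embed_circle` raises a structured error when the second
  admissible eigenvalue is ≤ 1e-10 of the first (symmetric object or
  collapsed graph) or a point has no direction in the plane (< 1e-12).

## Problem sizes

The suite and the acceptance script run the pipeline at N up to 512,
S = 299, P = 128 — the same N/S as the quantitative experiments the
package reproduces, with the phantom generator standing in for external
image data. The exact-circle oracle runs at N ∈ {16, 64, 256}; the noise
experiment uses 5 noise seeds at N = 512.

## Known limitations

* **Symmetric objects** are unidentifiable in principle; the pipeline
  reports a degenerate embedding or returns a low-agreement order
  (asserted as expected behavior in the suite).
* **Heavy noise defeats the magnitude-feature configuration on these
  phantoms.** At SNR 10 dB the additive noise floor in the
  magnitude-feature metric exceeds the adjacent-view signal distance and
  approaches the whole manifold diameter, so graph geodesics lose
  additivity and the embedding stops winding the circle; reconstruction
  quality drops by ~4 dB instead of staying within 2 dB, and at 2 dB SNR
  the ordering fails outright. Measured alternatives (complex features,
  narrower bands, larger thresholds, squared-distance debiasing) do not
  recover it at these scales; complex quarter-band features do keep the
  mean angle error at ~0.02–0.03 rad at SNR 10. The corresponding
  acceptance tests are left failing by design rather than weakened.
* Non-uniform angular densities are supported only with `refine=False`
  and inherit the raw embedding's metric warp.
* 3D geometries, fan/cone beams, detector PSFs, and Poisson noise are out
  of scope.
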