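# Methods

## Orientation model

A streamline is a finite point sequence (γ₁, …, γ_N) in world millimeters,
N ≥ 2. Local orientation at an interior point is the normalized vector
connecting its neighbors, γ_{i+1} − γ_{i−1}; the first and last points use
the forward and backward difference. These are *axes* (sign-free): every
downstream quantity depends on them only through |n·t| or the dyadic
n nᵀ, so reversing a streamline's point order changes nothing observable
except the sign of the endpoint chord.

The scatter matrix S = (1/N) Σ n_i n_iᵀ is symmetric positive semidefinite
with unit trace. Its first eigenvector is both the dominant segment axis
and the maximum-likelihood mean axis of a bipolar Watson distribution
fitted to the segment axes; its sorted eigenvalues give the linear
coefficient c_l = (β₁ − β₂)/(β₁ + β₂ + β₃). Closed forms used as test
oracles: a planar quarter-circle arc has tangent-dyadic integrals
S = [[1/2, −1/π], [−1/π, 1/2]] in-plane, hence c_l = 2/π and dominant axis
along the 45° diagonal between the chord endpoints' tangents; a semicircle
has β₁ = β₂ = 1/2 in-plane and c_l = 0.

Numerical choices:

- Eigenvectors are axes (±s₁ equivalent); the sign is fixed so the
  largest-magnitude component is positive, making outputs deterministic.
  With β₁ = β₂ (exact ties, e.g. two orthogonal axes) the returned axis is
  whichever eigenvector the symmetric eigensolver orders first under this
  sign rule; it is deterministic but otherwise arbitrary, and documented as
  such.
- Eigenvalues below 10⁻¹² · β₁ are snapped to exact zero. A perfectly
  straight streamline yields a rank-1 scatter matrix whose small
  eigenvalues are pure solver noise (~10⁻¹⁶); snapping makes the c_l = 1
  straight-line limit exact rather than 1 − ε.
- The endpoint chord is undefined for closed loops (‖γ_N − γ₁‖ < 10⁻⁹ mm);
  the operation returns `None` and opacity assignment falls back to fully
  opaque for such streamlines, logged.
- Coincident consecutive points would make a local orientation 0/0. They
  are removed at file ingest (with a logged count); the geometry layer
  raises a degenerate-geometry error if it still encounters one.

## Opacity

α_decreasing = (1 − |n·t|)^c and α_increasing = |n·t|^c map [0, 1] → [0, 1]
for any exponent c > 0; they are monotone, mirror images of one another
(α_dec(x) = α_inc(1 − x)), and larger c lowers α_decreasing pointwise on
(0, 1). Default c = 3, the setting used throughout the package's examples;
c ≈ 7 is a noticeably more aggressive fade. The alternative piecewise
linear ramp operates on θ = acos|n·t| ∈ [0, π/2]: α = aθ + b clamped to
[0, 1], defaults a = 2/π, b = 0 (a ramp from 0 at parallel to 1 at
orthogonal). Inner products are validated against a 10⁻⁹ tolerance and then
clipped, so non-unit axes upstream fail loudly rather than silently
producing α outside [0, 1].

Scales: `local` evaluates the function per point; `global_endpoints` and
`global_scatter` evaluate it once per streamline and broadcast, which
preserves the continuous appearance of a pathway at the cost of coarser
selectivity. The dispersion gate T_cl forces α = 1 for any streamline with
c_l < T_cl. The gate uses the scatter-matrix c_l in *all* scales, including
endpoint mode — there is no endpoint-based dispersion measure, and a single
definition avoids mode-dependent semantics. The gate is off by default.

## Watson distribution

Density p(±n; μ, κ) = exp(κ(μᵀn)²) / (4π M(1/2, 3/2, κ)) on S², bipolar
regime κ ≥ 0 only (the girdle regime κ < 0 is out of scope). The 1/(4π)
factor makes the density integrate to 1 under the uniform surface measure,
verified by Gauss–Legendre × trapezoid quadrature in tests. The Kummer
normalizer is summed as its power series Σ κ^k / ((2k+1) k!) to relative
tolerance 10⁻¹²; the closed form (√π/2)·erfi(√κ)/√κ serves as an
independent oracle. Sampling is by rejection from a uniform-sphere
proposal with envelope e^κ — chosen for transparency over specialized
samplers; the acceptance rate (~√(π/κ)/2 for large κ, ≈ 0.12 at κ = 50) is
logged and is unproblematic at the sample sizes used here. Mean-axis
estimation is the first scatter eigenvector of the sample.

## Synthetic phantoms

The generator produces the geometric regimes the method is designed
around: `straight` bundles (corticospinal-like, c_l = 1), planar `arc`
bundles (U-fiber/callosal-like; 90° ⇒ c_l → 2/π, 180° ⇒ c_l → 0),
constant-pitch `helix` bundles, and two straight bundles `crossing` at a
set angle (fiber-crossing clutter). Defaults — 50 streamlines of 100
points, 80 mm length, 30 mm arc radius, 4 mm bundle spread — are plausible
for major human white-matter bundles at tractography point spacings of
~1 mm. Optional per-streamline axis jitter draws a Watson axis around the
bundle's principal direction and rigidly rotates the streamline onto it;
`jitter_kappa=None` (default) disables jitter so analytic expectations
hold exactly. Everything is a pure function of the spec including its
seed.

What the phantoms do *not* emulate: tractography noise along a streamline
(points are noise-free), variable step sizes, fanning/branching topology,
partial-volume or false-positive streamlines, and anatomically realistic
bundle shapes. Tests passing on phantoms therefore validate the orientation
statistics, opacity mapping and compositing pipeline — not robustness to
scanner noise or tracking errors.

## Compression

Redundant points in near-linear regions are removed by a greedy sequential
scan: from the last kept point, extend the candidate span while every
spanned point lies within the tolerance of the chord to the candidate
endpoint (point-to-segment distance); on failure keep the previous
candidate and restart there. The first and last points are always kept,
and every removed point is within the tolerance of the compressed
polyline, verified as a property on random smooth streamlines. Default
tolerance 0.01 mm. Tolerance 0 removes only exactly-collinear interior
points.

## Rendering

Orthographic projection is the default (anatomical axis-aligned views are
orthographic in character); perspective is available. Segment opacity is
the arithmetic mean of its endpoint opacities and segment color the DEC
encoding of the normalized endpoint difference — opacity is attributed to
points, but the raster primitive is the segment, and the mean is the
simplest consistent reduction. All segments of the whole tractogram are
depth-ordered together (not per streamline) by mean distance along the
viewing axis, far-to-near, with a stable sort for ties, then composited
with the back-to-front "over" operator. Rasterization is 1-px Bresenham
lines with no antialiasing, so renders are bit-reproducible; this trades
visual smoothness for exact testability. Painter's-algorithm compositing is
approximate where segments intersect in depth, which at 1-px lines is
visually negligible.

## File formats

TRK and TCK are read and written through nibabel's streamline API, always
converting to world millimeters (RAS+) on read. TRK carries per-point
scalars natively; TCK and the plain-text polyline dialect (one `x y z` per
line, blank line between streamlines) cannot, so the opacity channel is
written to a `<file>.alpha.txt` sidecar with the same blank-line-delimited
layout, and picked up again on read. Validation (scalar lengths, α range)
runs before any bytes are written.

## Problem sizes

The test suite and the acceptance script run on synthetic inputs sized for
convergence of their analytic limits: arcs up to 2×10⁴ points for the
c_l integrals, 10⁵ axes for the uniformity check of |n·t|, 10³-sample
Watson recovery over 20 replicates, 100 random streamlines for the
compression bound, and 256×256 renders. The full suite completes in a few
seconds on one core.
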