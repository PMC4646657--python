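# Methods

This note records how the model is realized numerically, the parameter
choices that matter, what the synthetic phantoms do and do not emulate,
and the design decisions taken where the formulation was genuinely open.

## Vesselness enhancement

The local-phase channel is computed with oriented log-Gabor quadrature
pairs constructed in the frequency domain: a radial log-Gaussian at each
scale's center frequency (2-octave bandwidth, i.e. `σ/f₀ ≈ 0.555`) times
a single-half-plane angular Gaussian (spread `(π/J)/1.5`).  The inverse
transform of this one-sided spectrum is a complex kernel whose real part
is the even (line) filter and whose imaginary part is the odd (edge)
filter.  Kernels are built on a 63×63 grid (odd, so the frequency
lattice is closed under 90° rotations and orientation symmetries hold
exactly) and cropped to the configured spatial support (default 15×15);
cropping is followed by exact (anti)symmetrization and removal of the
even kernel's residual DC component, so constants produce strictly zero
response.  Defaults: center frequency `5π/7` at the finest scale,
halving per scale, 3 scales, 6 orientations, `β = 2`.

The odd responses are rectified (`|o|`) before the orientation sum, so
the per-scale response `q_m = Σ_j e_j + i Σ_j |o_j|` is
orientation-invariant for inputs rotated by a bank angle.  Scales merge
by the magnitude-weighted mean; the bounded map
`V = P|P|/(P²+α²)` uses `α = 0.1·max|P|` per image, floored at an
absolute `1e-6` so a structureless image cannot saturate round-off
noise into ±0.99.  The map is built for **bright** curvilinear
structures; on fundus green channels, where vessels are dark, negate
the input (or the map) first.

## Local two-feature Gaussian statistics

The window `ω` is a truncated Gaussian (scale `σ = 3` px, half-width the
smallest odd integer ≥ 2σ, hence a 15×15 mask summing to 1), applied as
two 1-D correlations (exact separable factorization).  For fixed `φ` the
minimizing statistics are the `H_i`-weighted windowed means and
variances per feature and region; denominators are floored at `1e-10`
(inert, since those means are multiplied by the vanishing `H_i`), and
every standard deviation at `1e-2` (on the 0–255 intensity scale, same
floor on the vesselness channel) so `log σ` and `1/σ²` stay finite on
locally constant data.

The per-pixel data terms fix the feature value at the output pixel and
let the statistics vary over the surrounding window centers,

    e_i(x) = ∫ ω(x−y) [log 2π + log σ_i(y) + (u_i(y) − F(x))²/2σ_i(y)²] dy,

which is the form the first variation of the region energy produces
(each pixel is judged by every neighborhood containing it); with it,
`δ_ε(φ)(λ₁e₁ − λ₂e₂)` is the exact descent direction of the bookkept
data energy, and logged energies decrease monotonically after the
initial transient.  The constant is kept as `log 2π` in both the force
and the energy, so the two stay consistent (it is φ-independent per
pixel and nearly cancels between regions).

## Level-set evolution

Convention: `φ < 0` inside, region 1 = interior, `H₁ = H_ε(−φ)`.  One
explicit Euler step (Δt = 0.1) assembles

    ∂φ/∂t = δ_ε(φ)·F_data + ν δ_ε(φ)·div(∇φ/|∇φ|)
            + μ (∇²φ − div(∇φ/|∇φ|)) + γ-force,

with central differences, edge-mirrored boundaries, and gradient
magnitudes floored at 1e-10.  The γ-force is the descent direction of
the small-|φ| penalty `η γ^κ/(γ^κ+|φ|^κ)`:
`η κ γ^κ |φ|^{κ−1} sign(φ)/(γ^κ+|φ|^κ)²`, pushing φ away from zero and
vanishing in the far field (γ = 3 px, κ = 2, η = 1; κ restricted to
integers so powers of negative φ are well defined).  The sign matters:
the opposite orientation attracts the whole |φ| < γ band to zero and
erases the interface — measured Dice drops from 1.0 to 0.0 on the
two-phase disk — so the energy-consistent direction is used.

**Heaviside width ε.**  The arctan Heaviside has 1/φ tails, so ε
controls how much each region's statistics leak into the other at the
working amplitude |φ| ≈ c₀ = 2.  At ε = 1 the leakage is ~15 %, which
inflates the local σ estimates enough to cap data forces at |F| ≈ 10
while the curvature term (ν = 0.00065·255², with δ_max·ν·Δt ≈ 1.3)
injects O(1) noise into φ everywhere — even a ground-truth φ then decays
to Dice 0.0 on the standard phantom.  The default ε = 0.1 keeps leakage
below ~2 % and confines the curvature flow to the interface; held-truth
Dice rises monotonically with sharper ε (1.0 → 0.0, 0.5 → 0.29,
0.25 → 0.72, 0.1 → 0.92).  ε remains configurable.

**Initialization.**  Local-Gaussian region models discriminate only
within the window's reach of the contour, so capture requires the
initial interior to be vessel-dominated; a large background-dominated
disk converges to the "everything is background" basin.  φ is
initialized as a binary step ±c₀ (c₀ = 2) over either seed disks
(default: one centered disk of radius min(H, W)/4, kept for generic
objects) or, recommended for vessels, the thresholded vesselness map
(`initialize_from_vesselness`, default threshold 0.35).  The final
segmentation is insensitive to that threshold across 0.2–0.5 (Dice
differences < 0.01 on the phantom).

**Stopping.**  Runs stop at `max_iters` (default 400) or when the
fractional change of the interior pixel count over a 10-iteration
window falls below `tolerance` (1e-4), checked only after `min_iters`
(50) warm-up steps — the integer area is static during the first
iterations while the statistics organize, which would otherwise trigger
immediately.

## Baselines

CV (two global means, no μ/γ terms), LBF (Gaussian-window local mean
fitting, μ term) and LGDF share the initialization, Heaviside/Dirac,
curvature and stopping code paths; only the data forces differ, and
LGDF *is* the multi-feature model with zero vesselness weights (the
equality is bit-exact and tested).  Baseline parameters default to the
shared values so comparisons vary only the model.

## Synthetic phantoms

The generators emulate exactly the structure the model assumes: tubes
of width 1–10 px along quadratic-spline centerlines (rasterized by
continuous distance-to-centerline, so a width-4 tube centered between
pixel rows covers exactly 4 rows), additive contrast on a constant
background, a smooth multiplicative bias field (mean exactly 1, extremes
± amplitude), then i.i.d. Gaussian sensor noise — in that order; ground
truth is geometric and precedes bias/noise.  The standard phantom is
128×128 with tubes of widths 2/4/7 (one crossing), background 80,
contrast +60, bias amplitude 0.25, noise std ∈ {1, 3, 5}.

What passing tests show: the implementation recovers the generating
statistics, descends its energy, is robust to noise and initialization,
and the vesselness channel measurably improves thin-vessel recovery
over the single-feature model.  What they do not show: performance on
real fundus images — phantoms lack texture, the optic disc, pathology,
dark-on-bright vessel polarity, and contrast that varies along vessels.

One comparison deserves honesty: on these phantoms the Chan–Vese model
is *strong*, not weak.  A multiplicative bias of ±25 % on an additive
contrast of +60 over background 80 leaves the two class intensity
ranges globally separable (contrast ratio 1.75 vs bias ratio 1.67) with
equal variances, so the global-means optimum nearly coincides with the
truth (Dice ≈ 0.97–1.0).  The inhomogeneity-driven CV failure seen on
real images corresponds to class-histogram overlap, which this
acquisition model cannot produce at that amplitude; CV's documented
failure mode does appear, and is tested, on the equal-mean /
different-variance fixture (CV Dice ≈ 0.5 vs LGDF ≈ 0.99) and under
strong shading with reduced contrast (CV < 0.7 where LBF > 0.9).

## Problem sizes

The test suite and the acceptance script run on 32–96 px fixtures,
128×128 phantoms and one 256×256 statistics fixture; evolutions
converge in 70–150 iterations at these sizes.  All randomness is
seeded; every generator is a pure function of its spec and seed.

## Known limitations

- Explicit time stepping: the curvature term operates beyond its formal
  stability limit at the default ν·Δt and relies on the μ-diffusion and
  the sharp δ_ε localization for stability; very large ν or Δt will
  abort with a diagnostic rather than silently diverge.
- Two regions only; no narrow-band acceleration (desk-scale images do
  not need it); no multi-page TIFF, DICOM or 3-D input.
- The vesselness polarity assumes bright vessels; callers must negate
  dark-vessel imagery.
- `Auc` is the (Se+Sp)/2 summary conventional in this literature, not a
  ROC integral.
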