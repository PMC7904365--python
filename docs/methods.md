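# Methods

This note documents the models implemented in `oct_edema`, the parameters
that matter, and the numerical choices made where the design was open.

## Observation model and phantom generator

OCT B-scans are modelled as

    I(x, y) = S(x, y) · N_s(x, y) + N_b(x, y)

with `S` the noise-free reflectance, `N_s` multiplicative speckle and `N_b`
additive background noise. The generator rasterizes `S` as a
piecewise-constant scene: a bright retinal band (optionally curved by a
smooth per-column offset peaking mid-scan, a crude foveal curvature) on a
dark background, with dark elliptical cavities standing in for edema.
Membership is evaluated at pixel centers (row-major, 0-based).

Distributional choices (neither is dictated by the physics of a specific
scanner; both are the standard idealizations):

- **Speckle**: i.i.d. gamma with shape `k` and scale `1/k` — positive,
  unit mean (so clean intensities stay interpretable), variance `1/k`.
  This is the classical model for incoherently averaged speckle; `k = 4`
  (the default) corresponds to roughly 4-look imaging, a 50% coefficient
  of variation — visually severe but realistic for raw B-scans.
- **Background noise**: i.i.d. zero-mean Gaussian, default sd 0.02. The
  additive term's distribution is an assumption of this package, not a
  physical measurement.

Default scene: 128×256 pixels, band rows 36–91 with 4 px curvature, two
cavities (semi-axes 11×24 and 9×18 px), reflectances 0.78 (tissue), 0.22
(fluid), 0.06 (background). All intensities live in [0, 1]; 8/16-bit I/O
rescales at the boundary, and noisy values are clipped (not wrapped) to
[0, 1], matching display-referred images.

What the phantom does **not** emulate: wave-optics speckle correlation
(real speckle is spatially correlated; ours is white), multi-layer
anatomy (ILM/RPE banding), shadowing under fluid, motion artifacts, and
3-D context. Passing tests therefore demonstrate correctness of the
algorithms under the stated noise model, not clinical performance.

## Enhancement

Fixed order: Gaussian smoothing → structure transfer → Retinex.

**Gaussian filter.** Discrete kernel sampled at integer offsets and
renormalized to unit sum (the continuous prefactor is irrelevant after
renormalization); default σ = 1, 5×5 window. Convolution uses reflect
padding. Being a convex combination it never expands the value range.

**Structure transfer.** The output `O` solves

    (λA + DxᵀDx + DyᵀDy) O = λI + DxᵀV_h + DyᵀV_v

with `A` the identity, `Dx`/`Dy` forward differences under replicate
(Neumann) boundaries, and `V` a guidance gradient field. The guidance is
taken from the *original* image smoothed at `guidance_sigma`, so the stage
re-imposes the original's large-scale edges on the smoothed image without
its pixel-scale speckle gradients. The sparse SPD system is solved
directly; the relative residual is checked against 1e-8.

With small λ the solution is dominated by the guidance term, i.e. `O` is
approximately the `guidance_sigma`-blurred original. `guidance_sigma` is
therefore an edge-localization/speckle-suppression trade-off: larger values
smooth more speckle but displace layer boundaries outward by a comparable
number of pixels. Default `guidance_sigma = 1.5` px keeps boundary
placement within ~1 px while retaining two-orders-of-magnitude ENL gains;
λ defaults to 0.05.

**Single-scale Retinex.** `R = ln(I + ε) − ln(G_c ∗ I + ε)` with the
surround `G(x, y, c) = K exp(−(x²+y²)/c²)` normalized to unit mass
(computed separably; window 3 standard deviations, σ = c/√2), ε = 1e-6
guarding 8-bit zeros. OCT images are single-channel, so the per-channel
index of the color formulation collapses to one plane. The log-domain
appears only here — applying a separate logarithmic compression stage as
well would double-log the image.

The surround constant `c` must be large relative to the structures whose
*regional* contrast has to survive: with a small surround (c ≲ the band
height) the band's interior is normalized against itself and the
region-based segmentation downstream loses its driving statistic. Default
`c = 100` px on a 128×256 scan makes the surround an effectively global
illumination estimate. The rescaled output is affinely mapped to [0, 1]
(a constant log-ratio field maps to 0.5 by convention).

## Segmentation (SBGFRLS)

Signed pressure force, with `c1`/`c2` the mean intensities inside (φ > 0,
exact Heaviside; φ = 0 counts as outside) and outside the contour:

    SPF(I) = (I − (c1+c2)/2) / max|I − (c1+c2)/2| ∈ [−1, 1].

One iteration: recompute (c1, c2); explicit update
φ += dt·α·SPF·|∇φ| (central differences); selective binary step
φ ← ±1; Gaussian regularization at `reg_sigma`. Because φ is re-binarized
every iteration, no smoothed Heaviside or re-initialization is needed.

Defaults: α = 20, dt = 1, reg_sigma = 1, max_iter = 500, initial contour a
rectangle inset 10 px from the border. Convergence is declared when the
changed-pixel fraction stays ≤ tol (default 1e-4) for 5 consecutive
iterations; on default phantoms this happens after ~20–25 iterations.

**Finalization.** The frozen binary state of the raw iteration can differ
by single boundary pixels depending on where the contour came from: where
|SPF| is small the update cannot overturn φ, leaving a history-dependent
±1 px jitter. After convergence the contour is therefore snapped to the
zero-pressure set of the force: the midpoint (c1+c2)/2 is iterated to its
fixed point t* (t = (mean{I<t} + mean{I≥t})/2, seeded from the overall
image mean — the midpoint map can admit adjacent fixed points one pixel
apart, and the canonical seed keeps the final contour a pure function of
the image), pixels are relabelled by the sign of the SPF at t*, and the
selective-binary Gaussian regularization is applied once more. This makes
the final partition independent of the initialization while preserving the
level set's smoothness.

**Retina vs edema.** The reported retina mask is the hole-filled largest
connected component of the positive region. Edema is recovered by
`extract_edema`: candidates are the topological holes of that component
plus connected components of sub-threshold pixels strictly inside it — the
balloon force vanishes away from the contour, so a cavity the outer
evolution never swept across still shows up only as a dark pocket. The
threshold is the SPF-midpoint fixed point computed *within* the filled
retina (the value a second region-mean evolution confined to the retinal
interior would converge to). A within-retina threshold is essential on the
Retinex output: the log-ratio transform compresses dark values, which
places fluid above the global band/background midpoint. Components
touching the outer retina boundary are excluded, as are components below
`min_area` (default 16 px, guarding against residual speckle pockets).

Degenerate inputs raise typed errors: a uniformly one-signed φ raises a
contour-collapse error; an image uniformly equal to the SPF midpoint
raises a degenerate-contrast error (the 0/0 in the SPF).

## Metrics

CNR and ENL are averaged over the supplied ROIs (the prefactor is the ROI
count — the only self-consistent reading of a mean over regions); variances
are population variances. CNR is returned raw; a 10·log₁₀ decibel view is
offered at the CLI layer only. Zero-variance regions raise a
degenerate-ROI error rather than returning infinities.

The seven confusion scores use the standard definitions; κ is two-class
Cohen's kappa with chance agreement from the product of the marginals.
Undefined ratios (zero denominators) are reported as NaN, never silently
as 0. Dice > 0.70 is surfaced as an "excellent agreement" flag — a
labelling convention, not a computation.

When the pipeline derives CNR/ENL ROIs from ground truth, the tissue ROI
(band minus fluid) and the background are each eroded by 3 px so the
homogeneous samples exclude boundary mixtures.

## Reproducibility

Only the phantom stage consumes randomness; enhancement and segmentation
are deterministic, so a single seed fixes the whole run. The pipeline
manifest records the config echo, package version, seed and SHA-256
checksums of every stage array; two runs with the same config and seed are
bit-identical. YAML configs are strictly validated — unknown keys are
rejected rather than ignored.

## Problem sizes

The test suite and the acceptance script use 128×256 phantoms, ten
replicates for the simulation-based checks, and exhaustive ≤8×8 cases (200
random draws) for the oracle-equivalence checks; the full suite runs in
well under a minute.

## Known limitations

- The one-pass evolution discovers interior cavities through the
  within-retina threshold, not by contour splitting; cavities whose mean
  intensity is not below the interior midpoint are missed.
- Balloon-force-only evolution has no curvature term beyond the Gaussian
  regularization, so `reg_sigma` controls both smoothness and the minimum
  detectable feature size.
- Depth/volume quantification of edema is out of scope; the tool
  delineates outlines on single B-scans.
- Phantom realism limits are listed above; no claims are made about
  clinical scans.
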