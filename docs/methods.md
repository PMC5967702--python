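# Methods

This note records the models implemented, the parameter choices that
matter, what the synthetic scenes do and do not emulate, and the numerical
decisions a maintainer would otherwise have to reverse-engineer.

## Rig model and metric conversions

The rig is two identical pinhole cameras looking straight down from height
*H* above the ground reference, apertures separated horizontally by the
baseline *G*, focal length *f*, sensor pixel pitch *S_c*. All internal
lengths are millimetres and disparities pixels; reported traits are
centimetres rounded to 0.1 cm (one internal unit avoids conversion bugs;
0.1 cm matches the precision a ruler protocol reports).

For a rectified pair, depth is *P = fG/(dS_c)* and height *h = H − P*.
Heights are computed through the normalized disparity *η = d − d_g*
(*d_g* = ground-level disparity):

  h = H² η S_c / (fG + η S_c H)

which is the algebraic composition of the two steps above evaluated at
*d = d_g + η* when *d_g = fG/(HS_c)*. The point of the normalized form is
vibration robustness: a platform shake offsets *d* and *d_g* equally and
cancels exactly. The equivalence of the two routes is enforced in tests to
1e-9 relative error over rigs spanning ±50% of the field geometry.

*S_c* is a required configuration parameter; it is not derivable from the
other three. The metric-conversion test rig uses
S_c = fG/(H·500) ≈ 0.0037895 mm so the ground plane sits at exactly 500 px
of disparity and one pixel covers ≈0.04 cm of ground — the field
configuration. Negative heights (furrow bottoms below the ground
reference) are physically real; height maps clamp them to zero but count
them in a diagnostics channel.

Open design point: the rig model assumes a vertical optical axis with the
principal point at the frame centre and square pixels; no skew or
tangential terms. For an overhead fixed rig this is the appropriate
economy.

## Synthetic scenes

The generator builds a 2.5-D height field over a plot: a sinusoidal-furrow
ground surface, canopy patches covering an exact coverage fraction
(quantile-thresholded smooth random field), canopy heights drawn from a
named family, and optionally a sparse spike layer — a fraction of plant
pixels lifted by a fixed offset, emulating wheat heads protruding above
the leaf canopy near heading.

Canopy heights use a Gaussian copula: a smooth random field is pushed
through the normal quantile function, so the *marginal* distribution
matches the requested family (mode/spread) while the field stays spatially
coherent. Coherence matters: stereo matching needs surfaces that extend
over many pixels, which is also what real leaves look like at the default
5 mm/px footprint. The height-field correlation length defaults to 12 px
(≈6 cm): disparity gradients then stay below the ~1 px/px slope that
census/SGM matching can follow. The patch (coverage blob) scale defaults
to 10 px (≈5 cm gaps and clumps).

The default scene rig keeps the field geometry (f = 18 mm, G = 20 cm,
H = 190 cm) but sets S_c so the ground disparity is 40 px rather than
500 px: a 500 px baseline shift cannot fit inside a 640×480 frame, while at
40 px a frame covers a 3.2 m × 2.4 m plot at 5 mm/px — the scale of a
field plot. All geometry is exercised identically; only the pixel pitch
differs.

Rendering is orthographic texture plus disparity warp, not ray tracing.
The left view is the textured height field from above; the right view is
the left texture forward-splatted along rows by the true disparity at
1/8 px resolution (span-filled so stretched surfaces stay gap-free, with a
z-buffer so near surfaces win), then box-downsampled. Columns no surface
lands on are disocclusions: they are filled with a ground texture carrying
an *independent* noise pattern and flagged in an occlusion mask excluded
from accuracy scoring. Textures are class-colored (green canopy / brown
soil) with band-limited luminance noise (strength 0.25 of base color) so
matching is well-posed; untextured surfaces are a separate failure mode,
deliberately not simulated by default. Optional radial distortion and a
constant vibration offset are applied last, as the lens and the platform
would.

What the scenes do **not** emulate: perspective parallax within a single
view (each view is orthographic; only the stereo displacement is
modelled), leaf-scale BRDF/illumination variation, wind motion between
the two exposures, mutual shading, and thin-structure spikes (spike pixels
are lifted singletons, not rendered stalks). Passing the end-to-end tests
therefore demonstrates the geometry, matcher, and trait logic are correct
— not that the matcher is robust to every field nuisance (illumination is
specifically the census transform's job, and is untested here).

## Self-calibration

One stereo pair of flat ground suffices. On a fronto-parallel rig the
epipolar lines of an undistorted pair are image rows, so radial distortion
appears as vertical displacement of correspondences growing toward frame
edges. Harris corners (rank-selected, no relative threshold, ≤300) are
matched by NCC (11×11 patches, ±8 rows, sub-pixel parabola); the
coefficients (k1, k2) — radial model on radius normalized by the
half-diagonal — minimize the Cauchy-robust (scale 1 px) mean squared row
residual of the undistorted matches, by Nelder-Mead from (0,0), tolerance
1e-6, ≤500 iterations. The Cauchy loss saturates gross mismatches without
discarding the strongly distorted edge matches that carry the signal; hard
inlier thresholds or trimming proved biased for exactly that reason.

After the fit, the deviation of the undistorted disparity field from an
affine plane in (col, row) is evaluated as a planarity diagnostic: above
1 px (median, robust) the scene was not flat enough and a warning is
raised — a canopy pair can never calibrate silently. Identity lenses
recover |k1| < 0.001 and a k1 = −0.10 barrel lens recovers within a few
percent across scene realizations; pincushion and |k1| ≥ 0.2 are less
accurate (fewer usable edge matches) and are outside the validated range.

## Rectification

Fundamental matrix by normalized 8-point inside RANSAC (threshold 1 px,
≤500 trials, seeded). If the inlier correspondences already share rows
(95th percentile |Δrow| ≤ 0.5 px), the transforms are the identity and the
images are passed through (or only lens-corrected) — no needless
resampling. Otherwise Hartley's method maps the right epipole to infinity
(rotating through the minimal angle so orientation is preserved), derives
the matching left homography, least-squares-corrects its affine x-part to
minimize disparity, re-centers both outputs, and aligns mean rows. Lens
correction and the homography are composed into one bilinear resampling
per image. Dimensions never change.

Note that projective rectification rescales the disparity field, so height
maps obtained through a non-trivial Hartley warp carry that scale; the
identity fast path (the common case for a rigid, well-mounted rig) does
not.

## Stereo matching

- Cost: 5×5 census transform per view, Hamming distance (24 bits), chosen
  over intensity SAD for illumination robustness. Out-of-frame candidates
  carry a sentinel cost (25) that can never win.
- Aggregation: standard SGM recurrence along 8 paths; penalties P1 = 8
  (one-level change) and P2 = 96 (jump), on the census bit scale,
  config-exposed. A single path is cost-exact against a brute-force
  scanline DP oracle, by test.
- Search range from geometry: disparities for heights −5 cm (furrows) to
  150 cm (tallest pre-heading canopy) around the rig's ground disparity,
  ±4 px vibration margin, capped at 256 levels. Studies on scenes with a
  known lower canopy ceiling narrow `h_max_mm` accordingly (the evaluation
  studies use 110 cm), which only shrinks compute.
- Selection: winner-take-all (ties to the lowest disparity), parabolic
  sub-pixel refinement clamped to ±0.5 px, then a left-right consistency
  check (tolerance 1 px) between *independently aggregated* left- and
  right-referenced volumes. Deriving the right map from the left volume
  (the cheap standard reuse) shares its failure modes and lets frame-edge
  hallucinations validate themselves; independent aggregation doubles the
  cost and catches them. A raw-cost gate (winner census cost ≤ 12 of 24
  bits — the similarity of unrelated patches) additionally rejects matches
  that only aggregation smoothness invented. Invalid pixels stay masked.
- Ground disparity: median (not mean — robust to stray plant pixels in the
  segmentation complement) of valid ground pixels inside the region of
  interest, requiring ≥100 pixels and agreement with the rig-implied value
  within 8 px (vibration offsets are a few px at most; a larger gap means
  the visible "soil" was mismatched, e.g. under a closed tall canopy).
  Failing either check falls back to the rig-implied d_g with a warning —
  correct in a vibration-free setting, but forfeiting cancellation.

Accuracy under the default synthetic conditions: ≥95% of valid pixels
within 1 px of truth on slab scenes (≈99.9% typical), ~90–93% on dispersed
canopies, with errors concentrated at canopy/ground boundaries where the
census window straddles two surfaces.

## Traits

- Plant segmentation: excess-green index ExG = 2g − r − b on
  chromaticity-normalized channels, Otsu threshold, with a fixed fallback
  (ExG > 0.05) deciding when Otsu's two classes do not straddle it
  (single-class scenes). A user mask can override. The method and
  threshold are recorded in output metadata.
- Region of interest: central 80% of the frame by default, mitigating
  plot-edge and border-row effects.
- Histograms: 1 cm bins (the ruler resolution of the manual protocol),
  plant pixels only (ground pixels at h ≈ 0 excluded; a mask argument
  exposes the choice).
- Percentiles: nearest-rank on the exact pixel-height multiset — the
  smallest height at or below which at least (1 − top_fraction) of plant
  pixels lie. The histogram is for reporting; the multiset is the
  estimator. Canopy height = top-2% threshold, median canopy height =
  top-50%. On concentrated (slab-like) canopies the top-2% threshold
  ignores spike layers below the 2% allowance and jumps to the spike
  height above it; the median tolerates spike fractions an order larger.
  For strongly dispersed height distributions a 1.5% spike layer *does*
  move the top-2% threshold by several cm — the robustness claim is a
  property of concentrated distributions, not of the estimator alone.
- Area normalization: each pixel contributes its physical footprint
  (P·S_c/f)² at its own depth instead of a unit count. Totals then agree
  across camera heights (verified at H = 190 vs 150 cm, <0.1% apart),
  whereas pixel counts scale with the squared footprint ratio.
- Biomass: M = Σ_t ρ_t ∫₀ᵀ a_t(h) dh with the integral as the Riemann sum
  of per-bin areas (each bin already holds the area in its height slice,
  so the sum is exact for binned data — no quadrature error to manage).
  Per-tissue distributions (leaf/stem/spike) are accepted when supplied
  externally; the pipeline itself produces only the combined distribution,
  since tissue segmentation is out of scope. A uniform profile reproduces
  the naive ρ·A·T block product exactly; any other profile is strictly
  below it.

## Batch runs and evaluation

Per-record failures are caught, logged and skipped. Reference comparison
uses least squares through the origin (y = αx), R² computed against the
origin-constrained fit, residual SD with ddof = 1. Replicate dispersion is
the min–max range per bin: with three replicates a standard deviation
would suggest more than the data supports.

Problem sizes in the shipped evaluation: the height-recovery study uses 20
scenes at 640×480, coverage 0.6, spread 8 cm, modes 15–85 cm (true top-2%
heights ≈30–100 cm); smaller frames (160×224 to 240×320) everywhere a
property does not depend on scale. Under those conditions the
origin-constrained slope is ≈0.99, R² ≈ 0.999 and the residual SD
≈0.3–0.6 cm — the residual reflecting rendering and sub-pixel quantization
rather than field nuisances, hence far below what field data shows.

## Known limitations

- The matcher's fronto-parallel bias under-estimates steep local slopes;
  heights at canopy edges are less reliable and partially masked.
- Sub-pixel parabola refinement pulls toward integer disparities (~0.1 px),
  a ≈0.5 cm systematic at these geometries, visible as slope ≈0.99 rather
  than 1.0 in the recovery study.
- Hartley-path rectification rescales disparities (see above); pipelines
  with persistently misaligned rigs should calibrate the rig rather than
  rely on per-pair projective rectification.
- Self-calibration is validated for barrel distortion up to |k1| ≈ 0.15
  with k2 small; stronger or pincushion lenses reduce edge-match quality.
- The biomass estimate shares whatever bias the height map and
  segmentation carry; it is a relative, not absolute, measure unless the
  density ρ is known.
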