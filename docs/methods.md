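# Methods

## Coordinate and angle conventions

Rasters are `(row, col)`, 0-based. Angles live in the mathematical frame
`x = col, y = −row`, so counter-clockwise is positive as displayed.
Orientations of nuclei and cells are *axial* (θ ≡ θ + 180°): differences
between axes are folded to [0°, 90°]. The flow direction is a unit vector
supplied per run; Golgi polarization uses the *directed* full-circle angle
with 0° at the upstream direction (−flow).

Boundary handling for the orientation histogram: the nine bins are
half-open [0°,10°), …, [80°,90°], with 90° assigned to the last bin; the
aligned fraction counts angles strictly below 30°. The source analyses
state the 0–30° rule without specifying boundary behaviour, so the
half-open convention is declared here once and used everywhere.

## Ellipse fitting and eccentricity

Nucleus and cell masks are summarized by the moment-equivalent ellipse:
the ellipse with the same normalized second central moments as the pixel
set. Semi-axes are `2·sqrt(eigenvalues)` of the pixel covariance, with the
1/12 px² continuous-pixel correction (the variance of a unit square),
which makes a 20×10 filled rectangle measure an exact 2:1 axis ratio.
This was chosen over a boundary least-squares ellipse fit because it is
parameter-free, exact on solid shapes and standard in region-properties
toolchains. Eccentricity is the first eccentricity √(a² − b²)/a.
Near-isotropic objects ((a − b)/a < 0.02) carry a `theta_stable=False`
flag, since the major-axis direction of a disc is numerical noise.
Fitting requires ≥ 5 foreground pixels.

## Junctional linearization index

JLI = contour perimeter / convex-hull perimeter. The contour is the
sub-pixel iso-contour of the mask at level 0.5 (marching squares), lightly
smoothed with a periodic Gaussian along the vertex chain
(σ = 0.75 vertices). The smoothing removes marching-squares staircase
inflation — without it a rasterized disc measures ≈ 4% longer than its
true circumference and a convex cell would score JLI ≈ 1.04 — while
rounding true corners so little that a plus-sign polygon stays within 0.03
of its exact polygon geometry. The convex perimeter is the hull of the
same contour vertices (shapely), so both lengths share one discretization.
Holes are filled with a warning; multi-component masks are rejected.
Border-clipped cells are excluded from shape metrics by default because a
perimeter truncated by the field of view is meaningless.

## Circular statistics

Mean direction from the resultant of unit vectors; spread defaults to the
circular standard deviation √(−2 ln R̄) (reported in degrees). The
literature this field leans on ("circular SD" from commercial circular
statistics software) does not print a formula; the angular deviation
√(2(1 − R̄)) is provided as `sd_kind="angular"` so either definition can
be matched, with the circular SD as default. Axial data are doubled
before averaging and mean/SD halved after. Resultant lengths below 1e−9
leave the mean flagged undefined.

## Colour and area fractions

RGB images convert through the standard hexcone HSV model; blue pixels
have hue in the inclusive window [120°, 240°]. No saturation or value
gating is applied by default (none is specified for the assay this
emulates); a `min_saturation` gate is available. Gray pixels (undefined
hue, reported as 0°) count as non-blue. Area fraction is foreground
pixels over ROI pixels; object density is labelled objects per mm², using
the supplied pixel size.

## Vessel geometry

Tube masks are measured by chords perpendicular to the tube axis
(auto-chosen as the longer principal direction), with 5% of the occupied
span trimmed at each end to avoid partially drawn vessel ends; a
medial-axis mode (2× distance transform along the skeleton) handles
curved vessels. Masks with aspect ratio below 2 trigger a non-tubular
warning. Cross-section counting on 3-D stacks labels each slice
independently and bins every cross-section by its equivalent diameter
2√(area/π)·pixel_size, totalling over slices.

## Sprouting depth

Slice z of a label stack lies z·z_step µm below the gel surface (z = 0).
The depth profile sums foreground area per slice. "Sprout length" is not
operationally defined in the source assay; here it is the centroid depth
of an object, averaged over objects deeper than a 5 µm surface-exclusion
band (cells still resting on the surface are not sprouts). With no
invading cell the mean is reported as 0 alongside `n_invading = 0`.

## Synthetic scenes: what they emulate and what they do not

The generator supplies ground truth for every stage: elliptical nuclei
with an exact orientation law and eccentricity, nearest-nucleus cell
polygons with controllable boundary roughness, Golgi blobs at a drawn
angular offset from the upstream direction, constant- or noisy-width tube
phantoms, pure-hue RGB tissue (so HSV conversion is unambiguous), and
ellipsoidal cells at drawn depths. Axial orientations are sampled as von
Mises on the doubled angle and halved (κ = 0 gives the uniform law).
Nuclei are placed by rejection sampling with a minimum separation;
exceeding the retry budget raises an error naming the density. All
randomness flows from one `numpy` Generator per scene, so identical
configs are bit-identical.

Deliberate simplifications: no point-spread function, shot noise,
intensity gradients, touching nuclei, or curved/branching vessel
topology. Passing the test suite therefore demonstrates that the
*measurement chain* is correct on clean, known geometry — not that
segmentation is robust to difficult real microscopy, which is exactly why
thresholds (Otsu default, fixed-level override) and minimum-area filters
are exposed and recorded in the run snapshot.

Boundary jitter re-rasterizes each cell polygon after radial vertex
displacement by smooth periodic noise; contested pixels go to the
lower-numbered cell and unclaimed pixels remain background, read by the
junction channel as junction gaps. Even at zero irregularity, rasterized
polygon boundaries measure a mean JLI slightly above 1 (≈ 1.015), which
is the declared raster tolerance, not a bias in the index; the JLI is
monotone in the jitter amplitude.

The vessel phantom re-centres its edge-noise to zero mean, so the
phantom's nominal diameter is exact by construction and measured
deviations reflect only rasterization.

## Pipeline

Runs are driven by a flat YAML/JSON config validated before any
computation; every resolved default is written to `config_snapshot.json`
next to the outputs, so a snapshot re-run reproduces the CSVs byte for
byte. Per-object and summary tables are CSV; angles are always degrees;
physical units require a pixel size (µm/px) and, for stacks, a z-step.
A metric requested without its channel fails naming the metric.

## Problem sizes

The validation suite uses 200-cell monolayers (1024² px) for orientation
recovery, an 800-cell field (2048² px) for the uniform-orientation
control (keeping binomial sampling noise on the aligned fraction near one
point), 60–100-cell scenes for junction and Golgi metrics, 400-column
vessel phantoms and 200-slice tube stacks — sizes comparable to one
imaging field per condition, chosen so each check isolates measurement
error from sampling error.

## Known limitations

- Segmentation is threshold-based; crowded or low-contrast real images
  need external segmentation, then `LabelImage` inputs are accepted.
- JLI carries a ±0.02–0.03 raster tolerance from contour discretization;
  very small cells (tens of pixels) inflate it further.
- The equivalent-diameter binning treats each slice independently: a
  vessel oblique to z contributes elongated cross-sections whose
  equivalent diameter overestimates its lumen.
- Sprout length as centroid depth underestimates the tip extent of long,
  anisotropic sprouts.
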