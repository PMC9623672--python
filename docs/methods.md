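# Methods

This note documents the models, conventions and numerical choices behind
`teatherm`, in the order the pipeline runs. Defaults throughout are the study
conditions the toolkit is built to reproduce: no image interpolation, fixed
0.1 °C gray-level bins, range re-segmentation off, symmetric GLCM, no
Laplacian-of-Gaussian filtering, all wavelet sub-band features, expression
thresholds P < 0.01 and |d| > 1.2, and 10 × 10-pixel feature-map windows.

## Temperature calibration

A colorized thermogram carries temperature in color, with the displayed range
[T_min, T_max] supplied as sidecar metadata (it is printed beside the image's
colorbar). The lookup table anchors the first and last colorbar colors to
T_min and T_max and assigns interior colors temperatures linear in list
position, quantized half-up to 0.1 °C — the instrument's precision, which also
bounds the useful table size: a 5–40 °C range admits (40−5)/0.1 = 350 steps,
so essentially no interpolation is needed. Conversion assigns each pixel the
temperature of the nearest LUT color by unweighted Euclidean distance over the
three 8-bit channels; ties resolve to the lower LUT index (the colder entry).
Nearest-color matching is also the only robustness mechanism against JPEG
chroma noise; no colorbar auto-detection or OCR is attempted.

Temperatures are stored as unsigned 16-bit integers at 0.1 °C per unit
(8 bits cannot hold 40.0 °C × 10 = 400). DICOM output is single-frame
MONOCHROME2 with rescale slope 0.1 and intercept 0, so conforming viewers
display °C directly; acquisition metadata (emissivity 0.95, reflected
temperature 20 °C, atmosphere 23 °C / 81 % RH, animal id, pre/post label)
travel as a JSON text field. The SOP instance UID is derived from a hash of
the pixel and metadata content, so identical maps produce byte-identical
files and pipeline re-runs can be verified by checksum. No vendor radiometric
tags are emitted and no emissivity correction is applied — the toolkit
quantifies what the camera displayed.

## Segmentation

A teat trace is an ordered (row, col) polyline along the outer perimeter;
where the teat meets the udder the trace is closed with the straight chord
between its endpoints (the "tangent line" of interactive tracing).
Rasterization uses 0-based coordinates with pixel centers at integers: a pixel
is foreground iff its center is inside the polygon under the even-odd rule,
with boundary centers counted as inside. Dice similarity is 2|A∩B|/(|A|+|B|).
Summaries of Dice scores use the sample mean with a percentile bootstrap
interval (default 95 %, ≥1000 resamples, seeded): observed Dice intervals
are asymmetric near 1, so a Gaussian interval would be wrong; the exact
interval method behind published values of this kind is generally unstated,
and the percentile bootstrap is the documented choice here.

## Gray-level discretization

Intensities inside the ROI are binned with a fixed width of 0.1 °C anchored at
the ROI minimum: bin(x) = floor((x − min)/w) + 1. On original images the
stored units make this exact (bin = stored − stored_min + 1) and manifestly
shift-invariant; on wavelet sub-bands the same width is applied to the
sub-band values. The floor quotient is nudged by 1e−9 before truncation
because 0.1 is not exactly representable in binary floating point — without
the nudge a value a few ulp below a bin boundary lands one bin low.

## Feature inventory

The feature vector is fixed at 851 names:
14 shape + 93 intensity/texture on the original image + 93 on each of 8
wavelet sub-bands. The 93 decompose as 18 first-order, 24 GLCM, 16 GLRLM,
16 GLSZM, 14 GLDM, 5 NGTDM. Only this inventory is consistent with
851 = 107 + 8 × 93; the individual definitions follow the standardized
image-biomarker conventions. Names are `<image>_<class>_<feature>` with image
`original` or `wavelet-XXX`.

Class conventions that were genuinely open and are fixed here:

- **First-order.** Variance/Skewness/Kurtosis are population moments
  (Kurtosis is the raw fourth standardized moment, 3 for a Gaussian);
  percentiles use linear interpolation; Entropy and Uniformity use the
  discretized histogram (log base 2); TotalEnergy equals Energy because the
  pixel area is the unit of measure (thermograms carry no spatial
  calibration). A relative tolerance of 1e−12 on the second moment treats
  rounding dust on constant ROIs as zero variance.
- **Shape (2-D).** Mesh surface is the shoelace area of the marching-squares
  0.5-level contour; the perimeter uses the Crofton formula (4 directions),
  which is unbiased on smooth outlines where the staircase length of the
  raster contour is not; Sphericity = 2√(πA)/P with those two estimates.
  Axis lengths are 4√λ from the eigenvalues of the foreground pixel-coordinate
  covariance (population); Elongation = √(λ₂/λ₁), Eccentricity = √(1−λ₂/λ₁).
  Maximum diameter is the largest pairwise distance between foreground pixel
  centers (via their convex hull). The dimensioned features are in pixel
  units; only the ratio features are comparable across images, which is why
  they are the ones used for morphometric claims.
- **GLCM.** Distance 1, the four in-plane directions (0°, 45°, 90°, 135°);
  each direction's count matrix is symmetrized (P + Pᵀ), normalized
  separately, features computed per direction and then averaged. Directions
  with no valid pixel pair are skipped; if none has a pair the degenerate
  single-entry matrix (all mass at gray level 1) is used so every feature
  stays defined. Correlation on a zero-variance matrix is defined as 1, MCC
  as 1, Imc1 as 0.
- **GLRLM.** Runs along the same four directions, features averaged.
- **GLSZM.** Zones are 8-connected components of constant gray level;
  direction-free.
- **GLDM.** α = 0 (exact-level dependence), distance 1, 8-connectivity.
  The matrix column index is the *dependence size* j = (number of dependent
  neighbors) + 1, counting the center pixel; this keeps the j⁻² emphasis
  features defined for isolated pixels and matches the tooling convention the
  851-feature inventory comes from.
- **NGTDM.** sᵢ sums |i − mean of in-mask 8-neighbors| over valid pixels
  (those with at least one in-mask neighbor); pixels without valid neighbors
  are excluded from the level probabilities. Strength and Coarseness
  denominators carry ε = 1e−16 so constant ROIs yield 0 (Strength) and a
  capped large value (Coarseness 1e6).
- **Wavelet bank.** One-level undecimated transform, Coiflet-1 kernel,
  applied along a singleton depth axis, then rows, then columns, each by
  discrete convolution with half-sample symmetric extension; sub-bands keep
  the input shape. On the singleton depth axis the symmetric extension
  replicates the slice, so the depth low-pass multiplies by √2 and the depth
  high-pass (zero-sum) annihilates it: the four `wavelet-HXX` bands are
  identically zero images. They stay in the inventory — treating the 2-D
  thermogram as a one-slice volume is the only convention that yields the
  fixed 851 total — and their features are the well-defined constants of a
  zero image. Shape features are never recomputed on filtered images.

## Expression screening

For each feature, pre and post values paired by teat: a two-sided paired
Student's t-test, and Cohen's d = (mean_post − mean_pre)/s_pooled with the
classical pooled SD over the two condition groups. The paired variant
(d_z) and an unpaired t-test exist behind flags; pooled d is the default
because the cited effect-size convention defines d that way. A feature is
expressed when P < 0.01 **and** |d| > 1.2; the |·| reflects that the
threshold is direction-free. The reported percent difference is
|mean_post − mean_pre|/|mean_pre| × 100. No multiple-testing correction is
applied by default (the screening design uses raw P < 0.01); a
Benjamini–Hochberg option exists. Features with zero difference variance get
a degenerate flag, an undefined p, and are never expressed. Inter-observer
comparison applies the same paired machinery across two observers' feature
tables over the same ROIs; identical tables are reported as perfect agreement
(|d| = 0, degenerate p).

## Local feature maps

Maps are sliding-window (stride 1) statistics over the in-ROI pixels of a
window centered on each pixel; with an even window w the offsets span
[−w/2, w/2 − 1]. Available statistics: mean; population skewness (defined as
0 on zero-variance windows, NaN behind a flag); gradient magnitude
√(gx² + gy²) from central differences of the °C image, window-averaged by
default (the raw per-pixel variant is exposed); and Shannon entropy of the
0.1 °C histogram within the window. Pixels whose window holds fewer than
`min_pixels` (default 4) ROI pixels are undefined (NaN). Sliding rather than
tiled windows is the documented reading of "computed over 10 × 10 pixels": it
is the convention that produces smooth maps. Window skewness moments are
computed after centering on the ROI mean — skewness is shift-invariant and
the centering avoids catastrophic cancellation of running sums near 30 °C.
Delta maps are post − pre on the intersection of defined regions; disjoint
regions give an all-NaN map, not an error, because pre/post ROIs legitimately
differ (the teat elongates after milking).

## Phantom generator

The phantom emulates the acquisition geometry: a 640 × 480 frame, a cool
background (20 °C with a 2 °C smooth vertical drift), and teat footprints that
are rotated superellipses (|u/a|^p + |v/b|^p ≤ 1, p = 2.5 — an elongated
ellipse with rounded apex; defaults a = 60 px, b = 22 px). Teat temperature
falls quadratically from a 33 °C base by 1.5 °C toward the apex and 2 °C
toward the rim, reproducing the qualitative apex gradient of real pre-milking
teats. Pixel noise is Gaussian with σ = 0.3 °C by default; optional impulse
("salt and pepper") noise replaces a stated fraction of pixels with T_min or
T_max. The field is clipped to the colorbar range, quantized to 0.1 °C, and
rendered through a built-in 351-entry iron-style ramp (black → red → orange →
white, monotone and injective per construction) — one color per 0.1 °C step,
so with zero noise the render → convert round trip is exact. No attempt is
made to reproduce a vendor palette or photorealistic udders.

Milking effects transform the phantom description: Δmean shifts the teat base
temperature;
the apex-gradient factor scales the axial drop (this is also what moves the
histogram skewness, so no separate skew dial exists); the elongation factor
scales the major axis (1.31 emulates the observed +31 % axis length); an area
factor scales both axes. Cohorts draw independent teats with ±10 % relative
geometry jitter and 0.5 °C SD base-temperature jitter from spawned sub-seeds
of a single seed; the reference cohort size is 36 teats (18 cows).

What the phantom does *not* model: vascular texture within the teat, motion
blur, JPEG compression artifacts, emissivity variation, background clutter
(udder, legs, milking cluster), or correlated noise. Passing tests therefore
demonstrate the correctness of the computational pipeline under known ground
truth — not that any particular biomarker is biologically expressed in real
cows; the study's biological counts require the original animal images.

## Problem sizes in the validation suite

Texture-matrix oracle equivalence runs on 100 random images up to 10 × 10
with up to 5 gray levels against brute-force enumeration; first-order and
feature-map values are checked against naive recomputation on a noisy phantom
ROI of ~1,400 pixels to 1e−9. The screening power and type-I simulations run
100 cohorts of 36 single-teat phantoms each in 96 × 128 frames with
first-order extraction — the frame and feature-class reduction keeps 200
simulated cohorts (14,400 phantom pipelines) cheap while exercising the full
render → convert → extract → screen path; power for the +2 °C design is
required to reach 99 % and each feature's null expression rate to stay within
0.01 + 2·SE. The acceptance script extracts the full 851-feature vector from
a full-resolution 640 × 480 phantom.

## Known limitations

- The feature engine is 2-D throughout; true multi-slice volumes are out of
  scope (the depth axis exists only to fix the wavelet sub-band inventory).
- Mesh surface sums absolute contour areas, so a mask with interior holes
  would have its hole areas added rather than subtracted; teat masks are
  simply connected in practice.
- The Crofton perimeter is exact in expectation for smooth shapes but
  approximates polygonal ones; Sphericity of a perfect raster disk computes
  to ~0.999, of a square to ~0.94.
- `interobserver_compare` requires identically ordered ROI indexes rather
  than attempting fuzzy matching; misalignment is an error by design.
- GLCM MCC uses a dense eigendecomposition, O(Ng³); with 0.1 °C bins and
  wavelet sub-bands Ng can reach a few hundred, which is the dominant cost of
  a full extraction (~0.4 s per ROI at 120 × 160, a few seconds at
  640 × 480).
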