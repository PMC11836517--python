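# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations of the anisotex pipeline.

## True stress–strain conversion and parameter extraction

The specimen is treated as volume-conserving during uniaxial extension
(Poisson's ratio ν = 0.5), so the instantaneous cross-section is
A(t) = (h₀/h(t))·A₀ with h(t) = h₀ + displacement, and strain is the
Hencky (logarithmic) strain ε = ln(h/h₀). `poisson_assumed` generalizes
the area update to A = (h₀/h)^(2ν)·A₀ for users who want to probe the
sensitivity of the extracted parameters to the incompressibility
assumption; 0.5 remains the default because comparative studies of
shear-structured products use it throughout.

Defaults follow the measurement protocol the pipeline targets: gauge
length 8.5 mm, crosshead speed 11.4 mm/min, three replicates per
direction.

Extraction decisions:

* **Fracture point** — global stress maximum, first index on ties.
* **Failure point** — first post-peak sample with σ ≤ 0.02·σ_fracture.
  Measured force never reaches exactly zero, hence the small relative
  threshold (configurable). A record truncated before crossing returns
  the last strain with a warning.
* **Young's modulus** — the curve's "linear part" is located
  deterministically: among all contiguous windows within the first 40%
  of the pre-fracture strain whose length is at least 10% of the
  pre-fracture points (and ≥ 10 points), the window with maximal
  least-squares R² wins; ties go to the earliest start, then the
  longest window, so an exactly linear initial segment is fitted over
  its full length rather than a later pseudo-linear stretch or the
  global secant. R² computed from prefix sums is clipped at 1 because
  floating-point cancellation can push it marginally above 1 for short
  windows. Consequence: the elastic segment must span at least 10% of
  the pre-fracture record to be resolvable — for the bilinear synthetic
  curves this means E·ε_f/σ_f ≤ 6 with the default 60% linear fraction.
* **Toughness** — trapezoidal ∫σ dε from zero to the failure strain,
  with stress clipped at zero from below (negative force readings are
  sensor noise) and the curve interpolated at the failure strain.
* **Fracture length** — ε_failure − ε_fracture. The difference
  convention is used because short values should read as "abrupt"
  fracture; a ratio variant is available via `mode="ratio"`.
* **Anisotropy index** — AIx = parallel/perpendicular. The ratio
  convention makes 1 isotropic and larger values more anisotropic;
  `mode="abslog"` gives the symmetric |ln ratio| for users who need
  AIx(a,b) = AIx(b,a).

## Dynamic Poisson's ratio and the Moran heterogeneity profile

ν(t) is the ratio of consecutive-frame increments of the spatial-mean
transverse and axial strains, reported as a positive magnitude so 0.5
reads as incompressible. Frames with an axial increment below 1e-5 are
invalidated (scatter-outlier exclusion: near-zero denominators amplify
noise), and the surviving trace passes through a 3-frame median filter
with nearest-edge padding (window 1 disables it). The decrease is the
first valid value minus the last valid value. Spatial means are taken
over the whole field; a single-subset variant was considered and
rejected because the full-field mean is the lower-variance estimator on
the synthetic fields.

Global Moran's I uses a single-axis binary kernel: cells are neighbours
when they share their coordinate on the other grid axis and are offset
by 1..d cells along the adjacency axis. The default adjacency axis is
perpendicular to the tensile direction ("horizontal" rows), where
strain values are comparable because strain varies mostly along the
tensile axis; the axis is always explicit in the configuration, never
inferred from the data. The profile evaluates I at d = 1..8 (37 µm per
cell) with the *cumulative* kernel (all offsets 1..d), matching the
5×5 matrix with centre row 1 1 0 1 1; a ring kernel (exact offset d)
is available. The heterogeneity parameter is the OLS slope of I against
d. Implementation is by shifted-array products — edge cells simply have
fewer neighbours — and is tested against the literal O(N²) double sum.
Note that I is not confined to [−1, 1] for all fields: very smooth
fields can exceed 1 by a few percent; the bound holds in distribution
for noise-like fields. The Moran analysis uses the final
(pre-fracture) frame only. Fields narrower than 2·d_max+1 along the
adjacency axis reduce d_max with a warning; constant fields raise.

## Void morphometry

Air components are labelled with 26-connectivity (6-connectivity
available). Boundary-touching bubbles are kept and flagged, so callers
can exclude them. Per-bubble features are deterministic, documented
definitions rather than re-implementations of any commercial package:

* extents are peak-to-peak projections of voxel centers onto the
  covariance eigenvectors plus one voxel, sorted into
  length ≥ breadth ≥ width;
* thickness is the minimum projection extent over 162 Fibonacci-lattice
  probe directions;
* surface area is the marching-cubes isosurface mesh area of the padded
  mask;
* orientation angles come from the eigenvectors, folded to θ ∈ [0°, 90°]
  from the volume z-axis and φ ∈ [0°, 180°) azimuth, because principal
  axes are unsigned;
* air anisotropy = length/width.

A single-voxel component degenerates to all extents equal to one voxel
with a warning. A two-threshold intensity classifier
(air < t₁ ≤ rest < t₂ ≤ solid) is provided for raw reconstructions;
thresholds are user-supplied. "Rest" is the segmented phase that is
neither protein matrix nor air; it only enters the volume percentages.

## Micrograph morphometry

Auto-contrast is a linear rescale clipping 0.35% of pixels at each
tail. The minimum threshold smooths the 256-bin histogram with a 3-bin
moving mean (reflected edges) until exactly two local maxima remain and
returns the bin of the valley between them; edge bins count as maxima
candidates so saturated bimodal images still threshold. Dark
(below-threshold) 8-connected components are the non-protein domains —
protein stains bright; a polarity flag inverts this. The size filter
keeps domains whose maximum caliper exceeds 40 µm (the cut is a length,
hence Feret rather than area; an equivalent-diameter variant is
configurable). Calipers run on the convex hull of pixel *corners*, so a
40×20 px rectangle measures exactly 40 and 20. Border-touching shapes
are kept by default.

Image-level orientation comes from the energy-weighted (summed)
structure tensor with Gaussian-derivative gradients (SD 1 px); the
dominant direction is the texture orientation — perpendicular to the
principal gradient eigenvector — in degrees from the column axis,
mod 180, and coherency is (λ₁−λ₂)/(λ₁+λ₂). A per-pixel-coherency
averaging mode exists but the summed tensor is the default because it
yields a single deterministic number for "coherency to the dominant
direction". A perfectly isotropic tensor returns coherency 0 with an
arbitrary direction; a zero-gradient image raises. These defaults are
documented as this package's definitions and are not claimed to
reproduce any specific GUI tool's numbers.

## Integration statistics

Correlations are computed on product-level replicate means (a
replicate-level table can be passed directly if needed). Pearson
correlations are pairwise-complete with a 3-pair minimum because the
modalities have different replicate counts; p-values are reported for
information only, with no multiple-testing correction, since the
correlation matrix is exploratory. Normalization is min-max per column
(constant columns → 0 with a warning; NAs preserved); parameter
variance uses the sample (n−1) denominator and is compared against
0.10 for the combined table and 0.15 per product set (the per-set
tables have fewer products and higher spread). Univariate selection
ranks features by the regression F-statistic — computed via
least-squares per feature on the pairwise-complete rows, equal to
r²(n−2)/(1−r²) — and keeps the top 3, ties broken by column order.
Normalization is applied only before variance and selection, not before
correlation (Pearson r is scale-invariant).

## Synthetic generators: what they emulate and what they do not

Each generator emits ground truth beside the raw data; recovery tests
compare against construction-time truth only.

* **Tensile curves** rise bilinearly — exactly linear with slope E up
  to 60% of the peak stress, then linearly to the peak — and decay
  linearly to zero over the softening span; curves are built in true
  stress–strain space and inverted through the incompressible-area
  relations, so all ground-truth parameters are exact. Noise is
  multiplicative on force. Validity requires E·ε_f ≥ σ_f (secant
  modulus cannot exceed the initial modulus). Real curves have smooth
  toe-in and serrated fracture; the synthetic kinks are deliberate so
  recovery is testable at machine precision.
* **Strain-field series** ramp the mean axial strain linearly to 0.2
  over the frames; heterogeneity is a smooth (Gaussian-filtered,
  wrap-padded) zero-mean profile along each axis with exactly the
  requested final-frame SD. The transverse field applies ν
  incrementally (transverse increment = −ν_t × axial increment), so
  the frame-to-frame estimator recovers ν_t exactly; with constant ν
  this reduces to transverse = −ν·axial and ν = 0.5 satisfies
  incompressibility identically. Real DIC fields contain speckle
  dropout, correlation noise and localized necking that these smooth
  fields do not emulate.
* **Void phantoms** place identical ellipsoids (long semi-axis =
  aspect × radius) with near-parallel long axes. Overlap is prevented
  by an ellipsoidal exclusion region (the Minkowski sum of two aligned
  ellipsoids — exact at zero jitter), with the transverse exclusion
  semi-axis padded by a·sin(2·jitter) to absorb angular jitter; each
  bubble is then one connected component. Bubble count derives from the
  target air fraction when not given. Real products have polydisperse,
  irregular voids.
* **Micrographs** are sinusoidal stripe textures (wavelength 8 px, a
  single closed-form orientation, so the coherency limit of 1 is
  analytic) or isotropic noise, plus dark elliptical domains with
  recorded Feret/width truth and optional additive noise.
* **The study table** draws a standard-normal latent factor per product
  and sets each parameter to loading × latent + Gaussian noise, so the
  implied Pearson r between two parameters is the product of their
  standardized loadings — a closed form the recovery tests use. The
  end-to-end simulated study maps one latent anisotropy factor (driven
  by each set's process variable) onto every modality's generator
  parameters; the planted-effect magnitudes are this package's choices
  of a realistic spread, not estimates of any particular dataset.

Passing recovery tests on these generators demonstrates that the
measurement chain is correct and unbiased under its own assumptions; it
does not certify accuracy on real instrument data with segmentation
errors, drift, or phase-classification ambiguity.

## Problem sizes

The shipped analysis and test configurations use desk-scale inputs
chosen as the smallest sizes at which every statistic is
well-conditioned: 72³–96³ voxel volumes with ~5–20 bubbles, 256²–512²
micrographs, 48×40 strain grids with 15–20 frames, 400–500-point
tensile records, and 11-product studies. All thresholds, kernels and
estimators are size-independent.

## Known limitations

* The 3D extent definitions (principal-axis projections + 1 voxel) are
  this package's documented stand-ins for proprietary morphometry
  definitions; each is independently configurable, and digitization
  biases extents of small bubbles upward by about one voxel per axis
  (a ~3% anisotropy underestimate for an aspect-3 ellipsoid of 4-voxel
  radius).
* The Moran kernel family is single-axis only; 2D kernels are out of
  scope.
* The linear-region fit requires the elastic segment to cover ≥ 10% of
  the pre-fracture record (see above); very strain-hardening curves
  need a custom `strain_fraction`/`min_window_fraction`.
* The image pipeline is single-channel; no registration, stack
  alignment or spectral unmixing.
* The fibre score is consumed as an externally supplied column; its
  computation is out of scope.
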