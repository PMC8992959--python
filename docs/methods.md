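# Methods

This document records the model assumptions, parameter choices, the scope of
the synthetic scan generator, numerical choices, and known limitations.

## Coordinate conventions

Analysis runs in a right-handed in-plane frame with the origin at the image
centre: +x along columns, +y "up" (towards row 0), so clock angles measured
clockwise from 12 o'clock map to the unit vector `(sin a, cos a)`. Slice
positions increase along the scanner axis; `mm_to_px` / `px_to_mm` in
`scan_io` convert between millimetres and (row, column) pixel indices using
pixel centres.

## Phantom layout

`geometry.default_layout()` encodes the analysed subset of the CatPhan 504:

- Phantom radius 100 mm; housing rendered as a graded boundary.
- **CTP404** (z extent ±12.5 mm about its centre): eight sensitometry inserts
  of radius 6.1 mm on a 58.4 mm ring every 45°, starting with air at
  12 o'clock and including a second (unlabelled) air insert at 6 o'clock;
  four linearity rods of radius 2.5 mm at (±25, ±25) mm — label 1 Teflon,
  labels 2–4 air; two wire ramps (radius 0.5 mm, half-length 25 mm, 1000 HU)
  at x = ±15 mm inclined 23° to the axial plane.
- **CTP528**: a sub-pixel point source on the axis.
- **CTP486**: homogeneous; analysed within a 75 mm module radius.

Nominal insert HU values are bundled in `material_table()`. Every layout
constant can be overridden from a YAML/JSON file (`load_layout`) so other
phantom revisions can be analysed without code changes; unknown fields are
rejected.

## Metric definitions

- **CT numbers**: mean HU in a circular ROI concentric with each insert and
  1 mm smaller in radius, to exclude the blurred rim.
- **Spatial linearity**: Euclidean distances between intensity-weighted rod
  centroids — four sides and both diagonals of the 50 mm square.
- **Uniformity**: a central ROI plus four peripheral ROIs at 3/6/9/12
  o'clock; all five have radius 0.2 × module radius and the peripheral ROI
  edges sit 10 mm inside the module margin. The index is
  `U_i = (ROI_i − ROI_c)/(ROI_c + 100) · 100 %`; the +100 offset stabilises
  the denominator for water-like centres. A centre mean near −100 HU makes
  the index ill-defined and raises an error.
- **CNR**: `(mean_bkg − mean_insert)/sqrt((σ²_bkg + σ²_insert)/2)` with the
  background ROI at the same ring radius as the insert, rotated half the
  angular gap between inserts (22.5°) so it samples pure background. The
  signed value and its magnitude are both reported.
- **PSF/MTF**: rows and columns of a 5 × 5 mm ROI about the point source are
  summed to two 1-D projections; each is fitted with a Gaussian
  (amplitude, centre, sigma, offset). The radial PSF is the average of the
  two recentred fits and the MTF is its zero-order Hankel transform
  `MTF(f) = ∫ 2πr · PSF(r) · J₀(2πfr) dr`, normalised at f = 0. HWHM and
  HWTM are the first downward crossings of 0.5 and 0.1, located by linear
  interpolation.
- **NPS**: difference of the central uniformity slice and a partner slice
  4 slice-thicknesses away (cancels deterministic structure; the factor ½
  restores single-image scaling):
  `NPS(fx,fy) = (1/N_ROI) (ΔxΔy/(NxNy)) Σ |DFT{ROI − mean}|² · ½`
  over ~200 overlapping 5 × 5 cm ROIs whose centres lie within 4 cm of the
  phantom centre. The scalar noise value is the square root of the polar
  integral of the radial NPS.
- **Slice thickness**: the wire ramp maps the longitudinal sensitivity
  profile into the plane; thickness = mean FWHM over 3 central slices
  × tan 23°, averaged over both ramps.
- **Dose**: `CTDIw = DLP_c/(3C) + 2·DLP_p/(3C)` with C the nominal beam
  width; `CBDIw = (DLP_c + 2·DLP_p)/300 mm` for wide cone beams that cover
  the whole 300 mm chamber.

## Tolerances

`auto_baseline` measures a commissioning scan and stores each metric with a
symmetric tolerance band: ±50 HU (CT numbers), ±1 mm (rod distances),
±0.5 mm (slice thickness), ±10 percentage points (uniformity), ±20 % of
baseline (HWHM, HWTM, CNR, both noise metrics). `run_qar` evaluates with
inclusive bounds; NaN metrics (e.g. an HWTM beyond the sampled range) are
reported as "not computed" and counted as failures.

## Synthetic scan generator — scope

`simulate.render_scan` is a geometric forward model, not a CT reconstruction
simulator. It renders the phantom as piecewise-constant HU with:

- area-weighted supersampling (factor 4) at disc edges and z-slab overlap
  fractions at module boundaries, so partial volume is modelled exactly for
  the geometry;
- the ramps as 3-D supersampled wire cylinders;
- an isotropic Gaussian PSF applied per slice (`scipy.ndimage.gaussian_filter`);
- the point source added after the blur as a pixel-averaged (erf-integrated)
  Gaussian of the same sigma, peak 1000 HU — the analytically correct image
  of a delta source under the model blur (when the configured blur is zero,
  the source is rendered at half-pixel width, the narrowest width
  representable on the grid);
- white (optionally frequency-shaped, variance-normalised) Gaussian noise
  added last.

It does **not** model beam hardening, scatter, reconstruction-filter noise
correlation (other than the optional isotropic shaping), helical artefacts,
ring artefacts, or detector afterglow. Its purpose is ground-truth-exact
validation of the analysis chain, not realism.

The generator is deterministic: `rng_seed` fixes the noise stream, and
identical configurations render bit-identical volumes.

## Numerical choices

- **Pixel aperture**: sampling a Gaussian blob on a pixel grid adds h²/12 to
  the fitted variance (h = pixel size). Recovered PSF sigmas are therefore
  compared against `sqrt(σ² + h²/12)`, e.g. 0.617 mm for σ = 0.6 mm at
  0.5 mm pixels.
- **Hankel transform**: for the fitted Gaussian PSF the transform has the
  closed form `exp(−2π²σ²f²)`, used as the fast path; a trapezoidal
  quadrature over r ∈ [0, 8σ] with 1024 samples is retained as an
  independent cross-check (pointwise agreement < 1e−4).
- **Radial NPS binning**: samples are binned at the DFT's native frequency
  resolution out to the *corner* frequency, and each bin carries its exact
  frequency-plane measure (sample count / (NxNyΔxΔy)). The scalar integral
  `Σ NPS_k · w_k` is then Parseval-exact: truncating the polar integral at
  the axis Nyquist with the textbook `2πf Δf` weights would capture only
  π/4 of a white spectrum's energy (≈ 0.886 of the noise SD).
- **Detection**: the phantom margin is thresholded at −300 HU (largest
  connected component, filled); module slices are anchored at the first
  detected phantom slice and confirmed by content checks (rod count,
  homogeneity, source peak). Rod and source positions are intensity-weighted
  centroids. Module identification is accurate to about one slice; the slice
  thickness measurement re-centres its 3-slice window on the candidate whose
  weakest slice has the strongest ramp signal.
- **DICOM round trip**: HU are stored as int16 with rescale intercept −1024,
  so a write/read round trip is exact to the 1 HU quantisation.

## Limitations

- The generator's simplifications mean absolute agreement with a physical
  scanner is out of scope; only the analysis chain is validated end to end.
- The PSF model is a single isotropic Gaussian; strongly anisotropic or
  non-Gaussian kernels would bias the fitted MTF (the oversampled-edge
  method in `fourier_metrics` is retained as a model-free cross-check).
- The slice-thickness method follows the ramp geometry and loses accuracy
  when the slice thickness approaches the ramp's longitudinal extent; at
  3 mm slices the systematic error is a few percent (2.85–2.89 mm measured
  for a 3.0 mm truth), well within the ±0.5 mm tolerance.
- The uniformity index is undefined for centre means near −100 HU; this is
  reported as an error rather than silently clipped.
- CTDIw assumes the 100 mm pencil chamber fully covers the beam; CBDIw
  assumes a 300 mm chamber fully covered by the cone beam. Intermediate
  geometries need partial-coverage corrections that are not implemented.
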