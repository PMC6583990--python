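# Methods

## The cell coordinate system

`rodcoords` describes each rod-shaped bacterial cell by a curvilinear
coordinate system built on a quadratic midline

    p(x) = a0 + a1·x + a2·x²,   x ∈ [xl, xr]

with a sixth parameter, the cell radius `r`. All six parameters are in
pixel units; images follow the y-down convention with the centre of the
top-left pixel at (0.5, 0.5), so pixel (row i, col j) has centre
(j + 0.5, i + 0.5).

A Cartesian point (x_p, y_p) maps to cellular coordinates (l_c, r_c, φ):

1. The abscissa x_c of the closest midline point minimises
   (x_c − x_p)² + (p(x_c) − y_p)². Its stationarity condition is the cubic
   2a2²·x³ + 3a1a2·x² + (1 + a1² + 2a2(a0 − y_p))·x + (a1(a0 − y_p) − x_p) = 0,
   solved in closed form (Cardano, complex arithmetic). The cubic can have
   three real roots for strongly curved midlines, so the squared distance is
   evaluated at every real stationary point and the arg-min taken; x_c is
   then clamped to [xl, xr] so that points beyond the endpoints (the
   hemispherical pole caps) project onto the domain boundary.
2. l_c is the arc length of p from xl to x_c, computed from the closed form
   (u√(1+u²) + asinh(u))/(4a2) with u = a1 + 2a2x.
3. r_c is the Euclidean distance from the point to (x_c, p(x_c)).
4. φ (degrees) is 0 on the top side of the body (y_p < p(x_p), i.e. smaller
   image row), 180 on the bottom, and on the pole caps the angle between the
   top-oriented normal at the endpoint and the segment to the point. It
   runs continuously 0 → 180 clockwise around the right pole and 180 → 0
   around the left pole, which makes φ continuous across the body/pole seam
   by construction (the behaviour at the seam is a convention; nothing in
   the data model depends on it beyond continuity). On the midline (r_c = 0)
   the angle is undefined and fixed to 0 to keep the transform total.

The inverse transform (used for multi-cell alignment and for synthesising
data) inverts the monotone arc-length function by a safeguarded Newton
iteration (tolerance 1e-12 px) and places the point at distance r_c along
the direction selected by φ. The round trip is the identity to better than
1e-6 px wherever r_c > 0.

### Numerical choices

* **Degenerate curvature.** For |a2| < 1e-10 px⁻¹ the cubic's leading
  coefficient 2a2² underflows meaningfully, so the exact linear-midline
  solution is used. The two branches agree to < 1e-6 px at the threshold.
* **Arc-length cancellation.** The closed form differences two
  antiderivative values that agree to O(a2·Δx); for |a2·Δx| < 1e-5 a
  midpoint-slope chord Δx·√(1 + p′(x_mid)²) is used instead (second-order
  accurate, absolute error ≤ |Δx|³a2²/6, i.e. < 2e-9 px in that regime).
* **Cubic root selection.** Evaluating the objective at the real parts of
  all three Cardano roots is safe even when two roots are complex: the real
  minimiser is always among the candidates and spurious candidates can only
  lose the arg-min.

## Coordinate-system optimization

Initial parameters come from the segmentation mask of a horizontally
oriented cell: a least-squares quadratic through the per-column foreground
centre of mass, `r` as half the median per-column foreground height, and
midline endpoints at the foreground column extrema pulled inward by `r`
(poles are caps beyond the midline domain).

Three χ² objectives refine the six parameters against a chosen data
element:

* **binary** — the model mask (r_c ≤ r) is compared pixel-wise with the
  measured mask; χ² is the number of disagreeing pixels. All 6 parameters
  are free (the mask constrains the radius directly, so `r` is fitted
  jointly rather than held at its guess).
* **image** — an isotropic model image is bootstrapped from the measurement
  itself: pixel intensities are binned by r_c (histogram binning, default
  bin width 0.5 px; empty bins take the nearest occupied bin's value), each
  pixel is assigned the profile value at its r_c by linear interpolation,
  and χ² is the summed squared difference. Pixels with r_c > r + 5 px are
  excluded so a large background does not dominate either the profile or
  χ². The five geometry parameters are fitted; `r` is then set from the
  half-maximum point of the radial profile: the first crossing of
  (peak + baseline)/2 outward of the global profile peak, with the baseline
  estimated from the outermost 20 % of bins. This works for both
  membrane-peaked (brightfield) and interior-filled (cytosolic
  fluorescence) profiles; for monotone profiles the peak is at r_c = 0.
* **localizations** — χ² = Σ_i (r_c,i − r)² over all localizations of a
  membrane-marker SMLM table. All 6 parameters are free; the optimal `r`
  converges to the mean radial distance of the scatter.

Minimisation uses a derivative-free Nelder–Mead simplex (scipy), with the
initial simplex scaled to natural parameter steps (1 px for a0/xl/xr, 0.01
for a1, 1e-4 px⁻¹ for a2, 0.5 px for r), relative function tolerance 1e-6,
and an absolute parameter tolerance of 1e-4. Parameter vectors violating
xl < xr or r > 0 score +∞. No bounds are imposed by default; optional
per-parameter bounds are accepted. The driver never returns a point worse
than the start: if the minimiser ends above the starting value the starting
parameters are kept and the result flagged unconverged. Unweighted squared
differences are used throughout (no per-pixel variance model).

## Analysis outputs

* **Axial distributions** bin pixel intensities (mean ± std per bin) or
  localization counts by r_c, l_c or φ.
* **Ensemble radial distributions** are computed per cell on the normalised
  abscissa r_c/r (the fitted radius maps to 1), y-normalised to each cell's
  maximum, then averaged across cells with the std reported per bin.
* **Alignment** maps every weighted pixel centre or localization of each
  cell to cellular coordinates, rescales l_c by the model/cell length ratio
  and r_c by the radius ratio (uniformly, including pole regions), maps the
  result into the model frame and renders the point cloud as a sum of 2-D
  Gaussians (default σ = 0.5 model px, truncated at 4σ, each patch
  normalised to the point's weight so mass is conserved up to frame
  clipping).
* **Perimeter periodicity** projects membrane localizations onto the closed
  isodistance outline at distance r. The outline position is zero at
  (l_c = 0, φ = 0, r_c = r) and increases clockwise: top segment
  (s = l_c), right pole (s = L + φ/180·πr), bottom segment, left pole;
  total 2L + 2πr. For curved midlines the in-segment metric is the midline
  arc length; the offset-curve correction (~a2·r per unit length) is
  neglected, which is a deliberate simplification — at the default
  curvature scale it is below half a trace bin. Counts are binned at 10 nm
  (well below the tens-of-nm structures of interest), autocorrelated with
  unbiased lag normalisation over lags up to half the perimeter, detrended
  by subtracting a centred moving average (window 150 nm — wide enough to
  pass the low-frequency envelope, narrow enough to keep ~50 nm
  oscillations; configurable), and Fourier-transformed with 4× zero padding;
  the wavelength of the largest non-DC amplitude is reported.

## The synthetic benchmark

The generator produces ground-truth cells and "measured" data so the whole
pipeline can be scored without real microscopy data.

* **Geometry.** r ~ N(5, 0.5) px, midline length ~ N(25, 5) px truncated
  above 10 px, curvature a2 ~ N(0, 0.004) px⁻¹, all truncated to
  configurable bounds; pixel size 80 nm/px. These defaults give visually
  E. coli-like cells at the stated magnification; the true distributions of
  any particular strain/imaging setup should be configured by the user.
* **Binary.** Exact thresholding of the radial distance map at r.
* **Brightfield.** Relative intensity 1 + 0.5·exp(−(r_c − c)²/(2·1.5²))
  with the ring centre c = r − 1.5·√(2 ln 2). The centre is calibrated so
  that the half-maximum point of the radial profile, moving outward of the
  peak, falls exactly at the geometric radius r: the radius measured from
  the brightfield by the half-maximum criterion then agrees with the radius
  defining the binary, as it must for the normalisation conventions
  (brightfield radius ≡ 1, membrane positions placed relative to it) to be
  self-consistent. The image is scaled by the photon count (500, 1000 or
  10000), Poisson shot noise is drawn per pixel, and Gaussian read noise
  with σ = 20 photons is added.
* **Membrane localizations.** Positions uniform along the closed outline at
  the element's mean radius, radial scatter Gaussian with σ = 0.25 px
  (20 nm at 80 nm/px); 200 localizations per element by default. The inner
  membrane element sits at 0.9·r and a second, outer element 100 nm further
  out.
* **Fields.** 10 ± 3 cells per 512 × 512 px (40 µm × 40 µm) field,
  randomly rotated and placed with ≥ 5 px between any two cells' binaries
  (verified against a distance transform), localization tables combined
  into one full-frame table, brightfield composed from the noiseless
  models before the noise draw.
* **Degraded binaries.** Segmentation is out of scope, so the measured
  masks in the benchmark are the truth binaries with morphological boundary
  noise: each outer-band background pixel is flipped with probability equal
  to the severity, each inner-band foreground pixel with half that
  probability (severity 0.5 / 0.35 / 0.2 at 500 / 1000 / 10000 photons).
  The outer/inner asymmetry reproduces the mild over-segmentation bias of
  low-contrast segmentation — masks get noisier *and* slightly fatter as
  the signal drops, which is what ties binary-method accuracy to photon
  count in the benchmark.
* **Matching and scoring.** Measured cells are matched to truth by greedy
  nearest-centroid pairing with a 5 px gate (the generator controls truth
  identity, so no cluster analysis is needed); localizations not belonging
  to the matched truth cell are removed by truth membership, and cells
  recovering less than half their truth localizations are flagged. The
  relative χ² of a fit is the localization objective at the fitted
  parameters divided by its value at the ground truth (with the truth
  radius set to the localization element's true mean radius), so 1 means a
  perfect fit; the optimizer can score slightly below 1 on a finite sample.
  Radial-coordinate errors are reported normalised to the true
  inner-membrane radius, as the mean absolute deviation D, the RMS
  deviation D², and the per-cell median absolute relative deviation.

### What the generator does and does not emulate

The generator reproduces the geometry, the noise statistics of a
shot-noise-limited camera, membrane-localised SMLM scatter and
segmentation-quality degradation. It does not simulate fluorophore
photophysics, a PSF, frame-by-frame blinking movies, drift, or real
segmentation networks; cells are perfect quadratic rods, so benchmark
accuracies are upper bounds for real cells whose midlines deviate from a
second-degree polynomial.

### Problem sizes

The benchmark tables in the test-suite and the acceptance script use 100
cells per condition (50 for the three-method ordering comparison), 200
localizations per membrane element, and full-resolution single-cell frames;
field-composition checks use 256 px fields. These sizes put the Monte-Carlo
error of the reported medians well inside the acceptance bands while
keeping a full run in minutes on one core.

## Known limitations

* The 180° ambiguity of the second-moment orientation estimate is not
  resolved; extraction is deterministic but cells may be flipped
  end-to-end. An optional flip flag is exposed instead of guessing.
* Perimeter positions on curved cells use the midline metric (see above).
* The image objective's histogram-binned profile trades accuracy for
  speed; the residual binning bias is visible as fitted radii a few
  hundredths of a pixel off at 10000 photons.
* No global optimisation: a sufficiently bad initial guess can end in a
  local minimum (visible as rare high-χ² outliers in the benchmark, as
  expected for simplex refinement).
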