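# Methods

This note documents the models, conventions, parameters and design
decisions behind `kneealign`, in the spirit of a statistical software
methods appendix.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Coordinate and sign conventions

* Pixel convention: origin at the top-left corner, x rightward, y downward,
  integer pixel centres.  A horizontal flip therefore maps
  `x -> (width - 1) - x`, which is exact for integer-sized rasters and an
  involution.
* Landmark indices are 0-based.
* All measurement code assumes (but does not require) left-knee
  orientation; right knees are normalised by flipping, and the batch
  manifest records the flag.  Because the lateral side is re-detected from
  the fibula for every set, the *signed* aFTA is flip-invariant either way.
* Axis orientation `theta` is the angle of the proximal-to-distal axis
  vector from image-down, computed with the two-argument arctangent (no
  small-angle approximation), then multiplied by the lateral sign so that
  "positive" always means "tilted toward the lateral side".  With both
  orientations lateralized, `aFTA = theta_tib - theta_fem`; on the raw
  angles this equals `lateral_sign x (theta_tib_raw - theta_fem_raw)`.
  Proximal/distal endpoint assignment is by smaller/larger y, which assumes
  roughly upright knees (standard AP positioning); a radiograph rotated
  beyond ±90 degrees would be rejected by the orientation range check
  rather than silently mis-signed.
* Axes are straight lines *connecting* two resolved endpoints, not
  least-squares fits over shaft point sets.  Each endpoint is a single
  landmark or the midpoint of a symmetric landmark pair.

## 2. Schemas and measurement definitions

Four schemas (110/134 pre-operative, 157/181 post-operative points; the
extended variants append 24 shaft points) carry a role table naming the
axis-relevant landmarks: femoral shaft proximal/distal pairs, femoral notch
pair, tibial shaft proximal/distal pairs, tibial spine groove (pre) or
tibial plateau centre pair (post), and the fibula block.  The eight
measurement recipes are registered in
`kneealign.measurement.builtin_definitions`; their endpoint indices are
fixed by the published definitions and tested against frozen values.

Classification bands: varus below 0; [0, 5) is left unnamed clinically and
labelled `neutral_low` here purely for completeness; usual alignment
[5, 7]; valgus deformity above 7.  The acceptable post-operative band is
[2.4, 7.2] degrees of valgus.  All stated interval endpoints are inclusive
("between x and y" is read inclusively); inclusivity is documented here and
boundary behaviour is pinned by tests.

## 3. Agreement statistics

* **ICC**: the default form is ICC(2,1) — two-way random effects, absolute
  agreement, single measurement — computed from the two-way ANOVA mean
  squares, because method-comparison studies ask whether two methods agree
  in absolute value, not merely rank order.  `icc1` and `icc3`
  (consistency) are exposed behind the `form` parameter.  Confidence
  intervals use the standard F-based constructions (Satterthwaite degrees
  of freedom for the absolute-agreement form).  When the error mean square
  is numerically zero (error-free ratings) the interval degenerates onto
  the point estimate.  If the two-way table has no variance at all the ICC
  is undefined and a `ValueError` is raised.  Interpretation bands:
  poor < 0.5 <= moderate < 0.75 <= good < 0.9 <= excellent.  (Note that
  published prose sometimes calls 0.78 "moderate"; under these thresholds
  0.78 is "good".  The implementation follows the thresholds.)
* **MAD**: mean of |a_i - b_i|; the paired SD column is the sample SD of
  the same absolute differences, since that is the quantity whose mean is
  reported.
* **Bland-Altman**: bias is the mean signed difference, by default method A
  (automatic) minus method B (manual/clinical) — the direction is a
  convention, so it is a parameter; the 95% limits of agreement are
  bias ± 1.96 x SD with the sample (n-1) SD.  The per-pair means are
  returned for plotting.
* All SDs in the package use the n-1 denominator.  Human-readable reports
  round half-up to one decimal (`decimal.Decimal`, not banker's rounding),
  matching the one-decimal style of clinical agreement tables; machine
  outputs keep full precision.

## 4. Synthetic data generator

The generator stands in for clinical radiographs, which cannot be shipped.

* **Templates** are procedural: shaft edges, condyle/plateau arcs sampled
  by arc length from parametric polylines, implant outlines for the
  post-operative schemas, a fibula ellipse placed lateral.  Every
  axis-defining pair is symmetric about the vertical midline, so both axes
  are exactly vertical and every applicable definition reads exactly zero
  on the template — giving an exact algebraic ground truth.  Geometry is
  invented; only the role topology and point counts are contractual.
* **Alignment injection** rotates the femoral subset rigidly about the
  knee centre by `lateral_sign x angle`.  A rigid rotation rotates every
  line within the femur by exactly that angle, so all eight definitions
  recover the injected value exactly on clean landmarks; this is the
  oracle behind the angle-recovery tests.
* **Degradations**, applied in order: (i) shaft truncation — the scalable
  shaft landmarks are moved along the current axis direction toward the
  knee-side anchor so the visible shaft length scales by the configured
  fraction (landmarks are moved, never deleted, keeping files
  schema-valid); (ii) global in-plane rotation about the landmark
  centroid; (iii) iid Gaussian jitter per coordinate emulating annotation
  error.  Out-of-plane (projective) rotation and heavier-tailed noise are
  known omissions.
* **Rendering** fills the bone/implant outline polygons (implants
  brighter), then Gaussian blur and additive Gaussian noise.  This gives
  the detector a realistic *task structure* (edges, corners, repeated
  anatomy) but not radiographic texture, soft tissue or exposure
  variation — an important caveat on what detector benchmarks on synthetic
  renders can show.
* **Paired simulation** draws true angles t_i ~ Normal(mean, sd) and two
  noisy measurements a_i = t_i + e_a, b_i = t_i + bias + e_b.  Defaults
  (true mean 2, SD 5 degrees; method error SD 1 degree) emulate a mixed
  pre-operative arthroplasty population, where alignment spans roughly
  -15 to +15 degrees, measured by methods of about one-degree precision;
  the annotation-jitter default of 1 px is likewise a plausibility choice,
  as no quantitative annotation-error model is published.
* Every stochastic operation is deterministic given its seed
  (`numpy.random.default_rng`).

## 5. Landmark detector

`RegressionVotingDetector` is a compact, single-stage regression-voting
constrained local model.  The reference systems in this family are
multi-resolution and heavily engineered; this implementation keeps the two
defining ingredients and drops the rest, and makes no claim of equivalence
with any existing system.

* **Shape model**: generalised Procrustes alignment (similarity transforms,
  convergence when the mean moves < 1e-8) followed by PCA; the smallest
  number of modes reaching the configured variance fraction (default 0.95)
  is retained; mode coefficients are clamped to |b_i| <= c sqrt(lambda_i)
  with c = 3.
* **Per-landmark forests**: random-forest regressors (default 10 trees,
  depth <= 12) mapping a mean/variance-normalised square intensity patch
  (half-width 6 px) to the 2D displacement from patch centre to the true
  landmark; training patches are sampled at uniform offsets within ±d_max
  (default 12 px) of the truth.
* **Search**: per landmark, the forest is evaluated over a grid around the
  current estimate (half-width 8 px, spacing 1 px); each grid sample votes
  for its displacement-corrected position; votes farther than d_max are
  discarded; the candidate is the mean of votes in the fullest 1-px
  accumulator bin (votes are rounded to 1e-6 px before binning so bin
  membership — and hence the whole prediction — is stable under float
  dust from model reload or BLAS differences).  A similarity +
  constrained-shape fit to the candidates closes each of the 3 iterations;
  the first iteration searches 2.5x wider on a 2-px grid to absorb a rough
  initialisation.  Points are searched sequentially; no parallelism is
  promised.
* **Initialisation**: the mean shape placed into a caller-supplied bounding
  box (the synthetic harness uses the truth box jittered by ±10 px); a
  global object finder is out of scope.
* Displacements are learned and voted in image pixels, with the shape-pose
  scale only modulating sampling/search ranges.  This assumes roughly
  standardised image scale across a dataset — true of the synthetic
  renders — and is the main simplification versus reference-frame
  resampling implementations.
* All randomness (offset sampling, forest bootstrap) flows from
  `random_state`; models serialise to a single joblib archive with a
  format-version field.

## 6. Problem sizes and numerical tolerances

* Angle identities (scale/co-rotation/flip invariance, injection recovery)
  are asserted at 1e-6 degrees; pure-rounding identities at 1e-9 or
  tighter; statistics against brute-force oracles at 1e-10.
* The end-to-end benchmark trains on 40 renders and evaluates 50 held-out
  renders of the 134-point extended pre-operative schema at 320 px, using
  the notch-based extended recipe — the configuration with the longest
  axis baselines, where per-point detection error (~1 px) propagates to
  only a few tenths of a degree.  These sizes keep the whole experiment in
  the minutes range on a single CPU while leaving a wide margin to the
  excellent-agreement threshold it is checked against.
* Monte-Carlo properties (noise-linearity of the angle error, truncation
  variance inflation, ICC monotonicity) use 500-1000 draws and fixed
  seeds; the linearity ratio tolerance is 25%.

## 7. Known limitations

* Procedural geometry means detector results quantify machinery, not
  clinical accuracy; no bone texture, soft tissue, exposure variation,
  fractures or implant-orientation variation are modelled.
* Only in-plane rotation is simulated; projective (out-of-plane leg
  rotation) effects on aFTA are not reproducible here.
* The mechanical femorotibial angle (long-leg radiographs), DICOM
  ingestion, pixel-spacing calibration (aFTA is scale-invariant) and any
  annotation GUI are out of scope.
* The pts reader supports one dialect (`version:`/`n_points:` header and a
  braced coordinate block); alternative dialects would need a new reader
  hook.
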