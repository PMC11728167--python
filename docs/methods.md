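# Methods

## Problem and estimator

The broken rate of a maize kernel sample is a mass ratio,
Z_s = m_s / M_i × 100 (%), with m_s the mass of broken kernels and M_i the
total kernel mass. Neither mass is observed by a camera; the pipeline
estimates both from 2-D silhouettes: every segmented kernel is classified
broken/unbroken from its shape, assigned a predicted mass by the weight
regressor of its predicted class, and the per-kernel masses are pooled.
Misclassified kernels are weighed by the routed (wrong-class) regressor
with no post-hoc correction — the estimate degrades exactly the way a
deployed system would. The identity Z_s = m_s/M_i × 100 is enforced
bit-exactly on every result object.

## Shape descriptors

Seven descriptors per kernel: area S (foreground pixel count), perimeter C,
long axis L_ab, short axis L_cd, aspect ratio R_a = L_ab/L_cd, circularity
e = S/S₂ and rectangularity R_r = S/S₁ (S₂, S₁: areas of the minimum
circumscribed circle and minimum rotated circumscribed rectangle).

Numerical choices:

- The boundary is traced by marching squares at the 0.5 level and smoothed
  with a 5-point circular moving average. The raw staircase contour
  overestimates arc length by ~6–7 % and object extent by up to half a
  pixel per side; after smoothing, disc perimeters land within ~0.5 % and
  all descriptors of rasterized ellipses (a ≥ 15 px) within their raster
  tolerance. The smoothing window is short enough that true corners
  (rectangles) lose under 2 % of perimeter.
- Perimeter is the arc length of that polygon, not a pixel-edge count,
  so it converges to the true contour length with resolution.
- L_ab is the farthest point pair, computed exactly on convex-hull vertices
  (the hull diameter equals the set diameter). L_cd is the extent of the
  silhouette along the line through the area centroid perpendicular to the
  a–b segment, measured between the outermost boundary crossings: for
  concave (broken) kernels the gap is spanned, not summed, matching the
  single-chord definition of a short axis.
- The minimum enclosing circle and minimum-area rotated rectangle are
  delegated to shapely's exact algorithms; the test suite cross-checks them
  against an O(n³) pair/triple circle oracle and an exhaustive hull-edge
  orientation sweep to 1e-6 on random point sets.
- e and R_r are capped at 1.0 (raster quantization can push a ratio a hair
  over); all descriptors must be finite and positive.
- Ratios are computed from unscaled pixel geometry (scale-free); S, C,
  L_ab, L_cd are reported in mm via an optional mm/px factor (default 0.1
  mm/px across the package).

## Segmentation

Global gray-level threshold (Otsu by default, fixed value optionally) after
optional |image − background| subtraction, then 4-connected component
labelling with a 50 px² minimum area to drop noise specks. 4-connectivity
prevents diagonal bridging between adjacent kernels; touching kernels are
not split (no watershed) because the tray presentation keeps them separated.
RGB input is converted by standard luminance weighting. On a constant image
Otsu has no threshold and the call fails loudly rather than guessing.

## Synthetic data generator

The generator stands in for an undistributed image set of a high-moisture
dent maize variety (tray scenes of ~36 kernels, 2592×2048 px); it defines
the study conditions for every test and reported number.

- **Unbroken kernels**: superellipse silhouettes with semi-axis ratio
  (elongation) U(1.15, 1.7), superellipse exponent U(2.3, 3.2) (2 = ellipse,
  larger = blockier, as dent kernels are), low-frequency radial roughness
  (lobes k = 2..5, relative amplitude U(0.01, 0.04)), base radius
  U(42, 58) px (4.2–5.8 mm at 0.1 mm/px). The radial profile is normalized
  so the enclosed area is exactly π·base_radius² — a spec with elongation 1,
  roughness 0 and exponent 2 rasterizes to a disc.
- **Broken kernels**: the same blobs minus a cut removing a damage fraction
  U(0.2, 0.6) of the area — a wedge from the centroid (probability 0.6) or
  a half-plane cut with a ragged, crack-like edge (0.4). The cut threshold
  is placed at the exact pixel quantile, so the removed fraction is exact up
  to raster quantization of the cut line; a cut that disconnects the mask
  is retried with a new direction (10 attempts). Tissue loss and the ragged
  edge shift circularity, rectangularity and perimeter, which is what makes
  the classes distinguishable: on 300 default-parameter kernels the joint
  (e, R_r) histograms of the two classes overlap by ~10 % (< 20 % required
  for the task to be learnable).
- **Mass**: W = α·S_intact^1.5 · (1 − damage) · exp(ε), ε ~ N(0, 0.05),
  with S_intact in mm² and α tuned so the mean unbroken kernel weighs
  ≈ 0.35 g. The 1.5 exponent is area–volume allometry and makes projected
  area the dominant single-feature weight predictor; damage removes mass
  linearly in removed area (a broken-off slab of roughly constant
  thickness), while the lognormal ε stands in for thickness and density
  variation the silhouette cannot see.
- **Scenes**: kernels are placed by rejection sampling with a ≥ 12 px
  pairwise gap (enforced through gap-dilated occupancy), on a background of
  gray 40 with kernel level 200 and additive Gaussian noise of SD 5,
  clipped to [0, 255] — segmentable by construction
  (level difference > 4×noise SD).
- **Datasets**: 180 broken / 120 unbroken kernels split 75/25 into
  calibration/prediction, stratified by class; the per-class rounding is
  searched over ±1 so split class proportions stay within 5 points of the
  overall mix even for small n.
- **Mixtures**: bench-test scenes are packed greedily to a target broken
  rate: broken kernels are drawn until m_s falls in a ±0.25 pp band, then
  unbroken kernels fill the total to ~10 g inside the window that keeps the
  achieved rate within ±0.5 pp of target. The returned ground truth carries
  the exact packed masses.

Every generator output is a pure function of (spec, seed): each sampled
kernel spec carries its own sub-seed, so a kernel's mask is identical
whether it is drawn during mass packing or re-rendered during scene
composition. All stochastic steps in a run descend from one master seed
(default 2018).

What the generator does *not* emulate: embryo/endosperm color and texture,
lighting gradients, shadows, micro-cracks without tissue loss, touching or
overlapping kernels, and 3-D thickness observed directly. Passing tests
therefore demonstrate that the pipeline machinery (geometry, screening,
fusion) recovers known ground truth under realistic shape/mass statistics —
not that the trained models transfer to real imagery, where class overlap
is larger (slightly damaged kernels genuinely resemble whole ones).

## Models

- Weight regression: SPR (stepwise quadratic polynomial), RF, SVR, LGBM,
  KNN; classification: RF, SVM, LGBM, KNN. Per-class weight models are
  separate (broken vs unbroken kernels are different populations; the best
  algorithm differs by class), with LGBM routed to broken and RF to
  unbroken kernels by default.
- Grid screening by exhaustive search under five-fold CV (shuffled K-fold
  for regression scored by RMSE; stratified K-fold for classification
  scored by accuracy), ties broken by grid order, winner refit on the full
  calibration split. Every grid point's CV score is kept on the fitted
  model (`cv_results`) as the training log.
- Default grids: LGBM colsample_bytree 0.1–0.6 step 0.1 ×
  n_estimators 400–1000 step 10; SVM kernel ∈ {linear, poly, rbf, sigmoid}
  × C ∈ {0.1, 1, 10} × gamma ∈ {0.01, 0.1, 1}; KNN n_neighbors 1–6 ×
  weights {distance, uniform} × p 1–6; RF n_estimators 400–500 step 5 ×
  max_features 1–6 × a coarse max_depth ladder {1..10, 20, 40, 91} — depth
  saturates well below 91 on ~100-row calibration sets, so the ladder
  covers the informative region at a fraction of the cost of every integer
  depth; any axis can be overridden via config. Shipped no-search defaults
  for the regressors: LGBM colsample_bytree 0.1 / n_estimators 410 (broken)
  and RF n_estimators 435 / max_features 5 / max_depth 6 /
  min_samples_split 2 (unbroken).
- The n_estimators axes are scored by staged prediction: one fit at the
  largest tree count per fold, prefixes scored at every grid value. For
  both random forests (per-tree seeds are drawn sequentially) and gradient
  boosting (earlier trees are unaffected by later ones), the first k trees
  are identical to a k-tree model at the same seed, so the grid is
  evaluated exactly, ~20–60× cheaper. The tests verify staged scores equal
  direct fits.
- SVM and KNN see z-scored features (training-split statistics); tree
  models and SPR use raw features. The SVR *target* is also z-scored: the
  default ε = 0.1 insensitivity tube would swallow most of the gram-scale
  weight variation (SD ≈ 0.05–0.1 g) otherwise. ε itself is left at the
  library default and recorded with the model.
- SPR expands the 7 features to 35 quadratic terms (linear + squares +
  pairwise), z-scores the columns for conditioning, and selects terms
  forward-backward by strict AIC improvement with a fixed scan order —
  deterministic, and parsimonious under a pure-noise target. Aliased
  (rank-deficient) candidates are skipped.
- The Gaussian RBF kernel is implemented with the squared norm,
  exp(−‖x−x′‖²/2σ²), gamma = 1/(2σ²).
- Reproducibility: single-threaded fits, fixed seeds everywhere; the same
  dataset + seed reproduce chosen hyperparameters and predictions
  bit-for-bit.
- Feature importance for classifiers is permutation importance on the
  held-out split (mean accuracy drop over 20 shuffles, fixed seed), sorted
  descending with name tie-breaks. Ground-truth weight is never a
  classifier input; importance over a table that includes weight is
  available only as a user-supplied diagnostic.

## Evaluation metrics

r is the determination form 1 − Σ(y−ŷ)²/Σ(y−ȳ)² — the field-customary "r"
for these models — and equals the squared Pearson correlation whenever
predictions come from an OLS fit with intercept (property-tested); a true
Pearson r is reported alongside. SD is the population standard deviation
of the predictions (Taylor-diagram radius). RMSE uses an N−1 denominator
(an N variant sits behind a flag). Classification reports carry the 2×2
confusion matrix (rows actual, columns predicted), accuracy, per-class
recall, and the broken-kernel misjudgment rate defined as 1 − precision of
the broken class — the only definition consistent with reporting a high
broken recall and a nonzero misjudgment simultaneously. Taylor summaries
tabulate (model, r, SD, RMSE) and can be drawn as a polar plot (angle
arccos of Pearson r, radius SD, observation point at the actual-series SD).

## Bench validation

For each target level (default 1–15 % in steps of 2) × 3 repetitions, a
mixture scene is packed, imaged, segmented, featurized and estimated; the
table of (true, predicted) rates is fit by OLS. With oracle models
(ground-truth classes and weights) the fit is slope 1, intercept 0, R² = 1
exactly, isolating pipeline plumbing from model error. With the default
trained pipeline on the default generator, R² ≈ 0.97–0.99 at seed 2018;
the residuals are dominated by occasional classifier errors on mildly
damaged kernels, each of which moves a ~10 g scene by up to ±3 pp.

## Problem sizes and runtime

Defaults were chosen to keep a full from-scratch reproduction under ~10
minutes on one CPU: 300-kernel dataset, full LGBM/SVM/KNN grids, the coarse
RF depth ladder (~2,000 and ~1,600 evaluated grid points for the LGBM and
RF screens after staged evaluation), and 24 validation scenes at the full
2048×2592 frame.

## Known limitations

- Silhouette-only masses: two kernels with equal projected area get equal
  expected weight; real thickness variation appears only through the noise
  term.
- No watershed: touching kernels would merge into one component (the
  generator never produces them; real trays might).
- The classifier is trained on cleanly separated synthetic classes; real
  micro-cracked kernels without area loss are invisible to these seven
  descriptors.
- The SVR sigmoid kernel is retained for grid fidelity but is rarely
  competitive; grid search screens it out.
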