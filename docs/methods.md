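# Methods

This note documents the models implemented in `geodefol`, their
assumptions, the tunable parameters and defaults, what the synthetic
data does and does not emulate, and the numerical choices made where the
design was genuinely open.

## Segmentation

Image objects are grown from single pixels by pairwise region merging.
For adjacent regions *a*, *b* the merge cost is

    Δh = w_shape · Δh_shape + (1 − w_shape) · Δh_color
    Δh_color = Σ_b w_b · [ n_m σ_b(a∪b) − n_a σ_b(a) − n_b σ_b(b) ]
    Δh_shape = w_cmpct · Δ(n · perim/√n) + (1 − w_cmpct) · Δ(n · perim/bbox_perim)

with population standard deviations, and a merge is admissible when
`Δh < scale²`. Scheduling is deterministic: row-major passes over the
live regions with **mutual best fit** acceptance (a region merges with
its cheapest neighbour only if the preference is reciprocal), ties going
to the smaller label; passes repeat until no admissible merge remains.
Labels are finally renumbered 1..n by first-pixel order, 4-connectivity
throughout, nodata pixels excluded.

Defaults mirror a spectrally driven configuration: `shape_weight = 0`,
`compactness_weight = 1`, band weights 2.0 for Red/NIR/SWIR1/SWIR2 and
1.0 for Blue/Green. With `shape_weight = 0` the result is provably
independent of the compactness weight (tested). **The scale parameter
has no defensible default** — it is a required config value; on the
synthetic scenes (reflectance contrasts of ~0.01–0.1) useful scales lie
roughly in 0.3–3, and object counts are empirically non-increasing in
scale (tested on a five-point ladder).

## Object features (95 columns)

Per object: mean and sd of the six bands (12); mean and sd of eleven
index layers — NDVI, NDWI (Gao, NIR–SWIR1; the water-content variant
appropriate for canopy stress), GEMI, IPVI, ARVI, EVI2, GVI,
tasseled-cap brightness/greenness/wetness, max. band difference (22);
means of PC1–PC6 (6); eight GLCM statistics × six bands (48); area,
compactness `perim/(4√n)`, asymmetry `1 − λ₂/λ₁` of the pixel-coordinate
covariance ellipse (3); TWI/TPI/TRI means (3); majority forest type (1).
Published per-group counts for this feature family are internally
inconsistent; this accounting is the one that reaches exactly 95 with
every listed feature present. The panchromatic band participates in
segmentation if supplied but not in texture (bivariate pan texture is
out of scope).

Numerical choices:

* Zero denominators in indices yield NaN ("flagged missing"), never ±inf;
  aggregation is NaN-aware.
* Tasseled-cap coefficients are the published Landsat-8 reflectance set
  (Baig et al. 2014); GVI uses the Landsat-TM greenness coefficients
  (Crist & Cicone 1984). Pinned in `features/spectral.py`.
* PCA: eigendecomposition of the 6-band pixel covariance; each
  component's sign is flipped so its largest-magnitude loading is
  positive; scores are min-max rescaled to [0,1] per component (the
  scale on which partial-dependence thresholds such as "PC2 > 0.70" are
  interpretable); components beyond the covariance rank are NaN.
* GLCM: 32 gray levels by per-band min-max quantization; offsets
  {(0,1),(1,0),(1,1),(1,−1)} at distance 1, symmetric counting, pairs
  fully inside the object; entropy uses the natural log with 0·ln 0 = 0;
  correlation is defined 0 for zero variance; objects with fewer than
  two co-occurrence counts are flagged NaN.
* Terrain: D8 flow accumulation (steepest distance-weighted descent,
  cells processed high-to-low), Horn slope with tan β floored at 1e−6,
  `TWI = ln(a/tan β)` with `a` = contributing cells × cell area; TPI
  subtracts the in-bounds mean of a 9×9 window; TRI is the mean absolute
  difference to the 8 neighbours. Default cell size 30 m.
* Majority forest type breaks ties toward the smallest category code.

## Boosted classification

Binary logistic gradient boosting: `f₀ = log(p̂/(1−p̂))`; per stage a
least-squares regression tree (best-first growth, ≤ `max_leaves`
terminal nodes) is fitted to `y − p` on a `subsample` fraction drawn
without replacement, leaf values by one Newton step `Σ(y−p)/Σ p(1−p)`,
then `f ← f + ν · tree`. Defaults: 500 trees, 6 leaves, ν = 0.01,
subsample 0.5 — the reference protocol, with the stochastic half-sample
as the TreeNet-style randomization. Split search is exact with
deterministic tie-breaks (first feature in column order, smallest
threshold); categorical features (forest type) use the CART device
(order categories by mean pseudo-residual, then split as ordered);
missing values route to the child with more training weight. A stage
whose subsample is single-class is skipped with a logged warning.

**Ensemble size.** Test ROC area and misclassification are recorded
every stage. On a finite test set the ROC area is quantized in steps of
`1/(n⁺·n⁻)`, so an early stage can reach the maximum by a single lucky
pair ordering while being poorly calibrated at the 0 log-odds threshold.
Stages within one concordant-pair quantum of the maximum are therefore
treated as ROC ties, resolved by test misclassification rate, then by
fewer trees. Prediction, variable importance (split-gain, rescaled to
top = 100) and partial dependence (mean score over training rows with
one feature forced across its observed range, mean-centered) all use
this optimal prefix. Features at ≥15% relative importance are kept and
the model refitted on them.

## Hazard indices

Monthly anomalies are per-object, per-calendar-month z-scores against a
baseline of at least 10 years; a zero-spread month is NaN unless the
deviation itself is zero. SPI applies a rolling sum (default 12 months),
then per calendar month a gamma fit by Thom's approximation with zero
totals as a mixed point mass, and maps the CDF through the standard
normal quantile, clipped to ±3.09. Yearly dimensions count months beyond
the anomaly threshold (default |z| > 1, the conventional "below normal"
cut): severity = Σ|z| over exceedances, frequency = count, duration =
longest run. Two year bases: hydrological (Oct–Sep, labelled by the
September year — climate hazards) and growing season (Apr–Sep of one
calendar year — defoliation). Dimensions are standardized by fuzzy
linear (default anchors at the observed min/max) or fuzzy large
memberships and overlaid with the fuzzy-gamma operator; default
γ = 0.9 (a high-γ compromise near the algebraic sum, the convention in
fuzzy hazard overlay work); all indices live in [0,1]. Fire severity
uses frequency / total burned area / total burn days per object-season
through the same membership + overlay machinery; records without a
known object are logged and skipped; object-seasons without fires score
exactly 0.

## Panel econometrics

Balanced panels only. Pooled OLS; fixed effects by within demeaning
(covariance with df = NT − N − k, object intercepts recovered as
`ȳᵢ − β̂′x̄ᵢ`); random effects by Swamy–Arora: σ̂²_ε from within residuals,
σ̂²_α = max(0, σ̂²_between − σ̂²_ε/T), θ = 1 − √(σ̂²_ε/(σ̂²_ε + T σ̂²_α)),
quasi-demeaned OLS including the (1−θ) intercept column, slope
covariance σ̂²_ε (X*′X*)⁻¹. R² conventions: overall for pooled, within
for FE, overall of the quasi-demeaned regression for RE (flagged in the
output because conventions differ across software). The Chow statistic
is reported both as F and in the (N−1)·F χ² form with df = N−1, the
reporting convention of some packages; a perfect fit of both models
yields statistic 0 / p 1, a perfect FE fit alone +inf / p 0. The Hausman
statistic uses `(V_FE − V_RE)⁻¹` with a pseudo-inverse fallback
(flagged) and clips negative values at 0 with a warning — the standard
treatment of this finite-sample artifact. The χ² upper tail is computed
in-package via the regularized incomplete gamma (power series below
a + 1, Lentz continued fraction above; ~1e−8 absolute accuracy,
verified against an independent implementation in the tests).

## Synthetic data

The scene generator emulates: six Landsat-like reflectance bands in
[0,1]; spatially correlated backgrounds; irregular infested patches
(disc unions with blurred, noise-wobbled boundaries so segmentation
faces non-trivial edges) carrying the stress signature — green/red up,
NIR/SWIR down — and amplified high-frequency texture; a three-class
forest-type map; correlated DEMs whose relief scales with a roughness
parameter. It does **not** emulate atmospheric effects, clouds, sensor
geometry, seasonal phenology or real Landsat radiometry, so passing
classification tests demonstrate the pipeline's correctness and the
protocol's behaviour on separable data, not expected accuracy on real
imagery.

The climate generator draws per-calendar-month gamma precipitation (so
SPI's distributional assumption holds), seasonal Tmax with trend and
AR(1) shocks, and soil moisture as an exponential memory of
precipitation minus warm-anomaly demand, each with object-level offsets.
Yearly regressors are pooled-CDF transforms of hydrological-year
aggregates (unit-interval hazard-intensity-like scores with both within-
and between-object variation); previous-year fire severity is exogenous
Beta noise. The response is `y = α₀ + β′x + αᵢ + ε` with object effects
independent of every regressor (verified: |corr| < 0.1 at N = 500), so
the random-effects assumptions hold by construction and estimator
recovery is a meaningful test. Default β echoes the magnitude pattern of
the reference random-effects estimates (heat strongest, previous-year
moisture mildly negative); σ_α = 0.08, σ_ε = 0.10; default N = 19
objects over panel years 2010–2017 (T = 8 with one year consumed by
lags), matching the cross-section count implied by a Chow df of 18.
Fire records are Poisson per object-season with lognormal burned areas
and small positive integer durations.

Problem sizes used by the test-suite and acceptance computations —
128×128 scenes, ~150–250 objects, 200 replicate panels at N = 100,
T = 8, 100 replicates in the acceptance script — were chosen as the
smallest sizes at which the statistical checks are stable.

## Known limitations

* Segmentation is O(passes × edges) pure-Python; scenes beyond ~10⁵
  pixels are slow. No hierarchical multi-level segmentation.
* Unbalanced panels, robust/clustered covariances and dynamic-panel
  instrumentation are out of scope; lagged responses may appear as
  regressors but are not instrumented.
* Hydrological years at the series edges can be incomplete; the panel
  generator drops them, but `yearly_dimensions` scores whatever months
  are present — callers should trim edge years when completeness
  matters.
* The fuzzy anchors, γ and the anomaly threshold for real-data hazard
  maps are site-specific choices; defaults here are conventions, not
  fitted values.
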