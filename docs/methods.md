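# Methods

`spadvi` re-implements, as a tested pipeline, a nondestructive workflow for
estimating SPAD (relative chlorophyll) of tree seedlings from downward
canopy images taken under four shade levels (0%, 25%, 50%, 75% of incident
light blocked). The pipeline is: plant/background segmentation →
white-plate-corrected vegetation-index (VI) extraction → multicollinearity-
aware index screening → shade-aware regression → evaluation. Because no
field dataset ships with the package, a synthetic-scene generator defines
the study conditions; every stage is verifiable at desk scale against
known ground truth.

## The synthetic study

**Population.** Four shade levels with 50 seedlings each. Per level,
`spad_true ~ Normal(mean, sd)` truncated below at 5 SPAD, with level means
18.39, 25.76, 31.81, 29.26 (SPAD units) and a common standard deviation of
3.0 SPAD. The meter reading `spad_measured` averages three leaf readings
`spad_true + Normal(0, noise_sd)`; `noise_sd` defaults to 1.0 SPAD, a
typical repeatability figure for handheld transmittance meters. The level
means produce a strongly significant one-way ANOVA (F on the order of
100–200 at n = 200), with the non-monotone peak at 50% shade.

**Optics.** Leaf reflectance per band follows a Beer–Lambert-like decay
`rho_b(SPAD) = baseline_b · exp(-k_b · SPAD) + floor_b`, with decay rates
ordered `k_red > k_green > k_red_edge > k_nir = 0`. Only this qualitative
structure matters: it makes NDVI and NDRE increase with SPAD and the
red/green ratio decrease, the sign pattern every VI in the pipeline
exploits. Soil follows a fixed brightening-with-wavelength soil line. No
radiative-transfer realism (leaf angle distributions, PROSPECT/SAIL,
camera PSF) is attempted.

**Scenes.** Each seedling is rendered as 6–9 overlapping elliptical leaf
blobs (canopy fraction ≈ 0.1–0.3 of a 96×96 frame) over soil, with a
spatially uniform white reference panel (reflectance 1.0) in the corner.
Three noise sources, all clipped at ±2σ: per-pixel leaf-scale SPAD
heterogeneity (CV 15% — leaf-to-leaf chlorophyll variation is why meter
protocols average several leaves), a spectrally flat per-pixel brightness
field (σ = 5%; leaf angle and micro-shadow act on all bands together), and
a small independent per-band term (σ = 1%). The clipping is deliberate:
unbounded Gaussian tails create sparse histogram bins that distort
maximum-entropy thresholding in ways no real canopy histogram does.

**Cameras and exposure.** The MS camera writes 16-bit DN, the RGB camera
8-bit DN, both with floor quantization after scaling to full range, plus a
seeded sub-LSB uniform dither (`DN = ⌊radiance · maxDN + u⌋`, `u∈[0,1)`),
which keeps the per-pixel floor rule while making channel means unbiased
at any bit depth. By default both cameras auto-expose
(`exposure="auto"`): a per-scene gain holds the white panel near 90% of
full scale with an independent few-percent metering jitter per camera —
the behaviour of an aperture-priority consumer camera and of automatic-
exposure multispectral rigs, and the very reason the white-plate
correction exists (scene DN carry an unknown per-scene gain that the
panel ratio removes). `exposure="fixed"` disables the gains so DN scale
linearly with ambient illumination; the linear-light property and the
corrected-channel-mean invariance across illumination are tested in this
mode. With fixed 8-bit exposure, deep-shade scenes quantize the soil/plant
gray histogram onto a coarse lattice; the entropy-maximizing cut then
shifts by a few histogram bins between illumination levels, which changes
the segmented mask by a percent or two of pixels — enough to move
high-contrast ratio indices (RVI = NIR/Red) by far more than quantization
alone. Auto-exposure is the physically grounded mechanism that removes
this artefact.

**What the generator does not emulate.** Flat Lambertian leaves without
angle-dependent spectra; hard plant/soil boundaries without mixed pixels;
a single soil class; no specular highlights, vignetting, or mis-
registration between cameras. Consequently the rendered index–SPAD
correlations (~0.97) are far stronger than field values. Passing tests on
rendered scenes therefore demonstrates the correctness of the imaging
chain, not field-level accuracy. For model-level questions the package
provides an analytic shortcut, `simulate_feature_table`, which emits
per-seedling corrected band means with multiplicative lognormal noise
(CV 20%, representative of canopy-scale reflectance variability from
gaps, leaf angle and view geometry). This reproduces the regime real
studies report — single-index |r| ≈ 0.2–0.7 — and is the substrate for
the shade-aware-versus-blind model comparisons.

## Segmentation

RGB scenes are collapsed to one channel with excess green
(ExG = 2G − R − B on channels scaled to [0,1] by bit depth), MS scenes
with NDVI = (NIR − Red)/(NIR + Red); pixels with a zero NDVI denominator
are flagged invalid and excluded. The Kapur threshold histograms valid
pixels into 256 equal-width bins over the full [min, max] range and
returns the bin boundary maximizing the summed Shannon entropies of the
two classes (natural log; empty bins contribute zero via the x·ln x → 0
limit). Exact and floating-point ties — cuts through empty bins share the
same entropy — resolve to the smallest cut. Vegetation is the upper class
for both gray images. A known calibration region (the white panel) can be
excluded from the histogram; in the emulated study the regions of
interest are drawn around single seedlings, so the panel is never scene
content. No morphological cleanup is applied. All-plant or all-background
results raise rather than return.

## Index extraction

Channel means are computed over the plant mask first, then corrected by
dividing by the white-panel mean of the same channel (panel treated as
reflectance 1.0 — no further bit-depth normalization is needed after the
ratio), and only then fed into the index formulas; per-pixel index maps
are never averaged. Ten RGB indices (ExG, ExGR, NGRDI, NGBDI, RGRI, GBRI,
CIVE, VEG, RGBVI, MGRVI) and ten MS indices (NDVI, RVI, DVI, EVI, RDVI,
REVI, NDRE, RERVI, REDVI, sCCCI) are evaluated exactly as the source
convention prints them — including `RGBVI = (G²−B·R²)/(G²+B·R²)` and
`RDVI = (NDVI/DVI)^0.5`, which differ from the common literature forms;
`literature_formulas=True` switches to the standard variants. Zero
denominators and negative radicands flag an index invalid (NaN + flag)
instead of raising; records with a missing retained index are dropped
from modeling with a logged count. Note the exact identity
RERVI = REVI + 1: the screening stage must cope with perfectly collinear
candidates by design.

## Screening

Per index: Pearson r against SPAD with the two-sided t-based p-value
(n − 2 df), and VIF_j = 1/(1 − R²_j) from regressing index j on all
others with intercept (bands: <10 none, 10–20 some, >20 serious
multicollinearity; auxiliary R² ≥ 1 − 1e-6 reports the cap 1e6).
p-values are uncorrected by default, with an optional Holm step-down.
Indices with p ≥ α (default 0.05) are dropped, then the Lasso

    argmin ‖y − Xβ‖² + λ‖β‖₁

is solved on standardized columns (mean 0, variance 1; y centered) by
cyclic coordinate descent with soft-thresholding. The penalty enters once
(not scaled by n). Numerics: covariance (Gram) updates, a numba-compiled
kernel, coefficient tolerance 1e-8, at most 1e5 sweeps, and a secondary
first-order (KKT) stopping rule — on near-collinear designs the
coefficients drift along a flat objective valley long after the fit has
converged, and first-order optimality is the meaningful criterion there.
λ is chosen as the minimizer of 10-fold cross-validated MSE (not the
one-standard-error rule) over 100 log-spaced values from λ_max =
max_j |2x_jᵀy| down to 1e-4·λ_max, with warm starts down the path. The
retained set is the support at λ* (|β| > 1e-8; an empty support falls
back to the smallest grid penalty with a warning); exactly collinear
duplicates inside the support — where the L1 solution is non-unique —
are collapsed onto their first member so the subsequent OLS refit, which
reports the multiple correlation R, is well-posed.

## Models

Four estimator families relate the retained indices (x) and optionally
shade to SPAD:

- **OLR** — least squares with intercept; the shade-aware variant codes
  the four levels one-hot *without* a global intercept, so each dummy
  coefficient a_i is directly the level intercept in
  `SPAD = b·x + Σ a_i z_i + ε`.
- **LMM** — random intercepts by shade level,
  `SPAD = b·x + u_g + ε`, `u_g ~ N(0, σ²_r)`, fitted by REML: the
  variance ratio θ = σ²_r/σ²_e is profiled out (block-diagonal Woodbury
  identities for V⁻¹) and maximized by a bounded 1-D search (tolerance
  1e-8, θ ∈ [0, 1e4] with an explicit boundary check at θ = 0).
  Predictions for known levels add the BLUP
  `û_g = θn_g/(1+θn_g) · mean(residual_g)`. A single group degenerates to
  OLS with a warning. Random slopes exist behind a flag but are off by
  default — four groups cannot support a rich random-slope structure.
  (The implementation is in-repo; statsmodels' MixedLM serves as an
  independent oracle in the tests, agreeing to ~1e-3.)
- **RF** — scikit-learn regression forest: 500 trees, ceil(p/3) features
  per split, unlimited depth, minimum leaf 2, seeded.
- **SVR** — scikit-learn RBF ε-SVR behind a standardizing pipeline, with
  (C, γ, ε) selected by seeded 10-fold CV minimizing MSE over
  C ∈ 2^{−3..10}, γ ∈ 2^{−10..3}, ε ∈ {0.01, 0.1, 0.5, 1}. A documented
  coarse grid (C ∈ 2^{−1,1,3,5,7}, γ ∈ 2^{−7,−5,−3,−1,1}, ε ∈ {0.1, 0.5})
  is used inside multi-seed simulation loops, where the full grid's
  ~800 candidate triples per fit would dominate runtime without changing
  the qualitative comparisons. A constant response is rejected rather
  than fitted: hyperparameter selection by CV is meaningless there.

RF and SVR accept the same one-hot shade dummies as OLR.

## Evaluation

Random 3:1 modeling/test split (150/50 at the default scale),
unstratified by default with an opt-in shade-stratified variant.
Metrics: R² = 1 − SS_res/SS_tot (test-set R² uses the test-set mean and
may be negative), RMSE in SPAD units, MAPE = 100·mean(|y−ŷ|/|y|)%.
One-way ANOVA across shade uses the classic F = MS_between/MS_within.
Percent comparisons between models use 100·(value − reference)/reference
("higher") or its negation ("lower"), reported with half-up rounding to
two decimals; R²/RMSE are reported to four decimals.

## Orchestration and determinism

`run_experiment` executes features → per-source screening (on the
modeling rows) → the family × {RGB, MS} × {with, without shade} grid →
summary. Every stochastic element draws its own substream from one master
seed (SeedSequence keyed by a stream-name checksum), so identical
configurations produce identical outputs byte for byte. The CLI
(`spadvi generate/segment/extract/screen/fit/evaluate/run`) is a thin
layer over these functions; stage failures map to stage-specific exit
codes.

## Problem sizes used by the test and acceptance suites

Rendered-pipeline checks use the full 200-seedling study (a 200-scene
render plus segmentation takes ≈2 s). The shade-aware-versus-blind
comparison averages held-out R² over 20 replicate populations on the
analytic feature tables, with the coarse SVR grid. REML parameter
recovery simulates 50 replicates at n = 200 (4 groups × 50). The
acceptance script mirrors these sizes with 10 replicates for the model
comparison and 25 for REML recovery.

## Known limitations

- The renderer's flat-leaf, two-class world makes image-stage accuracy
  (Jaccard ≈ 0.95–0.99) an upper bound on anything achievable in the
  field; segmentation of real canopies with mixed pixels will be worse.
- Kapur's maximum-entropy objective systematically trades a sliver of the
  majority-class histogram tail into the minority class; with strongly
  unbalanced class areas this caps achievable mask accuracy regardless of
  noise level. The generator's canopy fractions keep this effect below
  10% of plant area.
- With only four shade levels, the REML estimate of σ²_r is noisy for any
  single dataset (few-group variance estimation); only its average over
  replicates is tested against truth.
- The CV-minimum rule for λ yields flat CV curves on mildly collinear
  designs, so the retained set can be generous; the collapse of exact
  duplicates is guaranteed, near-duplicates are not.
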