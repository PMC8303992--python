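# Methods

This note documents the models and procedures implemented in `fmisodyn`, the
parameters that matter, the numerical choices behind them, and what the
synthetic cohorts do and do not establish about clinical data.

## Data model

All stages consume co-registered 3D PET volumes in standardized-uptake-value
units (SUV, g/mL), carried as NIfTI-1 files.  SUV normalisation (decay and
body-weight correction) and rigid registration are upstream of this package:
volumes and masks are only *verified* to share a voxel grid, with a 10⁻³ mm
tolerance on spacing and origin.  Masks are inclusive voxel sets — there is
no fractional membership — and voxel volume is the product of spacings
(mm³ → mL).  Time-points are labelled W0 (baseline, before chemo-radiotherapy)
and W2/W5 (treatment weeks 2 and 5); W2 and W5 may be missing per patient, in
which case the patient contributes only to the pairs that exist.

## Hypoxic sub-volume segmentation

The hypoxic sub-volume (HSV) is the set of voxels inside the clinician-drawn
boost volume whose SUV is at least `tbr` times the mean SUV of a background
reference region (default `tbr = 1.4`).  Choices worth stating:

- **Background definition.** The background is a user-supplied ROI mask; its
  arithmetic mean SUV defines the denominator of the target-to-background
  ratio, its sample standard deviation is reported alongside.  A helper can
  propose a crude automatic ROI far from the boost volume for synthetic and
  exploratory work, but the reference procedure is an expert-drawn ROI.  The
  aggregation (mean rather than median or mean + k·SD) is the package's
  default and is deliberately isolated in `estimate_background` so it can be
  swapped without touching the thresholding rule.
- **Inclusive comparison.** The threshold uses ≥, which makes the boundary
  `SUV/BG = 1.4` testable bit-exactly.
- **No post-processing.** No hole filling and no minimum-component filtering
  by default; a `min_component_voxels` option exists (off, i.e. 0) for users
  who need to suppress single-voxel noise components.
- An **empty HSV is a valid outcome**, recorded as "no hypoxic volume at this
  time-point", not an error.

## Size and location dynamics: the classification parameter

For a pair (reference = baseline HSV, comparison = later HSV) on one grid:

```
ΔV    = 100·(V_new − V_ref)/V_ref           [%]
DICE  = 2|A∩B| / (|A|+|B|)
Sens. = |A∩B| / |A|        (A = reference)
PPV   = |A∩B| / |B|        (B = comparison)
```

Size classes: increasing hypoxia IH for ΔV ≥ 15, stable SH strictly inside
(−15, 15), decreasing DH for ΔV ≤ −15.  The printed class intervals leave
ΔV = −15 exactly unassigned; it is given to DH, closing the partition
symmetrically to the IH boundary (a measure-zero case that cannot affect
cohort results).  The classification parameter selects one overlap measure by
size class — CP = DICE (SH), Sens. (IH), PPV (DH) — so that full coverage of
the baseline contour in the branch's sense gives CP = 1 regardless of the
volume change, and disjoint contours give CP = 0.

Degenerate pairs: an empty follow-up HSV is *resolved* hypoxia and an empty
baseline is *absent*; both carry no CP.  For survival grouping, CP is
dichotomized at the cohort median (ties to the high group); a fixed threshold
is available by configuration, as is mapping resolved patients to the
CP-high group (hypoxia gone).  By default resolved/absent patients are
excluded from CP-based survival comparison but remain in every report.
Both follow-up pairs (W0→W2, W0→W5) always use W0 as the reference.

## Radiomic features

The frozen catalogue (`features_v1.yaml`, version 1) holds exactly 130
features: 10 first-order/histogram/shape features (SUV max/mean/variance/
skewness/kurtosis, fixed-bin histogram entropy and uniformity, volume,
mesh-based sphericity, inertia-based major axis length) plus 40 texture
features — 9 GLCM, 13 GLRLM, 13 GLSZM, 5 NGTDM — under three pre-processing
variants:

1. **plain** — fixed-bin-width discretization, `W = 0.01` g/mL, bins anchored
   at the in-mask minimum: `g = floor((s − min)/W) + 1`.  The anchor must be
   stated for bit-exact tests; the in-mask minimum is this package's choice.
2. **wf_** — one-level 3D discrete wavelet transform (Coiflet-1, symmetric
   boundary extension), reconstruction with the six mixed low/high sub-bands
   weighted 2 and the pure low-pass and pure high-pass sub-bands weighted 1
   (the 1:2 band-pass emphasis); since the pure low-pass band keeps weight 1,
   a constant input is returned unchanged.  The filtered volume is then
   discretized with the fixed bin width.
3. **q_** — equal-probability quantization (histogram equalisation) to 64
   gray levels (configurable), with level boundaries at empirical quantiles.

Texture conventions: GLCM and GLRLM counts are summed over the 13 unique
distance-1 directions of the 26-neighbourhood into one merged matrix (the
per-direction-average alternative is deliberately not implemented); the GLCM
is symmetrized.  GLSZM zones and NGTDM neighbourhoods use 26-connectivity;
NGTDM averages over the in-mask neighbours only and drops voxels with none.
Features that are undefined on degenerate regions — co-occurrence correlation
with a single occupied gray level, NGTDM contrast with one level — are
reported as missing (NaN), never as 0, so they cannot fabricate
delta-radiomics signal.  NGTDM coarseness on a perfectly flat region is
capped at 10⁶.

Whether the wavelet and quantization variants apply to all four texture
families was an open design point; this catalogue applies both to all four,
which together with the 10 non-texture features is exactly what the count
130 requires (10 + 3×40).

Longitudinal change per feature is the relative deviation
`Δ_RF = (RF_Wk − RF_W0)/|RF_W0|`, always computed inside the *baseline* HSV
contour transferred unchanged to the co-registered later scan (no
re-segmentation for feature extraction).  A zero or missing baseline value
makes the delta missing.

### LGZE and heterogeneity

Low gray-level zone emphasis, `LGZE = (1/N_z) Σ n(g,s)/g²`, is the
analysis-critical GLSZM feature.  Under min-anchored fixed-bin
discretization its behaviour is dominated by the in-mask intensity spread: a
homogeneous region collapses to few low levels and scores near 1, while a
heterogeneous region (many low-concentration pockets) spreads the bulk of
voxels to high gray levels and scores orders of magnitude lower.  The
package therefore treats *decreasing* LGZE as *increasing* tracer
heterogeneity, and the synthetic generator's heterogeneity parameter lowers
LGZE monotonically in expectation.  Consequently the planted
local-recurrence link uses a positive logit slope on ΔLGZE: patients whose
LGZE dropped most (strongest heterogeneity increase, consistent with
re-oxygenation) are the least likely to recur.

## Outcome statistics

- **Survival endpoints** (overall and progression-free survival, months from
  treatment start): Kaplan–Meier product-limit curves, two-group log-rank
  test, and multivariate Cox regression with Wald 95 % CIs (non-convergence,
  e.g. separation, raises rather than returning silent estimates).
  Continuous predictors (CP, Δ_RF) enter survival comparison through a
  cohort-median split, mirroring the CP grouping; the Cox path on the
  continuous value is available as the alternative.
- **Binary endpoints** (local recurrence, distant metastasis): Mann–Whitney
  U (exact for ≤ 20 observations without ties, tie-corrected normal
  approximation otherwise) for group comparison, and a single-feature
  logistic model for prediction performance.
- **Imbalance-adjusted bootstrap.** The cited resampling scheme is
  under-specified in print; it is reconstructed here as a class-stratified
  bootstrap with equal per-class resampling weight (⌈n/2⌉ draws per class,
  B = 1000, seeded), the plain bootstrap remaining available.  Each
  replicate fits the logistic model by Newton–Raphson and evaluates AUC
  (rank-based, ties at 0.5) and specificity on the out-of-bag patients; the
  specificity operating point is the threshold where sensitivity and
  specificity are closest, ties resolved toward the larger Youden index.
  Coefficients are reported as bootstrap means; complete separation is
  flagged and capped rather than diverging.  The per-replicate 2-parameter
  Newton fit is cross-checked against a reference maximum-likelihood fit in
  the test suite.
- **Multiplicity and confirmation.** Benjamini–Hochberg step-up adjustment
  is applied per endpoint × time-point across the feature family (missing
  p-values do not count toward the family size).  A feature is only called
  predictive when its adjusted significance holds at both W2 and W5 for the
  same endpoint.  Among confirmed predictors, a Spearman redundancy filter
  visits features by ascending p-value and removes any later feature with
  |r| > 0.8 to a kept one.
- A single top-level seed drives all resampling and is recorded in the run
  metadata together with a hash of the configuration.

## Synthetic cohorts

Each synthetic patient receives three volumes on a common grid (default 64³
at 2 mm isotropic; the test suite uses 32³ with 6–9 mm cores to stay fast —
these are the problem sizes behind all simulation results quoted by the
tests): Gaussian background with mean 1 g/mL and additive noise
(SD 0.05 g/mL, no point-spread blurring by default), a sub-threshold lesion
shell at 1.15×background, and a hypoxic core at 2.0×background containing
Poisson-many low-intensity pockets (SUV 1.5–1.75×background, radius 2–4 mm)
controlled by the heterogeneity parameter.  All core voxels stay above
1.4×background so the planted core and the segmented HSV agree (DICE ≥ 0.9
at default noise).

Dynamics: each patient draws a class from the mix over {static-IH,
static-SH, static-DH, dynamic, resolved}; defaults plant decreasing hypoxia
in 64 % of patients at W2 (40 % static-DH + 24 % dynamic, which also shrink)
and roughly 80 % at W5 (stable and increasing patients convert to decreasing
with probabilities 0.75 and 0.5).  ΔV is drawn inside the class band (IH:
+20…+50 %, SH: ±8 %, DH: −60…−25 %, deeper at W5) with the core radius scaled
by (1+ΔV/100)^⅓; dynamic patients are additionally translated by a fixed
10 mm drift vector.  Resolved patients lose the core entirely.

Outcomes: progression-free survival is exponential (baseline median 24
months) with a configurable hazard ratio for dynamic patients (default 3);
censoring times are independent Uniform(0, c_max) with c_max solved per
hazard class so the expected censoring fraction equals the configured rate
(default 20 %).  Overall survival adds an independent exponential tail.
For balanced-design simulations the class mix can be allocated in exact
proportions (seeded shuffle) instead of i.i.d. draws.
Local recurrence is Bernoulli with a logit linear in the patient's realized
ΔLGZE — either a fixed slope, or a slope calibrated by bisection so the
model-implied AUC on the cohort's realized deviations hits a target (0.8 in
the recovery tests) at a fixed base rate (40 %).  Distant metastasis is an
independent Bernoulli (24 %).  Everything reproduces bit-identically from
one integer seed.

**What passing tests do not show.** The generator has no PET physics
(scatter, randoms, partial-volume, reconstruction artifacts), no
inter-scanner variability, no registration error, and spherical geometry
only; effect recovery on these cohorts demonstrates the correctness and
power of the *analysis*, not expected performance on clinical images.

## Numerical choices and degenerate inputs

- Geometry tolerance 10⁻³ mm; grid mismatch is always an error, never a
  resample.
- Discretization level of the in-mask maximum follows the floor rule (no
  special-casing); equal-probability quantization with all-equal values
  collapses to a single occupied level.
- Sample standard deviation (ddof = 1) for the background; a single-voxel
  ROI reports SD 0.
- Skewness/kurtosis are flagged missing when the in-mask variance is
  numerically zero.
- The Cox fit uses Efron's tie correction (the library default).
- CP median split sends ties to the high group, making the all-equal cohort
  well-defined.

## Known limitations

- The 130-name feature catalogue is a reconstruction from the feature-family
  counts; exact name-by-name parity with any particular clinical extraction
  code is not claimed — the two analysis-critical features (LGZE, the GLCM
  correlation) are pinned by name and formula.
- Only merged (summed) direction aggregation is implemented for GLCM/GLRLM.
- No multivariable feature-combination models and no Harrell's C-index; the
  inference layer reports per-feature results only.
- DICOM ingestion, SUV computation from raw activity, and image registration
  are out of scope by design.
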