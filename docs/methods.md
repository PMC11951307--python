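# Methods

This note documents the models, algorithms and defaults behind `ctcsfat`,
and what the synthetic-data generator does and does not emulate.

## Agatston scoring

Calcium lesions are detected per axial slice inside each artery territory
mask as 8-connected components of voxels with HU ≥ 130; components smaller
than 1 mm² are discarded. A lesion scores `area_mm2 × w`, with density
weight `w` = 1/2/3/4 for peak HU 130–199/200–299/300–399/≥400, rescaled by
`slice_thickness / 3 mm` so non-3-mm acquisitions score on the standard
scale. Threshold, minimum area, connectivity and reference thickness are
configuration knobs (`AgatstonConfig`) with those defaults.

Derived features (12 in total): four per-vessel scores (LM, LAD, LCX, RCA),
their sum, `log10(score + 1)` of each and of the total, the diffusivity
index `1 − max(vessel)/total` (0 when total is 0 — all calcium in one vessel
and no calcium both count as "not diffuse"), and the high-CAC flag, true
strictly above 1000. Base-10 logarithms are the radiology convention and the
default; the natural log is a configuration away if a downstream consumer
needs it. The diffusivity maximum with four scored vessels is 0.75, attained
when all four score equally.

## Fat-omics

EAT masks are inputs; segmentation is out of scope. Three feature families:

* **Morphological.** Volume = voxel count × voxel volume. Principal axis
  lengths are `4·√λᵢ` for the eigenvalues λᵢ of the covariance of EAT voxel
  centres in mm (the ±2σ extent of a Gaussian cloud). Fat thickness is
  measured per slice by casting rays at 1° steps from the pericardial
  centroid and summing the ray's intersection length with the EAT band
  (sampling step = ¼ of the smallest in-plane spacing); the mean is over
  rays that hit fat, the max over all rays and slices. A single-voxel EAT
  degenerates to one in-plane voxel extent by convention.
* **Intensity.** Min/max/mean HU, skewness, and probabilities of 20-HU
  histogram bins over the adipose window [−190, −30] HU — the window and
  bin width are configurable; the defaults produce the bins the spatial
  features are named after.
* **Spatial.** The same bin probabilities within partitions of the EAT:
  four *slabs* of equal slice thickness over the occupied cranio-caudal
  range (slab 1 = top), and `n_ribbons` *ribbons* of equal depth width,
  where depth is the Euclidean distance transform (in mm) from the
  pericardial boundary, computed inside the pericardium. Ribbon 1 is the
  outermost. Feature names follow `SR{k}_Pro_{a}_{b}` / `SL{k}_Pro_{a}_{b}`
  with `a`,`b` the absolute HU bounds of the bin `[-a, -b)`.

Two deliberate choices need stating. First, `n_ribbons` defaults to 5:
the ribbon features discussed in this analysis family run up to SR5, and a
five-band partition makes SR4/SR5 genuinely "outer" bands. Second, ribbon
bands are equal-width over the *occupied* depth range `[d_min, d_max]` of
the EAT voxels rather than `[0, d_max]`: a boundary voxel's distance to the
nearest exterior voxel is one voxel spacing, never 0, so anchoring bands at
0 leaves the outermost band half-empty and aliases shell geometry. With the
occupied-range convention a uniform spherical shell yields monotonically
shrinking ribbon populations from outer to inner, as the r² volume element
dictates.

Empty partitions emit probability 0 with a warning — never NaN — so model
matrices stay dense. All features are invariant to rigid translation of
volume plus masks; mm-valued features scale linearly with voxel spacing.

## Remodeling labels

The plaque-site diameter is summarized by the **maximum** over the plaque
span (the conventional choice for remodeling assessment); the reference
diameter is the mean of the proximal-interval mean and the distal-interval
mean. RI exactly 1.1 is **not** PR (strict inequality). Patient-level PR is
the disjunction over the nine LAD/LCX/RCA × proximal/mid/distal segments;
the left main is scored for calcium but not for remodeling.

## Cohort simulator

The generator is a statistical emulator, not an anatomical one. Its defaults
live in `src/ctcsfat/data/table_calibration.yaml` and define the study
conditions:

* PR label ~ Bernoulli(0.324).
* 23 clinical covariates drawn per arm — normals for continuous variables
  (clipped below where negative values are meaningless), Bernoullis for
  binary ones — with the arm-wise means/SDs and proportions of the
  baseline-characteristics table the analysis targets. Covariates are drawn
  **independently**: means and SDs are the only published moments, so all
  cross-covariate correlations are 0 unless configured. (A consequence:
  derived "band" covariates such as age 60–75 are sampled from their own
  arm proportions rather than recomputed from the sampled age.)
* Per-vessel Agatston scores drawn on the `log10(score+1)` scale (truncated
  at 0) with arm-specific moments, then exponentiated; the 12 derived score
  features are computed from those draws by the same `score_panel` code used
  on images, so they are mutually consistent by construction. The printed
  raw-scale total-score moments are then *emergent*, not enforced.
* Fat-omics features with arm-shifted normal moments. No reference moments
  exist for these; the defaults give the elevated-HU outer-ribbon features
  (SR4/SR5 `Pro_90_70`) separations of roughly one pooled SD in the
  direction reported for remodeling, weaker shifts elsewhere, and are a
  one-time choice documented here.
* MACE times ~ exponential with baseline hazard 0.03 events/person-year
  (a plausible screening-cohort MACE rate of a few percent per year) and the
  PR arm's hazard multiplied by exp(log 6.5); censoring uniform over a
  5-year follow-up window. The published analysis states neither its
  baseline rate nor its follow-up distribution; these are the package's
  choices.
* Optional missing-completely-at-random clinical missingness
  (`missing_rate`), mirroring the shrunken denominators clinical tables
  show; the pipeline imputes medians fit on training folds.

What passing tests therefore show: the *machinery* — scoring, partitioning,
selection, CV accounting, survival estimation — is correct on data whose
ground truth is known. What they cannot show: real-data performance.
Independent covariates and exactly-informative features make synthetic AUCs
optimistic; no claim about clinical metric values transfers.

The voxel phantom (ellipsoidal pericardium, truncated-Gaussian-mixture EAT
shell, spherical uniform or radial-falloff lesions rasterized by the
voxel-centre-inside rule) exercises the imaging operators; it makes no
attempt at cardiac anatomy, gating or scanner noise.

## Selection and classification

Elastic-net logistic selection standardizes features internally (constant
columns dropped with a warning), builds a 100-value log-spaced λ path from
`λ_max = max_j |x_jᵀ(y − ȳ)| / (n·α)` — the smallest penalty at which all
coefficients are zero — down to `10⁻³·λ_max`, scores the path by validation
log-loss over stratified 5-fold CV (warm-started SAGA fits), refits at the
optimum and returns nonzero-coefficient features ordered by absolute
standardized coefficient. Importance confidence intervals, when requested,
come from bootstrap resampling of the selection at the chosen λ.

The default classifier is gradient boosting with the CatBoost-style
hyperparameters (100 iterations, learning rate 0.01, depth 6, L2 leaf
regularization 3, 0.75 per-level feature subsampling, 64 histogram bins,
Bernoulli row subsampling at 0.6, log-loss), realized on xgboost's
histogram tree learner; `random_forest`, `svm` (RBF, standardized inputs,
Platt-calibrated probabilities) and a plain `xgboost_style` backend are
interchangeable. All backends sit behind median imputation.

Evaluation is repeated stratified 5-fold CV. The operating point for
sensitivity/specificity is a fixed 0.5 probability threshold — the only
parameter-free choice, since no operating rule is published. Feature
selection is leak-free (re-run inside each training fold) when
`select_per_fold=True`; the default uses a fixed feature list, matching a
select-once reading of the original protocol, and both modes are exposed
because the published ordering of selection and CV is ambiguous. The
repetition count defaults to 25 at desk scale (5 in the end-to-end demo);
1,000 repetitions is a parameter, not a code change.

Model pairs are compared on identical patients: McNemar's χ² on discordant
correct/incorrect pairs without continuity correction (p = 1 by convention
when no pairs are discordant) and DeLong's variance-based test on the AUC
difference, implemented with the midrank algorithm and verified against an
independent R reference implementation on a frozen fixture.

## Survival

Kaplan–Meier curves use the product-limit estimator with Greenwood bands;
group contrast by two-sided log-rank. The Cox model is univariable on the
binary group, Efron tie handling (the only method lifelines provides; the
difference from Breslow is negligible at the tie rates the simulator
produces), Wald 95% CI on the log scale, Harrell's C-index on the fitted
risk. A binary marker caps Harrell's C below 1 — tied-risk pairs earn 0.5 —
so "perfect" group ordering yields the maximum attainable value for that
marker, not 1.0. Fits are refused with explicit errors when a group is
absent or eventless (complete separation).

## Numerical choices and degenerate inputs

* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); same spec + seed is bit-identical output.
* Lesion rasterization: voxel centre inside the sphere — the simplest rule
  a brute-force oracle can mirror exactly.
* Overlapping lesions of *different* arteries are an error (territory
  ambiguity); same-artery overlap merges.
* Zero-calcium panels: logs 0, diffusivity 0, flag false.
* Cohort summaries: constant continuous covariates in both arms report
  p = 1 (p = 0 if the constants differ); a binary covariate with an
  all-zero margin reports "not applicable" rather than a NaN chi-square.
* NIfTI spacing is validated on read (finite, positive); spacing is never
  assumed.

## Problem sizes

Defaults are desk-scale by design: the end-to-end demo runs 600 patients ×
5 CV repetitions; parameter-recovery checks use 200 cohorts of n = 2,000;
generator-calibration checks use n = 20,000. Every size is a function
argument, so study-scale runs (n ≈ 1,300 patients, 1,000 CV repetitions)
are configuration, not code.

## Known limitations

* The fat-omics catalogue guarantees the three feature families and the
  named SR/SL histogram features, not parity with any specific 211-feature
  inventory; the exact historical membership is not public.
* The cohort simulator's zero-correlation covariates and normal shapes are
  acknowledged simplifications; heavy-tailed score distributions are
  modeled only through the log-normal vessel draw.
* Diameter profiles are inputs (or synthesized); centerline extraction and
  lumen/wall segmentation are out of scope.
* Multivariable-adjusted Cox models and competing risks are out of scope.
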