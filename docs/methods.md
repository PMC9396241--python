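# Methods

`tnepredict` implements an analysis pipeline for predicting two outcomes of
a treat-and-extend (T&E) anti-VEGF regimen in neovascular age-related
macular degeneration (nAMD) from quantitative OCT biomarkers observed
during a two-visit observation window (baseline M0 and the 4-week
follow-up M1): the eye's visual responder status over 12 months and
whether its injection interval proves extendable.  Because per-visit
en-face biomarker maps from a real T&E trial arm are not publicly
distributable, the package ships a first-class synthetic cohort generator
that emulates the relevant data structure; every downstream stage runs on
either real thickness maps (as numpy arrays) or generated ones.

## Zonal OCT features

Inputs are per-biomarker en-face thickness maps (µm) on a fovea-centred
6 × 6 mm grid, for intraretinal fluid (IRF), subretinal fluid (SRF),
pigment-epithelial detachment (PED), hyperreflective foci (HRF) and the
photoreceptor (PR) layer.  Maps arrive at either 49 × 768 or 128 × 512
pixels depending on the scanner; all maps are bilinearly resampled on
pixel-centre coordinates to a canonical isotropic 128 × 128 analysis grid.
(The two native axes are both resampled, rather than only the B-scan axis:
zonal volumes are integrals and insensitive to in-plane resolution, and an
isotropic grid simplifies the zone geometry.  A consistency test holds the
two native grids to within 2% on zonal volumes.)

The ETDRS-style zones are the central 1 mm disc, the 1–3 mm parafoveal
ring, and the 3–6 mm perifoveal ring.  Zone membership is decided by the
Euclidean distance of each pixel centre from the geometric grid centre,
with half-open radial bands [r_lo, r_hi); the fovea is assumed at the grid
centre (scans are macula-centred; no foveal localisation is attempted).
Fluid compartments and HRF are summarised per zone as volumes in
nanolitres (Σ thickness_µm × pixel-area_mm², numerically), PR as mean
thickness in µm.  HRF is treated as a volume like the other compartments;
a count-based summary would be an alternative but is not implemented.

Difference features (M1 − M0) are computed on the zonal aggregates; by
linearity of the integrals this equals aggregating pixel-wise difference
maps, and a test asserts the antisymmetry this implies.  The predictor
vector is fixed-order: 45 imaging features (3 time blocks × 5 biomarkers ×
3 zones), then BCVA at M0 and M1, BCVA change, age, and sex (female = 1,
male = 0 — arbitrary but fixed; the classifier is tree-based, so the
coding is inert).  Eyes missing either visit's maps are excluded, never
imputed.

## T&E state machine

Every visit injects (proactive regimen).  The second injection always
follows at week 4 (loading dose); monthly dosing continues until disease
activity — IRF or SRF above a presence threshold, default 1 nl total per
fluid — first resolves.  Thereafter the interval extends by 2 weeks after
an inactive assessment (max 12) and shortens by 2 weeks after an active
one (min 4).  Extension is limited to two attempts; "attempt" is
operationalised as an extension-then-revocation episode: the first active
shortening from an interval above 4 weeks consumes one attempt, continued
shortenings within the same episode do not, and after the second
revocation the interval may shorten or hold but never re-extend.

An eye is labelled **extendable** when it received at least two injections
at intervals ≥ 8 weeks and did not fall back below 8 weeks afterwards
(i.e., the trailing run of ≥ 8-week intervals contains at least two); a
permissive variant counting any two ≥ 8-week intervals is available via a
flag.  Treatment patterns partition courses into monthly-intensive (all
intervals 4 weeks), continually-extended (non-decreasing intervals with
extension starting by the 4th injection), and individualized (the rest).
Visits are assumed to occur exactly on schedule; missed visits and
VA-based activity criteria are out of scope.

## Latent-class BCVA trajectories

Visual response subgroups are found with a latent class mixed model: a
K-component mixture (default K = 6) of linear mixed models with quadratic
fixed effects in time (months), a shared random intercept
u_i ~ N(0, τ²), residual σ², identity link, and no covariates.  The fit is
by EM: the random intercept is integrated analytically (per-eye marginal
covariance σ²I + τ²J, inverted via Sherman–Morrison), the E-step computes
exact class posteriors, and the M-step updates proportions exactly, class
coefficients by posterior-weighted GLS, and (τ², σ²) by one EM sweep over
the random effects.  Each full cycle is an ECM/GEM step, so the
observed-data log-likelihood is non-decreasing; tests assert monotonicity
on every fit.  σ² is floored at 1e-8.  A random slope is not implemented;
the random intercept is the smallest structure identifiable from three or
more visits per eye.

Initialisation is k-means on per-eye OLS quadratic coefficients; the best
of `n_starts` (default 10) seeded runs by final log-likelihood wins.
Convergence is declared at a relative log-likelihood change below 1e-6 or
500 iterations.  Runs that empty a class (proportion < 1/(10n)) are
discarded and retried; if all starts fail, the fit errors.  Classes are
reported sorted by intercept descending, which fixes label switching for
recovery tests.

Latent classes are merged into responders/non-responders by thresholding
the model-implied 12-month gain β₁·12 + β₂·144 at +5 letters (a common
clinically-meaningful change; configurable).  A 2 × 2 cross-tabulation
stratifies responder status by baseline BCVA at 50 letters, reporting
counts and one-decimal percentages of the total.

## Outcome prediction and evaluation

A random forest with 2000 trees, minimum node size 1, and 7 candidate
features per split predicts each binary target; the positive-class
probability is the forest vote share.  Evaluation uses stratified 10-fold
cross-validation (pooled out-of-fold predictions; per-fold AUCs are also
recorded, as is each fold's OOB error).  The AUC is computed in-package as
the Mann–Whitney concordance with ties at one half and is tested against a
brute-force all-pairs oracle and perfect/degenerate cases.  Confidence
intervals are 95% percentile bootstrap over 1000 case resamples
(single-class resamples redrawn).  Operating points: the Youden-optimal
point (ties broken toward higher specificity, matching the preference for
specificity in the interval task) and the sensitivity at the smallest
specificity ≥ 80%.  Permutation importance is the mean out-of-fold
accuracy decrease over 10 shuffles of each feature column within each
fold's test block — computed out-of-fold rather than OOB-internally so it
is independent of the forest implementation.  Three nested predictor sets
are evaluated: all 50, baseline-only (18), imaging-only (45).

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed once:

* **Cohort**: n = 270 eyes, six latent classes with mixing proportions
  (4, 173, 58, 12, 15, 8)/270; baseline BCVA ≈ 58 letters on average; age
  ~ N(75.2, 8.2²) clipped to [51, 95]; 55% female; scanner mix 65%
  49 × 768 and 35% 128 × 512.
* **BCVA**: per-class quadratics chosen so classes form responder
  (12-month gain ≥ +5 letters) and non-responder shapes at high (≥ 50) and
  low (< 50) baseline strata — a 2 × 2 responder-by-baseline structure;
  random intercept SD 4 letters, visit noise SD 3 letters, trajectories
  truncated to [0, 100].
* **Fluid kinetics**: per-injection multiplicative retention factors
  ordered IRF ≤ SRF ≤ PED (IRF clears fastest; PED responds partially and
  is floored at 25% of baseline, so it persists); baseline volumes
  log-normal (medians ≈ 80/120/250/5 nl for IRF/SRF/PED/HRF, with 15%/10%
  of eyes free of IRF/SRF).  Between visits, a per-week Bernoulli
  recurrence event regrows SRF (and, with probability 0.3, IRF) by a fixed
  per-eye fraction of baseline.  No quantitative recurrence rates or
  per-injection reduction fractions are established for this regimen; the
  ranges here are calibration choices that produce a mixed cohort of
  extendable and non-extendable eyes, not empirical claims.
* **Coupling** (`coupling` config, default 1): responder classes draw
  faster IRF clearance (retention 0.02–0.10 vs 0.12–0.30), and the
  recurrence hazard grows with SRF retention (≈ 0.004–0.10/week).  This
  makes IRF features genuinely prognostic for visual response and SRF
  persistence the driver of non-extendability, so the directional
  feature-importance structure is a property the pipeline can recover
  rather than an annotation.  Extendability ground truth always emerges
  from the simulated T&E course, never by direct assignment.  With
  `coupling = 0` the retention/hazard draws are independent of class —
  but the outcome labels still derive from the simulated disease course
  that the maps depict, so features remain predictive by construction.
  The faithful negative control is therefore `run_experiment(...,
  null_permute=True)`, which shuffles the labels (seeded) and severs all
  label–feature dependence; tests require chance-level AUC there.
* **Maps**: each fluid is rendered as a sum of three Gaussian bumps
  (geometry fixed per eye, so both scanner grids and both visits share the
  field), split across zones by per-eye Dirichlet weights centred on
  SRF-extrafoveal / IRF-central priors, and iteratively rescaled per zone
  until zonal volumes measured on the canonical grid match the simulated
  targets to 0.3% relative error.  PR is a smooth field around its
  baseline thickness.  Exclusion categories (missing scan, lost to
  follow-up, bad quality, protocol deviation) are assigned to distinct
  eyes with counts 10/22/5/5 at n = 270 (scaled proportionally otherwise).
* **Reproducibility**: every draw descends from
  `(config.seed, crc32(eye_id))`, so cohorts are bit-identical across runs
  and stable under eye reordering.

What the generator does **not** emulate: raw B-scan texture or speckle,
segmentation errors, foveal decentration, visit-schedule deviations,
drug-specific pharmacokinetics, or long-term remodelling (fibrosis,
atrophy, subretinal hyperreflective material).  Passing tests therefore
demonstrate that the pipeline's machinery is correct and that it recovers
structure it is designed to detect from data generated under its own
assumptions — not that the same performance would be attained on a real
trial cohort.

## Problem sizes and numerical choices

The default experiment uses n = 270 eyes (228 evaluable after
exclusions), 2000-tree forests, 10 folds, 1000 bootstrap resamples, and
10 permutation shuffles per feature; the full pipeline completes in a few
minutes on one CPU.  Unit tests use smaller cohorts and forests.
Bilinear resampling clamps target pixel centres to the source-centre
bounding box, preserving constant fields exactly.  Posterior ties in
class assignment break toward the lower class index; equal Youden indices
break toward higher specificity; zero-volume targets render as exactly
zero maps; degenerate inputs (empty masks, misaligned tables, single-class
labels) raise typed errors rather than warnings.
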