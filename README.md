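# tnepredict

Predicting visual outcomes and retreatment intervals of a treat-and-extend
(T&E) anti-VEGF regimen in neovascular age-related macular degeneration
(nAMD), from quantitative OCT biomarkers observed in the first two visits.

Anti-VEGF therapy dries the retina effectively, but treatment needs differ
widely between patients.  Under a T&E regimen the injection interval is
stretched by 2 weeks after a dry assessment and shortened by 2 weeks when
fluid recurs, between 4 and 12 weeks, with extension limited to two
attempts.  This package asks: from en-face thickness maps of five OCT
biomarkers — intraretinal fluid (IRF), subretinal fluid (SRF),
pigment-epithelial detachment (PED), hyperreflective foci (HRF) and the
photoreceptor (PR) layer — at baseline and 4 weeks, can we predict

* **responder status**: whether the eye's 12-month best-corrected visual
  acuity (BCVA) trajectory belongs to a gaining latent class, and
* **extendability**: whether the eye reaches and maintains an injection
  interval of ≥ 8 weeks?

It is aimed at ophthalmic image-analysis researchers who want the complete
analysis as reusable, tested code.  Since per-visit biomarker maps from a
real T&E trial arm cannot be redistributed, a seeded synthetic cohort
generator reproduces the data structure (scanner grids, loading dose,
fluid kinetics in which SRF clears more slowly than IRF and PED persists,
latent-class BCVA trajectories, extendable and non-extendable interval
dynamics), so every stage runs end-to-end without any download.

## Method

1. **Zonal features** — maps are bilinearly resampled to a canonical
   128 × 128 grid over 6 × 6 mm and summarised over the ETDRS-style zones
   (central 1 mm disc, 1–3 mm and 3–6 mm rings): volumes in nanolitres for
   fluids/HRF (Σ thickness_µm × pixel-area_mm²), mean thickness in µm for
   PR.  Two visits plus their difference give 5 × 3 × 3 = 45 imaging
   features; with BCVA at both visits, its change, age and sex the
   predictor has exactly 50 entries.
2. **Outcome labels** — a 52-week T&E course is run through the interval
   state machine; extendability requires ≥ 2 injections at ≥ 8-week
   intervals with no later fall-back.  Responder status comes from a
   latent class mixed model of BCVA: a K = 6 mixture of
   y_ij = β₀g + β₁g t + β₂g t² + u_i + ε_ij with u_i ~ N(0, τ²), fitted by
   EM with the random intercept integrated in closed form; classes with
   implied 12-month gain β₁·12 + β₂·144 ≥ +5 letters are responders.
3. **Prediction** — a random forest (2000 trees, node size 1, mtry 7)
   evaluated by stratified 10-fold cross-validation: pooled out-of-fold
   AUC (Mann–Whitney concordance), 95% percentile-bootstrap CI (1000
   resamples), Youden and 80%-specificity operating points, and
   permutation feature importance; over nested predictor sets (all 50 /
   baseline-only 18 / imaging-only 45).

See `docs/methods.md` for assumptions, parameter defaults, and what the
synthetic cohort does and does not emulate.

## Worked example

```python
import pandas as pd
from tnepredict import (
    CohortConfig, LcmmSpec, RfConfig, generate_cohort, simulate_course,
)
from tnepredict import pipeline as pl, predict_eval as pe
from tnepredict import synthetic_data as sd, tne_protocol as tp
from tnepredict import trajectory_classes as tc

eyes = generate_cohort(CohortConfig(n_eyes=270, seed=1))
courses = {e.eye_id: simulate_course(e) for e in eyes}
kept, tally = pl.exclusion_filter(sd.cohort_truth_table(eyes).reset_index())
print(tally, len(kept))
# {'missing_scan': 10, 'lost_to_followup': 22, 'bad_quality': 5,
#  'protocol_deviation': 5} 228

features = pl.extract_features(
    [e for e in eyes if e.eye_id in set(kept.eye_id)], courses)
labels = tp.label_courses([courses[i] for i in features.index])

vis = tp.courses_to_frame([courses[i] for i in features.index])
series = pd.DataFrame({"eye_id": vis.eye_id,
                       "t_months": vis.week / sd.WEEKS_PER_MONTH,
                       "bcva": vis.bcva})
fit = tc.fit_lcmm(series, LcmmSpec(k_classes=6, seed=1))
responder = tc.responder_labels(fit).loc[features.index]

ev = pe.cv_predict(features, labels["extendable"].astype(bool),
                   rf=RfConfig(seed=1), k=10, seed=1)
print(f"extendable AUC {ev.auc:.3f}, 95% CI {ev.auc_ci_95}")
# extendable AUC 0.805, 95% CI (0.746, 0.860)

imp = pe.permutation_importance(ev, features, seed=1)
print(imp.head(3))
# SRF_peri_3_6mm_M1        0.015789
# SRF_central_1mm_M1       0.003947
# SRF_para_1_3mm_change    0.003070
```

On this synthetic cohort, 228 of 270 eyes are evaluable after the four
exclusion rules; the cross-validated AUC for the extendable-interval
target is ≈ 0.80, and the most important predictors are the SRF volumes
remaining at the follow-up visit — persistent SRF is what blocks interval
extension, while for the responder target the IRF features dominate among
the imaging predictors.  (Exact numbers depend on the seed.)

A command-line interface mirrors the stages
(`tnepredict simulate|features|label|lcmm|predict|run-all`, with
`--config config.yaml` and `--seed`); `run-all` writes every artifact plus
a SHA-256 manifest, and reruns with the same configuration reproduce
identical hashes.

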