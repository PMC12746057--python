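# vsgrowth

Predicting growth of untreated sporadic vestibular schwannomas (VS) under
wait-and-scan management, from structural (T2-weighted) and dynamic
contrast-enhanced (DCE) MRI.

About a quarter to a half of newly diagnosed VS grow during observation;
the rest stay stable or regress. If growth could be predicted at
diagnosis, follow-up schedules and treatment decisions could be
personalised instead of waiting for growth to declare itself. This package
implements, as a tested and reusable library, the full computational chain
such a study needs:

1. **DCE pharmacokinetics** (`vsgrowth.dce`) — SPGR signal modelling,
   variable-flip-angle T1 mapping, signal→concentration conversion, and
   voxelwise fitting of the extended Tofts model

   `C_t(t) = v_p C_p(t) + K^trans ∫₀ᵗ C_p(τ) e^(−k_ep (t−τ)) dτ`,
   `k_ep = K^trans/v_e`,

   producing K^trans, v_e and v_p maps with per-voxel convergence flags.
2. **ROI conditioning** (`vsgrowth.roi`) — Z-score normalisation, cyst
   removal, 3×3 cross-shaped in-plane erosion against partial-volume
   contamination, nearest-neighbour mask projection between grids.
3. **Growth labelling** (`vsgrowth.labels`) — patient-specific
   volume-dependent significant-change thresholds (≈5–30% relative
   change, non-increasing in baseline volume) and the two-consecutive-scan
   growing/stable/shrinking rule, binarised to growth vs nongrowth.
4. **Radiomics** (`vsgrowth.radiomics`) — fixed-bin-width discretization
   (training-set mean ROI range / N_bins, min-anchored, no clipping) and
   101 IBSI-style features per channel (18 first-order, 8 shape, 24 GLCM,
   16 GLRLM, 16 GLSZM, 5 NGTDM, 14 GLDM) over the four channels T2,
   K^trans, v_e, v_p → a 404-element named vector per patient, every
   texture feature verified against brute-force oracles.
5. **Prediction** (`vsgrowth.pipeline`) — nested stratified 5-fold CV:
   per-fold standardisation → ANOVA-F top-k selection → PCA to n
   components → class-weighted SVM with Platt-calibrated probabilities and
   per-fold Youden cutoffs; hyper-parameter search over kernel, C,
   bandwidth, N_bins, k, n; ablation baselines (volume-only, T2-only,
   DCE first-order-only). All fold statistics are fitted strictly on
   training patients.
6. **Evaluation** (`vsgrowth.evaluation`) — AUC/AUCPR, confusion metrics
   with diagnostic odds ratio, calibration-in-the-large and Brier score,
   reliability and decision curves, rule-in/rule-out operating points,
   paired bootstrap model comparison, per-fold feature-set stability,
   Cohen's d effect sizes and permutation importance.

No public VS DCE dataset exists, so `vsgrowth.synthetic` generates seeded
cohorts with the structure such a study assumes (110 patients, 64%
growing, log-normal volumes with median 0.7 cm³, class-conditional
correlated parameter-map fields, label-consistent follow-up
trajectories). Everything below runs on generated data.

## Worked example

```python
from vsgrowth.synthetic import CohortConfig, generate_cohort
from vsgrowth.pipeline import CohortFeatureSource, run_nested_cv, run_baseline
from vsgrowth.evaluation import evaluate_predictions, paired_bootstrap_auc

patients = generate_cohort(CohortConfig(n_patients=40, seed=2024))
source = CohortFeatureSource(patients)          # ROI prep + caching
full = run_nested_cv(source, seed=2024)         # nested 5x5 CV, 404 features
vol = run_baseline(source, "volume_only", seed=2024)

print(f"full model:  AUC {full.summary['auc_mean']:.2f} ± "
      f"{full.summary['auc_sd']:.2f}, "
      f"accuracy {100*full.summary['accuracy_mean']:.1f}%")
print(f"volume only: AUC {vol.summary['auc_mean']:.2f}")
report = evaluate_predictions(full.oof, full.fold_metrics)
print(f"pooled DOR {report['pooled']['dor']:.1f}, "
      f"Brier {report['pooled']['brier']:.3f}")
```

prints

```
full model:  AUC 1.00 ± 0.00, accuracy 90.0%
volume only: AUC 0.46
pooled DOR 145.0, Brier 0.046
```

The full radiomics model separates the classes essentially perfectly —
expected, because the generator plants strong class differences in the
parameter-map statistics (growing tumours: higher K^trans and v_p;
stable/regressing: larger, more clustered v_e dispersion). The
volume-only baseline sits at chance because baseline volume is drawn
independently of outcome; the gap between the two is the added value of
the DCE-derived features. A pooled diagnostic odds ratio of ~145 means the
odds of a correct growth call are two orders of magnitude higher than
those of a false alarm, and the low Brier score reflects well-calibrated
out-of-fold probabilities on this synthetic cohort. None of this is a
clinical performance claim: the cohort is synthetic and deliberately
easy (see `docs/methods.md`).

A thin CLI covers the same stages
(`vsgrowth simulate|label|extract|run-all`), e.g.

```sh
vsgrowth run-all --n-patients 40 --seed 2024 --out report.json
```

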