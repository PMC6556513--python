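# msresponse

Detecting the imaging response to treatment in multiple sclerosis — or any
disease with anatomically distributed pathology — is hard with the small set
of conventional biomarkers (total brain volume, lesion count, total lesion
volume). `msresponse` implements, as a tested and reusable pipeline, the
comparison between such **low-dimensional** models and **high-dimensional**
models built from hundreds of regional imaging features, together with the
statistical machinery needed to make that comparison honest:

* **slope-sign trajectory features** — for every imaging feature and every
  patient, an OLS line is fitted to the feature against scan time separately
  over the pre-treatment (t &lt; 0) and post-treatment (t &gt; 0) periods, and
  only the slope's *sign* is kept (trajectory ∈ {−1, 0, +1}); homologous
  left/right region pairs are collapsed by summation into {−2 … +2};
* **confounder removal with adversarial verification** — TIV normalisation,
  Bayesian-ridge residualisation of every feature on the covariate design
  (age, gender, scanner manufacturer, field strength, disease duration,
  EDSS, slice thickness, voxel resolution), then a check that a multivariate
  classifier can no longer predict any binarised confounder from the
  features;
* **subject-constrained bootstrap cross-validation** — Monte-Carlo CV
  (500 iterations by default) allocating 80% of *patients* to training and
  20% to testing, so both periods of a patient always fall on the same side;
  per-iteration out-of-fold AUC, accuracy, sensitivity, specificity,
  balanced F and MCC aggregated as mean ± 1.96 SE;
* **greedy forward-stepwise feature selection** on the mean out-of-fold AUC,
  and an **AUC-weighted ensemble** of the regional-volume and regional-
  disconnection models: score = (AUC_v·s_v + AUC_d·s_d)/(AUC_v + AUC_d);
* **permutation null models** — each patient's per-feature time series is
  shuffled across that patient's scan times before slopes are computed;
* **simulated randomised controlled trials** — trials of N patients drawn
  without replacement, association between classifier output and true
  period tested with Fisher's exact test; per N, the mean odds ratio and
  the achieved power at α = 0.01.

Because the clinical cohort such analyses run on cannot be redistributed,
the package ships a first-class **synthetic cohort generator** that emulates
the per-scan feature tables: 72 homologous region pairs (288 regional
variables per scan), regional atrophy before treatment and
stabilisation/recovery after it, rising-then-flattening disconnection,
monotone lesion accrual, linear covariate effects on the features, and
per-scan measurement noise, with ground truth retained for
parameter-recovery tests.

## Worked example

```python
import pandas as pd
import msresponse as mr
from msresponse.experiment import predictor_sets
from msresponse.models import bootstrap_cv, ClassifierSpec, ensemble_results
from msresponse.rct import RCTConfig

cohort = mr.generate_cohort(mr.CohortConfig(seed=42))        # 103 patients
deconf = mr.residualize_features(mr.normalize_by_tiv(cohort))
traj = mr.build_trajectory_dataset(deconf)
print(f"{len(traj)} trajectory vectors, "
      f"{(traj.period_class == 0).mean():.1%} pre-treatment")

spec = ClassifierSpec(kind="svm")
results = {name: bootstrap_cv(traj, spec=spec, features=f, n_iter=100, seed=777)
           for name, f in predictor_sets(traj).items()}
results["ensemble"] = ensemble_results(
    results["regional_volume"], results["regional_disconnection"])
for name, res in results.items():
    mean, lo, hi = res.aggregate["auc"]
    print(f"{name:26s} AUC {mean:.3f} [{lo:.3f}, {hi:.3f}]")

frame = pd.DataFrame({
    "patient_id": traj["patient_id"],
    "label": results["ensemble"].labels,
    "prediction": mr.consensus_predictions(results["ensemble"]),
})
curve = mr.simulate_rcts(frame, RCTConfig(n_rep=200, N_grid=[20, 50, 103], seed=7))
print(curve[["N", "or_mean", "power"]].round(2).to_string(index=False))
```

prints

```
130 trajectory vectors, 33.1% pre-treatment
brain_volume               AUC 0.528 [0.506, 0.550]
lesion_count               AUC 0.554 [0.538, 0.571]
total_lesion_volume        AUC 0.582 [0.563, 0.600]
best_low_dimensional       AUC 0.578 [0.558, 0.598]
regional_volume            AUC 0.951 [0.942, 0.961]
regional_disconnection     AUC 0.963 [0.956, 0.969]
ensemble                   AUC 0.974 [0.968, 0.979]
  N  or_mean  power
 20    74.99   0.84
 50   157.74   1.00
103   291.67   1.00
```

The cohort composition (16 patients with only pre-treatment scan pairs, 60
with only post-treatment, 27 with both) fixes the class balance at 33.1% /
66.9%. The low-dimensional aggregates hover just above chance while the
regional models and their ensemble detect the intervention clearly, and the
simulated trials show the corresponding gain in odds ratio and achieved
power as enrolment grows — the qualitative pattern the pipeline exists to
quantify. Exact numbers depend on the generator seed.

A command-line surface mirrors the pipeline stages
(`msresponse simulate | deconfound | verify | features | select | fit |
null | rct | report | run-all`); `msresponse run-all --seed 0 --out runs/demo`
writes the full table/figure bundle with a manifest for bit-identical
regeneration.

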