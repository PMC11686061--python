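# dbsnet

EEG functional-connectivity analysis of subthalamic deep brain stimulation
(STN-DBS) efficacy in Parkinson's disease.

Deep brain stimulation of the subthalamic nucleus relieves the motor
symptoms of Parkinson's disease, but a substantial minority of patients
respond poorly, and there is no accepted electrophysiological marker that
predicts response before surgery. `dbsnet` implements a complete analysis
chain for task-EEG connectivity data addressing that question, for
researchers working with source-reconstructed EEG of DBS cohorts:

* **Phase-lag-index networks** — per subject, frequency band (delta through
  high gamma), and stimulation condition (ON/OFF), from ROI time series of a
  visual oddball task:
  PLI(i,j) = |⟨sign(Δφ_ij(t))⟩_t| with the instantaneous phase difference
  wrapped into (−π, π]; zero-lag (volume-conducted) coupling contributes
  nothing.
* **Motor-subnetwork statistics** — the 14 bilateral AAL motor ROIs
  (precentral, SMA, postcentral, caudate, putamen, pallidum, thalamus); the
  91 within-subnetwork connections are summarized per subject and condition
  by the first eigenvariate (first right singular vector of the centered
  subjects × connections matrix), tested ON vs OFF per band by a
  covariate-adjusted Wilcoxon signed-rank test under Benjamini–Hochberg FDR,
  with seed-connectivity post-hocs and a Spearman partial correlation of the
  stimulation-OFF scores with motor improvement
  (UPDRS_diff = MDS-UPDRS III ON − OFF).
* **Whole-brain patterns** — edgewise paired tests across all 4005
  connections, and PCA connectivity patterns of the ON state with an
  elbow-selected component count, correlated with neuropsychological
  T-scores.
* **Responder classification** — a nested leave-one-out procedure that
  sweeps the UPDRS_diff response threshold in the inner loop, extracts a
  connectivity profile (edges whose mean ON−OFF change among
  possibly-optimal responders deviates ≥ 4 SD from the band average), trains
  a linear SVM on stimulation-OFF values of the profile edges, and reports
  PPV/NPV/sensitivity/specificity averaged over folds and repetitions.
* **Synthetic cohorts** — a generator that plants a motor pattern
  anticorrelated with UPDRS improvement, a multi-band responder profile, and
  a cognition-linked whole-brain pattern into PLI-like matrices, with ground
  truth emitted separately, so every stage of the chain is testable without
  patient data.

See `docs/methods.md` for the full model description, parameter defaults,
and design decisions.

## Worked example

Run the whole chain on a simulated cohort (43 subjects, 90 ROIs, six bands)
from the command line:

```sh
dbsnet run-all --out demo --seed 1 --repetitions 2
```

or drive it from Python:

```python
import numpy as np
from dbsnet import (CohortSpec, generate_fc_cohort, MotorROISet, AAL90_LABELS,
                    on_off_subnetwork_test, motor_eigenvariate_scores,
                    correlate_off_with_updrs)

cohort = generate_fc_cohort(CohortSpec(seed=1))
rois = MotorROISet.from_labels(list(AAL90_LABELS))
meta = cohort.metadata
cov = np.column_stack([meta.age, (meta.gender == "F").astype(float)])

results, mask, _ = on_off_subnetwork_test(cohort.subjects, cohort.bands,
                                          rois, covariates=cov)
print({b: round(r.p_value, 4) for b, r in results.items()})
_, s_off, _ = motor_eigenvariate_scores(cohort.subjects, "high_gamma", rois)
res = correlate_off_with_updrs(s_off, meta.updrs_diff.to_numpy(), cov)
print(f"rho = {res.effect:.2f}, p = {res.p_value:.2g}")
```

which prints

```
{'delta': 0.2589, 'theta': 0.3813, 'alpha': 0.5581, 'beta': 0.5105,
 'low_gamma': 0.415, 'high_gamma': 0.0}
rho = -0.97, p = 3.4e-26
```

Reading: only the high-gamma band shows a stimulation-ON increase of
within-motor-subnetwork connectivity surviving FDR across the six bands
(p ≈ 0 here because the generator plants the effect in that band), and the
stimulation-OFF motor eigenvariate correlates negatively with UPDRS_diff —
subjects who improve most under stimulation already express the motor
pattern more strongly with the stimulator off. The planted correlation is
deliberately strong; on real data the same code path reports a much smaller
effect.

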