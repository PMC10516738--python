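# hnart — head-and-neck volume tracking and ART-triage prediction

During external radiotherapy of head-and-neck (HN) cancer, many patients lose
enough neck volume that the delivered dose drifts from the plan; adaptive
radiotherapy (ART — mid-course replanning) fixes this but is too costly to
apply to everyone.  `hnart` implements a quantitative triage pipeline for this
problem, aimed at medical-physics researchers:

1. **Track** the body volume between the C1 and C5 spinous-process levels on
   the per-fraction cone-beam CT already acquired for positioning, using the
   couch-shift registration records to map the planning-image annotation into
   every fraction.  For fraction *n*, `ΔV_n = (V_n − V_1)/V_1 × 100` (signed;
   reductions negative), with a successive-jump QC check (|ΔΔV| > 5 pp) and an
   automatic re-threshold repair path.
2. **Label** each patient *reduction* when some run of three consecutive
   fractions has mean ΔV ≤ −10% (the ART-need surrogate); the trigger is the
   middle fraction of the first qualifying run.
3. **Predict** that label before treatment from clinical factors, nine DVH
   dose parameters (D2%/D50%/D98% for GTVp/GTVn/PTV) and per-GTV radiomic
   panels: ICC(A,1) > 0.7 robustness filtering, four filter selectors
   (chi-square, MRMR, NCA, ReliefF), and nested stratified 5-fold
   cross-validation tuning random forests and SVMs by balanced accuracy, with
   a 1–10 feature-count sweep per feature-set/selector/classifier cell.

Real patient data of this kind is not publicly available, so the package
includes a first-class synthetic module: shrinking ellipse-stack phantoms with
exact closed-form volumes (couch slab, air cavity, noise, recorded couch
shifts) and 172-patient-style feature tables with a declared effect structure
(an IMC1-like texture feature with group means −0.35 vs −0.47, plus HPV and
chemotherapy factors) and a null mode.  Every stage is tested against these
known-truth inputs.

## Worked example

```python
import numpy as np
from hnart import (PhantomSpec, generate_phantom_series, track_series,
                   classify_reduction, CohortSpec, generate_feature_table,
                   rank_features, nested_cv_run, HyperGrid)
from hnart.selection import build_feature_matrix

# a patient shrinking 1.2% per fraction over a 33-fraction course
spec = PhantomSpec(n_fractions=33, shrink_rate=0.012, seed=42)
images, records, window, truth = generate_phantom_series(spec)
trace = track_series(images, records, window, spec.crop_box)
label = classify_reduction(trace)
print(f"measured dV at fractions 10/20/33: {trace.delta_v_pct[9]:.2f} / "
      f"{trace.delta_v_pct[19]:.2f} / {trace.delta_v_pct[32]:.2f} %")
print(f"group: {label.group}, trigger fraction: {label.trigger_fraction}")

# predict reduction from a synthetic cohort table
table = generate_feature_table(CohortSpec(seed=0))
fm = build_feature_matrix(table, "clin+rad")
print("MRMR top 3:", rank_features(fm, "mrmr", k=3).features[:3])
report = nested_cv_run(fm, "mrmr", "rf", n_features=3, mode="paper",
                       seed=0, grid=HyperGrid.reduced())
print(f"AUC {report.mean('auc'):.3f}  accuracy {report.mean('accuracy'):.3f}")
```

prints

```
measured dV at fractions 10/20/33: -10.27 / -20.50 / -32.03 %
group: reduction, trigger fraction: 10
MRMR top 3: ['hpv16_positive', 'chemotherapy', 'gtvp_glcm_imc1']
AUC 0.856  accuracy 0.809
```

The tracked ΔV follows the phantom's analytic geometric decay
(`(1−0.012)^(f−1) − 1`, i.e. −10.3% at fraction 10) to within a fraction of a
percentage point; the patient triggers the reduction rule at fraction 10.  On
the cohort table, MRMR's top three are exactly the three columns built to
carry signal, and the nested-CV AUC reflects that synthetic effect strength —
it is a recoverability check, not a clinical performance claim.

## Command line

```bash
hnart simulate --out sim --n-fractions 15 --n-patients 60 --seed 1
hnart track --images sim/images --reg sim/reg.csv --annotation sim/annotation.json --out trk
hnart select --table sim/features.csv --method mrmr --k 10 --out ranking.csv
hnart evaluate --table sim/features.csv --selector mrmr --classifier rf --out reports.json
hnart run --demo --out run_demo       # full study at desk scale
```

`hnart run` writes per-patient traces, labels, the ICC robustness report,
per-selector rankings, the 56-cell summary grid (feature set × selector ×
classifier) and a config snapshot that reproduces the run byte for byte.

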