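# csftoolkit

Analytics for predicting **intrathecal immunoglobulin synthesis (ISI)**
from routine CSF/serum chemistry. Confirming ISI requires isoelectric
focusing (IEF) for oligoclonal bands — a slow, specialized assay — while
nephelometric albumin and IgG levels are available within hours. For
clinicians and biostatisticians evaluating surrogate markers (typically
in neuro-ICU or neuroimmunology cohorts), csftoolkit provides:

- the three standard CSF index scores, with strict literature cutoffs:
  - IgG quotient `QIgG = CSF IgG / serum IgG` (> 0.0035),
  - IgG index `= QIgG / QAlb` with `QAlb = CSF albumin / serum albumin`
    (> 0.7),
  - Reiber's hyperbolic discrimination value
    `serum IgG × (QIgG − QLim)` in mg/L, with
    `QLim = 0.93·√(QAlb² + 6·10⁻⁶) − 1.7·10⁻³` and age-based
    `QAlb = (4 + age/15)/1000` (> 0 indicates probable synthesis);
- 2×2 diagnostic evaluation: Se/Sp/PPV/NPV with Wilson intervals,
  likelihood ratios, Youden index `J = Se + Sp − 1`, Woolf odds-ratio
  intervals, chi-square tests;
- ROC curves with exact/permutation/normal AUC null tests,
  Youden-optimal cutoffs, and the likelihood-ratio **grey zone**
  (lower bound = Youden cutoff, upper bound = first threshold with
  LR+ > 10; values in between are "intermediate");
- univariable screens and backward-stepwise multivariable logistic
  regression (Wald exit p > 0.05) over median-dichotomized factors;
- a calibrated synthetic neuro-ICU cohort generator so every stage is
  testable end-to-end without patient data.

See `docs/methods.md` for the model details, generator calibration and
numerical conventions.

## Worked example

A 50-year-old with CSF albumin 260 mg/L, CSF IgG 50 mg/L, serum albumin
36 g/L and serum IgG 11 g/L:

```python
from csftoolkit import PatientRecord, compute_panel, decision_support

patient = PatientRecord(
    patient_id="example", age=50, sex="female",
    isi_positive=False, cns_ad=False,
    csf_albumin=260.0, csf_igg=50.0,      # mg/L
    serum_albumin=36.0, serum_igg=11.0,   # g/L
)
panel = compute_panel(patient)
print(f"QIgG      {panel.q_igg:.7f}")
print(f"IgG index {panel.igg_index:.4f}")
print(f"Reiber    {panel.reiber_value:+.2f} mg/L")
print(decision_support(patient).category)
```

prints

```
QIgG      0.0045455
IgG index 0.6294
Reiber    -10.39 mg/L
unlikely
```

QIgG exceeds its 0.0035 cutoff, but the IgG index (0.63) is below the
grey zone (0.67–0.80), and the Reiber value is negative — QIgG sits
below the diffusion limit QLim — so intrathecal synthesis is unlikely;
IEF remains the confirmatory test.

Evaluating a marker against IEF from 2×2 counts (here: index positive in
53/93 reference-positive and 11/173 reference-negative patients):

```bash
csftoolkit perf --tp 53 --fp 11 --fn 40 --tn 162
```

```json
{
  "tp": 53,
  "fp": 11,
  "fn": 40,
  "tn": 162,
  "sensitivity": 0.5698924731182796,
  "specificity": 0.9364161849710982,
  "ppv": 0.828125,
  "npv": 0.801980198019802,
  "lr_positive": 8.962854349951122,
  "lr_negative": 0.45931235895393596,
  "youden": 0.5063086580893779
}
```

A full synthetic-study round trip:

```bash
csftoolkit simulate --seed 7 --n 266 --out cohort.csv
csftoolkit indexes cohort.csv --out panels.csv
csftoolkit roc cohort.csv --marker igg_index --reference isi_positive --out-prefix igg
csftoolkit analyze cohort.csv --out report.json
```

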