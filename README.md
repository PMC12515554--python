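# fastscore

Scoring and validation machinery for the **Fluid Assessment Scoring Tool
(FAST)**, a ten-variable bedside composite for fluid overload in
critically ill children.

Fluid overload — a pathological positive fluid balance — is associated
with worse outcomes in the pediatric ICU, yet no single bedside measure
captures it reliably: fluid-balance charts are often inaccurate, daily
weights are hard to obtain in intubated children, and chest X-rays are
insensitive. FAST grades ten routinely collected variables on an ordinal
0 (normal) to 3 (severe) scale and sums them:

| Variable | 0 | 1 | 2 | 3 |
|---|---|---|---|---|
| BUN trend (decrease) | <15% | 15–25% | 26–50% | >50% |
| Urine specific gravity | ≥1.010 | 1.005–1.009 | 1.000–1.004 | <1.000 |
| Fluid balance (mL/kg/day) | <15 | 15–30 | 30–50 | >50 |
| Weight change | <7% | 7–10% | 11–15% | >15% |
| Urine output (mL/kg/h)* | ≤3 | 3–3.5 | 3.5–4 | >4 |
| Fontanelle | flat | full | bulging | bulging + tense |
| Eyes | normal | swollen | puffy / conjunctival edema | puffy, unable to open |
| Liver below costal margin | <1 cm | 1–2 cm | 2–3 cm | >3 cm |
| Skin/extremities | no edema | limbs or abdomen | limbs and face | anasarca |
| Chest X-ray | no excess fluid | mild | moderate | severe |

\* not scored on diuretics or in renal failure (counts as missing).

Unmeasurable variables (closed fontanelle, no weight) are omitted from
the sum without reweighting; an encounter with more than two missing
variables is invalid. The total ranges 0–30 when everything is
measurable.

The package is aimed at clinical researchers validating or extending the
score. It provides:

- **scoring** — per-variable subscores, totals, missing-variable policy,
  CSV in/out, a vectorized path for large cohorts;
- **validation** — the non-parametric ROC cut-point table against a
  binary high-thoracic-fluid-content (TFC) reference (sensitivity,
  specificity, correctly classified per integer cut `c` for the rule
  FAST ≥ c, with Clopper–Pearson 95% CIs), cut-point selection policies
  (balanced |Se − Sp|, maximum accuracy, Youden J), empirical
  pair-counting AUC, dichotomized AUC (Se + Sp)/2, and seeded stratified
  k-fold cross-validated AUC;
- **fixture** — exact reconstruction of the 118-encounter development
  cohort (78 TFC-high, 40 TFC-normal) from its published per-cut
  operating characteristics: the sensitivity column is the
  positive-class survivor function of the score and 1 − specificity the
  negative-class one, so differencing recovers the per-score counts;
- **outcomes** — Mann–Whitney rank-sum comparisons (tie-corrected
  normal z, χ² = z², plus an exact-enumeration mode for small samples)
  of ventilator/PICU/hospital days across a cut;
- **synthetic** — a seeded latent-state cohort simulator for end-to-end
  testing without any patient data.

## Worked example

```bash
$ fast fixture -o fixture.csv
wrote 118-encounter fixture -> fixture.csv

$ fast roc fixture.csv -o roc_table.csv --policy max_accuracy
AUC 0.8527; max_accuracy cut 3 (sens 92.31%, spec 67.50%, accuracy 83.90%)

$ fast cv fixture.csv -o cv.json --cut 3 --repeats 200 --seed 1
mean CV AUC 0.7991 (95% 0.5625-1.0000, 10 folds x 200 repeats, seed 1)
```

The first command rebuilds the development cohort from the embedded
survivor proportions. The second computes the full cut-point table
(`roc_table.csv`, percent to 2 decimals) and reports the continuous
score's pair-counting AUC, 0.8527, plus the operating point of the
maximum-accuracy cut: FAST ≥ 3 classifies 83.90% of encounters correctly
with 92.31% sensitivity and 67.50% specificity against the high-TFC
reference. The third cross-validates the ≥3-dichotomized rule with
stratified 10-fold CV repeated 200 times from seed 1: the mean held-out
AUC is 0.7991 ≈ (Se + Sp)/2, with the wide percentile interval
reflecting 12-encounter folds. The same workflow runs end-to-end from a
config file via `fast run`, on raw observation tables via `fast score`,
and on simulated cohorts via `fast simulate`.

```python
from fastscore import study_fixture, cutpoint_table, select_cutpoint

table = cutpoint_table(study_fixture())
best = select_cutpoint(table, policy="balanced")   # cut 4: Se 79.49%, Sp 80.00%
```

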