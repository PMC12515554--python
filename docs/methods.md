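# Methods

## The score

FAST sums ten ordinal subscores, each 0–3, over clinical, laboratory and
imaging indicators of fluid accumulation. The printed rubric uses
integer-ish bin labels with seams ("15% to 25%" followed by "26% to
50%"; "1 to 2 cm" followed by "2 to 3 cm"). We map every numeric
variable onto contiguous half-open bins so that any value in the valid
domain receives exactly one subscore and the mapping is monotone in the
overload direction:

- BUN decrease d = −(percent trend): [0,15) → 0, [15,26) → 1, [26,50] → 2, >50 → 3
- urine specific gravity: ≥1.010 → 0, [1.005,1.010) → 1, [1.000,1.005) → 2, <1.000 → 3
- fluid balance (mL/kg/day): <15 → 0, [15,30) → 1, [30,50] → 2, >50 → 3
- weight gain (%): <7 → 0, [7,11) → 1, [11,15] → 2, >15 → 3
- urine output (mL/kg/h): [0,3] → 0, (3,3.5] → 1, (3.5,4] → 2, >4 → 3
- liver edge (cm): [0,1) → 0, [1,2) → 1, [2,3] → 2, >3 → 3

Categorical variables (fontanelle, eyes, skin, chest X-ray) score their
ordinal position. Values in the dehydration direction — rising BUN,
negative balance, weight loss, specific gravity above 1.010, urine
output under 1 mL/kg/h — score 0 with a logged note: the rubric measures
overload only, and dehydration has its own established clinical scores.
A "severe" specific gravity below 1.000 is kept verbatim from the rubric
even though urine osmolality cannot realistically produce it; in
practice that subscore tops out at 2.

Missing variables are omitted from the sum with no reweighting, on the
rationale that the remaining variables carry the signal; more than two
missing invalidates the encounter and excludes it downstream. Urine
output on diuretics or in renal failure, and a closed fontanelle, are
treated as missing. The encounter — not the patient — is the analysis
unit, with no within-patient clustering adjustment.

Weight change is percent change against a caller-chosen baseline
(admission weight or previous day); the rubric does not fix one.

## The reconstructed development cohort

The 118-encounter pilot cohort (78 TFC-high, 40 TFC-normal) is shipped
as an exactly reconstructed score × label table. For an integer score,
the published sensitivity column at cuts 0..8 is the positive-class
survivor function P(score ≥ c) and 1 − specificity the negative-class
one. Differencing adjacent values, scaling by the class size and
rounding gives integer per-score counts ([1,3,2,10,14,20,10,9,9] and
[12,8,7,5,4,1,0,1,2]); scores above 8 are lumped at 8, which cannot
affect any cut ≤ 8. Reconstruction validates that counts are
non-negative, that each class sums exactly to its size, and (in tests)
that re-running the cut-point analysis reproduces every published cell
at 2-decimal percent precision. The pooled reconstruction has median
score 4 with IQR (2, 6). Raw per-variable observations and outcome
columns are *not* recoverable from the published table, so
outcome-comparison numbers are exercised on synthetic data only.

## ROC analysis and cut-point selection

The classification convention is **score ≥ cut predicts overload** (a
score equal to the cut is positive). Sensitivity and specificity per cut
carry exact binomial (Clopper–Pearson) 95% intervals, the convention of
the classical non-parametric ROC tabulation; at the ≥3 cut the fixture
gives 92.31% (84–97%) sensitivity. The empirical AUC is the pair-counting
statistic P(score_pos > score_neg) + ½P(tie), computed through the
midrank identity and identical (to 1e-12, verified by test) to the
trapezoidal area of the ROC polygon traced by the cut-point rows. The
AUC of a dichotomized rule is (Se + Sp)/2.

`select_cutpoint` offers three policies: `balanced` minimizes
|Se − Sp| (ties broken toward higher accuracy, then the lower cut),
`max_accuracy` maximizes the correctly-classified proportion, `youden`
maximizes Se + Sp − 1. On the fixture, balanced selects cut 4 and
max-accuracy cut 3.

## Cross-validated AUC

The published cross-validation procedure is underspecified (fold
construction, what is refit), so we fix a reproducible convention: folds
are stratified by the TFC label with shuffling driven entirely by the
seed (per-repeat fold seeds derive from a `SeedSequence`), and nothing
is refit per fold — the score is a fixed rule, so each fold simply
evaluates its held-out encounters, dichotomized at the chosen cut
((Se + Sp)/2) or rank-based for the continuous score. Fold AUCs are
averaged over folds × repeats; the 95% interval is the percentile
interval of the fold AUCs (a bootstrap interval over repeats would be a
defensible alternative; the percentile interval is reported because it
needs no extra resampling layer). Single-class folds — impossible under
stratification when each class has ≥ k members, which is enforced — are
excluded with a warning. On the fixture at cut 3 the mean over 200
repeats is ≈0.80, matching the dichotomized full-sample value 0.79905;
the fold-level interval is wide because each held-out fold has only ~12
encounters.

## Outcome comparisons

Ventilator, PICU and hospital days are compared below vs at-or-above a
cut with the Mann–Whitney rank-sum test. U uses midranks; z is the
tie-corrected normal approximation **without** continuity correction;
the statistic is reported as χ² = z² with 1 df, the form conventional in
clinical tables. For combined n ≤ 12 an exact mode enumerates all
C(n, n_a) labelings and computes the two-sided tail of |U − n_a·n_b/2|
(ties handled exactly through midranks). All-tied data return χ² = 0,
p = 1. Quartiles use Tukey hinges (median-of-halves), fixed because no
quartile rule is canonical; the convention matters only at small n.
Nesting violations (ventilator > PICU days) log a warning rather than
raising — real charts contain them.

At combined n ≤ 10 the normal approximation is coarse: against exact
enumeration the mean absolute p-difference is ≈0.14 (worst cases on
heavily tied tiny samples approach 0.7, where the exact two-sided region
collapses to the whole sample space). The asymptotic test is
well-calibrated at moderate n: its null rejection rate at α = 0.05 is
≈5% in seeded simulation.

## Synthetic cohorts

The simulator draws a latent overload state per encounter
(default prevalence 0.66, two-thirds as in the development cohort), then
emits each raw variable from a state-conditional distribution: normals
(clipped to physiologic domains) for the six numeric variables,
two 4-level probability vectors for each categorical exam finding. TFC
is emitted from its own state-conditional normal (defaults
N(32, 8) / N(52, 12), threshold 40) and thresholded into the binary
label, so the reference label is a noisy proxy of the latent state — as
impedance cardiography is in reality. Outcomes are negative-binomial day
counts built cumulatively (hospital = PICU + extra, PICU = ventilator +
extra), so the nesting holds by construction; state-dependent means
(ventilator 9/12, +6/8 PICU, +3/4 hospital days; dispersion 2.5) put
medians in the 8–20-day range typical of such cohorts. Missingness
channels: a fontanelle-closed rate (0.60 — most PICU patients are past
fontanelle closure), a diuretics/renal-failure rate (0.30) that blanks
urine output, and independent per-variable missingness (0.05).

Default emissions were chosen once so the two latent classes' FAST
distributions resemble the reconstructed cohort's (class means ≈5 and
≈2); they are illustrative, not estimates of any real population. The
generator does **not** model longitudinal within-patient correlation,
age-dependent physiology, informative missingness, or correlated
variables within an encounter — so passing recovery tests demonstrates
the statistical machinery, not the clinical performance of FAST on real
patients. A recovery harness quantifies small-sample behavior: ground
truth operating characteristics from a single large Monte-Carlo cohort
(default 10⁶ encounters via the vectorized scoring path), bias and RMSE
across replicates at the pilot's n = 118.

## Numerical and testing choices

Determinism everywhere: one integer seed fixes cohorts byte-for-byte and
all CV fold assignments. Problem sizes in the test suite (200 CV
repeats, 200 enumeration datasets, 1,000 null simulations, 10⁵-scale
Monte-Carlo oracles) are chosen to keep the full suite under a minute
while leaving Monte-Carlo error well inside the asserted tolerances.
Degenerate inputs fail loudly: single-class data raise a dedicated
error rather than dividing by zero, empty groups and empty tables raise,
and reconstruction rejects non-monotone survivor input or counts that
fail the sum check.

## Known limitations

- The high-TFC threshold that defines the reference label is not part of
  the score; it is an input (`tfc_high`) or a configurable threshold on
  raw TFC values.
- The reconstructed cohort fixes only the score × label margin; any
  statistic needing raw covariates or outcomes cannot be reproduced from
  it and is exercised synthetically.
- Encounters are treated as independent although 32 patients contributed
  118 encounters; no cluster-robust variants are provided.
- The CV interval convention (fold percentiles) is one of several
  defensible readings of an underspecified procedure.
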