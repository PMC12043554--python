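# Methods

## Problem and model

Intrathecal synthesis of immunoglobulins (ISI) — IgG produced inside the
CNS compartment — is a marker of CNS immune activation and supports the
diagnosis of CNS autoimmune disease (CNS-AD). The reference assay,
isoelectric focusing (IEF) of paired CSF/serum for oligoclonal bands, is
slow; nephelometric albumin and IgG measurements are available within
hours. csftoolkit implements the three standard surrogate indexes built
from the paired concentrations:

- **QIgG** = CSF IgG / serum IgG (both reduced to the same unit; the
  quotient is dimensionless). Literature positivity cutoff: > 0.0035.
- **IgG index** = QIgG / QAlb, with QAlb = CSF albumin / serum albumin.
  Normalizing by the albumin quotient corrects the IgG transfer for
  blood–brain-barrier permeability. Cutoff: > 0.7.
- **Reiber value** = serum IgG × (QIgG − QLim), in mg/L: the estimated
  intrathecally produced IgG amount. QLim is the hyperbolic upper
  reference limit of QIgG expected from passive diffusion alone,

      QLim = 0.93 · sqrt(QAlb² + 6·10⁻⁶) − 1.7·10⁻³.

  A positive value (QIgG above the diffusion limit) indicates probable
  synthesis. QAlb inside QLim can be the age-based reference
  (4 + age/15)/1000 (the default here) or the measured albumin quotient
  (the canonical Reiber usage); both are supported via
  `ThresholdConfig.qalb_source` because the study convention is genuinely
  ambiguous, and both paths are tested.

All positivity rules are strict (`>`). Canonical storage units follow
clinical reporting: CSF analytes mg/L, serum analytes g/L; the reader
normalizes from g/L or g/dL on input and all index arithmetic is done on
dimensionless quotients.

The refined (Youden-recalibrated) cutoffs for the neuro-ICU setting are
QIgG > 0.005, IgG index > 0.67 and Reiber value > 5.46 mg/L. The last is
our reading of a threshold stated as an offset above QLim: since the
formula's output is an IgG amount in mg/L while QLim is a quotient of
order 10⁻³, the only dimensionally coherent interpretation is an offset
on the output scale. The cutoff is configurable for users who prefer a
different convention.

## Diagnostic evaluation

`diagnostic_performance` computes Se/Sp/PPV/NPV with Wilson score 95%
intervals by default (Clopper–Pearson available); the Wilson choice
reproduces the reference intervals at percent rounding (e.g. Se 67%
[57–75] for 62/93). Likelihood ratios, Youden's J = Se + Sp − 1, the
cross-product odds ratio with the Woolf log interval, and the Pearson
chi-square test (no Yates correction by default) complete the 2×2
toolbox. Zero denominators yield flagged-undefined (NaN) statistics,
never silent zeros; LR+ at Sp = 1 with Se > 0 is +∞. Zero cells in the
odds ratio get the Haldane–Anscombe 0.5 correction, flagged in the
result, or an explicit ±∞/0 estimate when the correction is disabled.

## ROC, Youden cutoff, grey zone

ROC curves use "score > c" positivity with candidate thresholds at the
observed unique values, anchored at (0,0) and (1,1); the trapezoidal AUC
then equals the Mann–Whitney concordance probability with ties counted
1/2 (asserted to 1e−12 against a brute-force pairwise oracle). The
Youden-optimal cutoff breaks ties toward the smallest threshold (most
sensitive); a best J ≤ 0 is returned with a warning.

The AUC null test (H0: AUC = 0.5) is implemented three ways: exact
enumeration of all C(n, n_pos) label placements over the observed score
multiset (feasibility bound: combined n ≤ 12 by default), a seeded
Monte-Carlo permutation version, and a large-sample normal approximation
from the tie-corrected Mann–Whitney null variance. The exact-permutation
definition is our documented choice of "exact test" for small samples,
not a claim about any particular published implementation.

The grey zone for a marker is [Youden cutoff, first threshold with
LR+ > 10]: values at or below the lower bound read "unlikely", above the
upper bound "likely", in between "intermediate". The upper-bound scan is
restricted to thresholds at or above the lower bound, which guarantees
lower ≤ upper on noisy empirical LR profiles; thresholds with Se = 0 are
skipped (LR+ is 0/0 there), and Sp = 1 with Se > 0 counts as LR+ = ∞.
When no threshold qualifies the upper bound is undefined and the
"likely" label is never emitted — the observed behaviour of all three
indexes for the CNS-AD outcome. For per-patient decision support the
default grey zone is 0.67–0.80 on the IgG index, and the output always
carries fixed caveats (IEF remains the gold standard; a negative index
does not exclude ISI); the tool never encodes treatment advice.

## Association models

Continuous factors are dichotomized at the cohort median with strict
inequalities; a fixed boundary can replace the median (used for the
pre-registered "age < 50 years" and "CSF leukocytes > 4/mm³" factors).
Logistic fits are maximum likelihood (statsmodels `Logit`, Newton/IRLS,
deviance tolerance 1e−8, max 100 iterations) with Wald inference —
matching the stepwise criterion, which operates on per-variable Wald
p-values. Backward elimination removes the largest-p term while p > 0.05
and refits after every removal; separated terms (|β| > 15 or a failed
MLE) are flagged non-converged and removed first, with no penalized
fallback. For a single binary predictor the fitted OR equals the
contingency cross-product OR (tested to 1e−6).

## Synthetic cohort generator

The generator emulates the statistical structure of a neuro-ICU ISI
study population; its defaults are the study conditions, not tuning
knobs: n = 266; ISI prevalence 0.35; CNS-AD prevalence 0.39 with
P(ISI+ | CNS-AD) = 0.53 (the CNS-AD indicator is drawn per patient from
the Bayes-inverted conditionals, validated to lie in [0,1]); age per ISI
class log-normal with medians 38/54 years and spreads fitted to the
interquartile ranges by the ratio ln(q75/q25)/(2·z₀.₇₅), truncated to
[18, 95]; HIV rates 10/93 and 1/173; CSF leukocyte medians 7/2 per mm³;
serum albumin Normal(36, 11) g/L truncated above 10 (the IQR-matched
spread); serum IgG log-normal median 11 g/L (σ = 0.47); measured QAlb
log-normal median 0.00722 (σ = 0.6, a free parameter chosen to span the
observed CSF-albumin range).

The IgG index is sampled directly per ISI class from log-normals whose
locations are calibrated so that P(index > 0.7 | ISI±) equals the target
exceedances 0.57 and 0.06 (μ = ln 0.7 − σ·Φ⁻¹(1 − p); σ = 0.35/0.30 are
free spread parameters). CSF analytes are then back-solved from the
sampled index, QAlb and serum analytes, so recomputing the panel from a
generated record recovers the sampled index to float precision and the
positivity rates are guaranteed by construction. Truncated log-normals
are sampled by inverse CDF with the location root-solved so the
*truncated* median equals the target (plain truncation would shift the
ISI-negative age median by ≈2.4 years).

What the generator does **not** emulate: the dependence of serum
analytes on ISI status (analytes ⊥ ISI given the index), diagnosis-level
granularity below the two analysis groupings, measurement error and
laboratory drift, and the within-patient correlation of repeated
punctures. Passing tests therefore demonstrate correctness of the
statistical machinery under a faithful marginal/conditional structure,
not clinical performance on real ICU data.

`generate_with_effects` replaces the marginal ISI draw with a logistic
model over derived factors (age < 50, HIV, leukocytes > 4, index > 0.7)
for parameter-recovery testing; covariates come from the
prevalence-weighted mixture of the class distributions. Randomness uses
one root `SeedSequence` spawning an independent child stream per field
in a fixed order, so adding a field never perturbs existing fields and
cohorts are byte-identical per seed.

## Numerical choices

- Double precision throughout; internal equality checks at 1e−9
  relative, oracle comparisons at 1e−12 where algebraic identity holds.
- Percentiles: linear interpolation between order statistics.
- All cutoff comparisons strict; boundary values classify negative.
- Degenerate inputs (empty strata, constant factors, single-class
  outcomes, zero denominators) produce flagged results or named errors,
  never silent defaults; single-class outcomes yield a partial analysis
  report with the affected sections flagged.

## Problem sizes

Calibration checks use 10⁶ index draws (exceedance within ±0.002),
distribution-level checks 5·10⁴–10⁵ patients, grey-zone recovery 10⁵
marker values against the analytic Youden point (0.57755) and LR+ = 10
crossing (0.70772) of the two-log-normal model, and stepwise parameter
recovery 10⁴ patients with true ORs 2.5 and 14.2 (recovered within 15%).
These sizes keep the full suite under ten seconds while leaving the
Monte-Carlo error well inside each assertion's tolerance.

## Known limitations

- The exact-permutation AUC test is exponential in n; beyond n = 12 use
  the seeded permutation or normal method.
- Wald inference is first-order; with small cells the Woolf/Wald
  intervals are approximate (no exact logistic regression).
- The grey-zone upper bound is an empirical threshold statistic with
  high variance at small n; at n = 266 it can move by several threshold
  steps between cohorts.
- IgA/IgM Reiber diagrams and free-light-chain (kappa) indexes are out
  of scope.
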