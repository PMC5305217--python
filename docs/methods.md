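# Methods

## Problem and endpoint

`prismor` models the risk that an adult hospital admission experiences at
least one **clinically significant medication error** (ME) — an
unintentional discrepancy with the best possible medication history
(BPMH) or a prescribing error — at any time during the stay.  Individual
MEs are graded on the NCC MERP index, collapsed to four analysis codes:
`C` (no potential harm), `D` (requires monitoring or intervention to
preclude harm), `E+` (potential harm, NCC MERP E and above) and `H`
(actual harm).  The patient-level endpoint is 1 iff the patient has at
least one ME of category D or above; category-C errors are tabulated but
never count as events of interest.  Clinical adjudication is out of
scope: severities arrive as labels.

## Synthetic cohort generator

No patient data ship with the package; every analysis runs on synthetic
cohorts with frozen default marginals:

* **Age** — skew-normal truncated to [18, 105] years with
  `skew=2.071, loc=51.484, scale=26.622`, fitted once so the truncated
  quartiles are 57 / 68 / 80.  Only the quantiles are targeted; the family
  is a package convention.
* **Binary covariates** — independent Bernoulli draws at fixed
  prevalences (male 52.4%, treatment initiated before admission 92.2%,
  BPMH available 54.8%, admission from the emergency room 13.4%, night
  admission 17.8%, surgical admission 25.2%, ...).
* **Drug count** — zero-inflated negative binomial
  (`pi=0.20, mu=3.0, size=1.6`): right-skewed, overall median 1–2, upper
  quartile ~4.  The higher median among event patients is *induced by the
  outcome model*, not built into the generator.
* **ATC class flags** — independent Bernoulli (B01 0.35, J01 0.20,
  N05 0.25, B05 0.30, N02 0.40); plausible hospital prevalences chosen
  once, since only marginals of the real cohort are published.
* **Outcome** — Bernoulli per patient with probability from a
  configurable *true* logistic model; the default is the reference
  coefficient set below.  The drug-count mean was calibrated once by
  simulation (n = 100,000) so the default generator + default model give
  outcome prevalence ≈ 25.9%, then frozen.

Covariates are independent by default (`copula_rho` offers an optional
Gaussian-copula age/drug-count link, off by default): the generator
emulates published *marginals* only.  Passing tests therefore shows the
methods behave correctly under a known data-generating law; it says
nothing about covariate interactions, inter-unit heterogeneity or
length-of-stay dynamics in real hospitals.

A companion fixture generator emits ME-level records (severity mix
D : E+ : H = 315 : 157 : 3, geometric hospitalization day with mode on
day 1), and `reference_me_fixture` pins the exact reference counts
(1,408 admissions, 365 positive, 609 errors of which 475 events of
interest) for arithmetic checks.

## Candidate screening

Univariate tests are deliberately permissive (eligibility at p < 0.50):
Wilcoxon–Mann–Whitney (asymptotic, tie-corrected) for continuous
variables, chi-square **with Yates continuity correction** for binary
ones.  The correction is the default because the published sex-table
p-value (0.119) is reproduced only with it (uncorrected: 0.105).

Drug-class/endpoint co-occurrence is explored with association rules:
antecedents are subsets of ATC flags (size ≤ 2 by default), the
consequent is always the endpoint, thresholds are support ≥ 5% and
confidence ≥ 10%.  With a handful of indicator columns the rule space is
enumerated exhaustively — results are exact, deterministic (support
descending, then lexicographic) and order-invariant.  No lift/leverage
metrics and no frequent-itemset framework: they are not needed at this
scale.

## Model

The development model is a maximum-likelihood logistic regression.  Age
enters through second-degree fractional polynomials: `a = age/100`
raised to a pair of powers from {−2, −1, −0.5, 0, 0.5, 1, 2, 3} (0 =
natural log; a repeated power contributes `a^p` and `a^p·ln a`).  The
pair is chosen by deviance over the 36 FP2 models with the standard
closed test at α = 0.05: any age effect (4 df)? non-linear (3 df)? FP2
over FP1 (2 df)?  Covariates are then pruned by backward elimination on
Wald p-values at a permissive retention threshold (p < 0.30), so weakly
informative predictors are retained for prediction; age terms and any
`force_include` list are exempt.  One FP-selection pass followed by one
elimination pass keeps the procedure deterministic.  Wald (not
likelihood-ratio) p-values are used for speed and because the reference
confidence intervals are Wald-style.

Numerical details: Newton fits via statsmodels with an L-BFGS retry when
Newton oscillates; non-convergence raises; |coefficient| > 50 raises a
separation error naming the term; rank-deficient designs are rejected,
but *constant* columns (common in bootstrap resamples of rare flags) are
silently dropped from that fit, being unidentifiable.

## Internal validation and shrinkage

Discrimination is the c-statistic (ties ½); calibration is the slope of
a logistic recalibration of outcomes on the linear predictor plus the
calibration-in-the-large intercept (slope fixed at 1) — reported as a
pair, matching the convention of quoting corrected intercept and slope
together.  Optimism is estimated by the Harrell bootstrap: the *entire*
recipe (FP selection and elimination included, if configured) is
refitted on each resample; optimism = performance on the resample minus
performance of that replicate model on the original data; corrected =
apparent − mean optimism.  The corrected slope is the uniform shrinkage
factor: `apply_shrinkage` multiplies every slope by it and re-estimates
the intercept by an offset logistic fit, restoring mean predicted
probability = observed prevalence.  Replicates whose refit fails
(quasi-separation in small resamples) are dropped; more than 20%
failures aborts.  The calibration curve uses lowess with span 0.75 plus
a decile table.

## The frozen reference model

The published coefficient set (intercept −3.83; 7.07 and −6.26 on
`(age/100)²` and `(age/100)³`; 0.14 per drug; 1.60 treatment initiated
before admission; −0.64 BPMH available; 0.31 psycholeptics (N05); −0.16
blood substitutes/perfusion solutions (B05); 0.29 surgical; −0.36 prior
hospitalization ≤ 30 days; 0.27 emergency-room admission; −0.18 night
admission; −0.51 outside-institution admission) stores *corrected*
(shrunken) log-odds ratios; the companion odds-ratio column is the
*unshrunken* estimate, recovered as `exp(b/0.926)` — confirmed across
rows (0.14 → 1.16, −0.64 → 0.50, 1.60 → 5.63 vs printed 5.64, a
two-decimal rounding artifact; reconstructed ORs are tested at ±0.01).
Probabilities use the corrected coefficients.  The age effect is
n-shaped with interior maximum at `a* = 2·b₂/(3·|b₃|)` → 75.3 years;
the peak odds ratio uses the unshrunken age coefficients and evaluates
to ≈ 4.23, within the 2% rounding tolerance of the printed 4.26.

## Simulated randomized trials

Each trial: (i) refit a training model on a bootstrap resample — by
default only the coefficients of the fixed reference structure (FP
powers (2,3), all candidate covariates) are re-estimated, which keeps
5,000 trials tractable; full per-replicate re-selection is available via
an `fp_powers="auto"` estimator; (ii) randomize the cohort 1:1; (iii)
the control arm reviews its top `⌈coverage·n⌉` patients by descending
age (or drug count), the model arm by descending training-model
probability, ties broken by a seeded uniform draw; (iv) an event in a
reviewed patient is *intercepted*, in an unreviewed patient *missed*;
(v) arms are compared by a Yates-corrected chi-square on the 2×2
intercepted-vs-not table among treated patients.  Interception rate =
intercepted/treated (so its reciprocal is the NNT versus no review);
missed rate = missed/untreated.  NNT = ceiling of the reciprocal risk
difference (undefined for non-positive differences).  Per-replicate
seeds derive from (master seed, coverage index, replicate index) via a
counter-based `SeedSequence`.

**A leakage caveat found while validating the no-signal null:** when the
training model is refit on a bootstrap of the *same* cohort it is then
evaluated on, ~63% of evaluated patients are in-bag; a rich training
model memorizes some in-bag noise, so even with outcomes independent of
all covariates the model arm shows a spurious positive improvement
(≈ +0.06 at n = 1,408, decaying roughly like √(p/n)).  The null
property — improvement → 0 without signal — holds exactly only when the
training sample is independent of the evaluated outcomes, which is the
situation bootstrap training is meant to emulate; `run_trial` therefore
accepts an optional external `training_cohort`, and the null test uses
one.  Results on signal-bearing cohorts are dominated by true signal and
barely affected.

## Problem sizes used in the checked examples

Marginal-convergence checks use n = 100,000; prevalence and calibration
checks n = 20,000; parameter recovery n = 50,000; the small-overfit
validation cohort n = 400 (~100 events against 16 candidate terms) with
b = 200; the ample-data validation n = 100,000 with a correctly
specified recipe and b = 200; trial-property checks 200 replicates per
coverage on n = 1,408 cohorts.  These sizes were chosen as the smallest
at which the asymptotic statements they check are expected to hold
clearly.

## Known limitations

* Parameter recovery of weak effects is bounded by information, not by
  the implementation: at n = 50,000 the Wald standard errors of the
  rare-flag coefficients (0.02–0.07) exceed a few percent of their
  magnitudes, so individual weak coefficients are recovered only to
  within sampling noise.
* Complete-case only; no penalized fitting; no multiple imputation.
* The trial engine assumes a reviewed ME is always intercepted and that
  intercepting potential harm prevents actual harm.
* No external validation is possible without an independent cohort; the
  bootstrap corrects optimism but not transportability.
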