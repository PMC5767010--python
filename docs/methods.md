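# Methods

`bmaselect` develops and internally validates *center-adjusted biomarker
combinations* for postoperative acute kidney injury (AKI) after cardiac
surgery.  This note records the statistical model, the algorithmic and
numerical choices, what the synthetic cohort generator does and does not
emulate, and the package's known limitations.

## Setting and model

Subjects from C medical centers carry 23 candidate predictors — 22 biomarkers
measured 0–6 h after surgery plus cardiopulmonary bypass (CPB) time — and a
binary primary outcome, sustained mild AKI (a ≥50% serum-creatinine rise
lasting ≥2 days).  Severe AKI (≥100% rise or dialysis) is a secondary outcome
largely nested within the mild cases.  Concentration-scale biomarkers enter
models on the natural-log scale; the signed change in serum creatinine and
CPB time enter untransformed.  We use natural logs throughout (the base only
rescales coefficients).  Postoperative and average serum creatinine are
treated as concentration-scale biomarkers and logged; the change variable can
be negative and is not.

Every candidate model is a logistic regression

    logit P(Y = 1 | center, X) = alpha_c + sum_{j in S} beta_j X_j

where `alpha_c` are center-specific intercepts (encoded as C−1 reference-cell
indicators against the lexicographically first center label) that are
**forced** into every model, and S ranges over the 2^23 = 8,388,608 subsets of
the candidate predictors.

## Bayesian model averaging

Each candidate predictor receives an independent prior inclusion probability
π (default 1/2, making all subsets a priori equally likely: (1/2)^23 ≈
1.19e-7 per model).  The integrated likelihood of each model is approximated
through its BIC — the standard approximation for BMA in generalized linear
models — giving the unnormalized posterior

    P(M_S | data) ∝ exp(−(BIC_S − BIC_min)/2) · π^|S| (1−π)^(p−|S|).

Models whose posterior odds against the best model exceed the Occam's-window
ratio (default 20, configurable; a conventional value) are discarded and the
rest renormalized.  Two combinations are selected: the maximum-posterior
model (ties broken toward fewer predictors, then lexicographic order — the
method's selling point is parsimony) and the median-probability model, the
set of predictors whose posterior variable probability strictly exceeds 1/2.
Forced center columns sit outside the prior and carry probability 1.

### Model-space search

For p ≤ 16 candidates the space is enumerated exhaustively and every model
fit exactly.  For larger p a two-stage screen is used:

1. the full logistic model is fit by IRLS and the likelihood is linearized at
   the solution (working response and weights of the final IRLS step);
2. an exact branch-and-bound search on the resulting weighted least-squares
   problem retains the `nbest` (default 50) lowest-RSS subsets of every size
   0..p, with forced columns projected out beforehand;
3. subsets whose *approximate* BIC (from the linearized RSS) falls outside
   the Occam window widened by a slack of 10 log-odds units are discarded;
4. every surviving subset is refit by exact IRLS and the posterior is built
   from exact BICs only.

The branch-and-bound is exact, not heuristic: a subtree is pruned only when
the RSS of its most saturated completion cannot enter any size list it could
still reach (RSS is monotone under adding predictors).  The widened-window
screen in step 3 is the standard device for making repeated model-averaging
(bootstrap, half-splits) tractable; its slack is far wider than the
quadratic-approximation error observed near the window boundary, and the
test suite checks agreement of the screened path with exhaustive enumeration
on repeated synthetic cohorts.

### Logistic fitting

IRLS (Newton) with convergence declared when the largest coefficient change
falls below 1e-8, capped at 25 iterations.  Two deliberate refinements:

* **Zero-event center cells.**  In center-stratified bootstrap resamples a
  small center frequently draws no events; its forced indicator coefficient
  then drifts to −∞ while the deviance and all candidate coefficients are
  fully converged.  Such fits are accepted (flag `forced_cell_separation`)
  — the drifting parameter is identical across candidate models and its
  likelihood contribution has plateaued — rather than discarding ~30% of
  replicates and biasing the bootstrap.
* **Candidate separation.**  A candidate coefficient that is still moving
  and has exceeded 30 on the log-odds scale marks the fit non-converged;
  non-converged fits are dropped from the posterior with a logged warning.

A batched fitter evaluates all models of a given size simultaneously through
stacked BLAS calls, with per-model convergence tracking; this is what makes
2^10-model enumerations inside 200-replicate bootstraps feasible on one CPU.

## Center-adjusted AUC

Between-center differences in marker distributions and outcome rates
confound the pooled AUC.  The adjusted AUC is a weighted average of
within-center Mann–Whitney AUCs (ties counted 1/2), weighting each usable
center by its number of cases (case-mix standardization); pair-count
weighting (cases × controls) is available as an option because the exact
weighting in the covariate-adjusted ROC literature admits both conventions.
Centers lacking a case or a control carry no within-center information and
are dropped with a warning — routine inside bootstrap resamples.  Scores are
pure biomarker combinations, `sum beta_j X_j`: intercept and center terms are
excluded, which cannot change any within-center ranking.  One consequence,
inherited from the adjustment, is that combinations are *prognostic scores*,
not individual risk predictions; calibration is therefore out of scope.

## Internal validation

Apparent (resubstitution) performance of a data-selected combination is
optimistic through both model-selection and resubstitution bias.  The
bootstrap correction repeats the **entire** selection — including the
model-space search — in every resample: for replicate b, optimism_b is the
selected model's adjusted AUC on the resample minus the same fitted model's
adjusted AUC on the original data; the corrected AUC subtracts the mean
optimism from the apparent AUC (an exact identity in the report).  The 95%
interval is the 2.5th/97.5th percentile interval of the replicate apparent
AUCs, shifted by the mean optimism and clipped to [0, 1].  Resampling is
stratified by center by default so center-adjusted fitting is defined in
every replicate (plain resampling is available).  Replicates selecting the
empty combination score AUC 1/2 on both datasets — an empty combination has
no discrimination, and dropping those replicates would bias the optimism
downward.  Severe AKI is scored inside the same loop using each replicate's
primary-outcome selection.  Diagnostics export, as tables: the posterior of
the full-data selection across replicates, per-replicate posterior variable
probabilities, leave-one-out variable probabilities (capped at n = 2000 by
default), and the original-data AUC of each replicate's selection.

A property worth stating explicitly: **BIC-based BMA is selection-
consistent**, so on signal-free data it usually selects the empty model and
shows *little* apparent optimism (mean apparent adjusted AUC ≈ 0.51–0.52 in
our null simulations, corrected ≈ 0.50).  The dramatic apparent-AUC
inflation classically used to demonstrate selection bias arises under
greedier selectors (forward selection at p-to-enter 0.1), not under
BIC-penalized model averaging.

## Selector comparison

Repeated stratified half-splits (cases and controls each split as evenly as
possible; odd strata give the training half the extra subject) compare four
procedures — BMA-max, BMA-median, forward selection (Wald p-to-enter 0.1, no
removal), univariate selection (per-marker center-adjusted Wald p < 0.1,
kept set refit jointly) — refit on the training half and scored by adjusted
AUC on the held-out half only.  Wald tests are the default (one fit per
candidate per step); a likelihood-ratio criterion is available through
configuration.  The univariate-selected set is refit jointly because a
combination needs a single score.  Typical output on default synthetic
cohorts: comparable held-out AUCs (within a few hundredths) with median
model sizes ordering BMA < forward < univariate — parsimony is the
operative difference between the methods.

## Prognostic enrichment and mortality

Enrolling only subjects above the q-th percentile of a combination score
requires screening 1/(1−q) candidates per enrollee (reported to one decimal)
and raises the untreated event rate among screen-positives (strictly above
the empirical quantile of the analysis cohort).  Two-arm sample sizes for a
treatment cutting event risk by a relative fraction (default 30%, 90% power,
two-sided α = 0.05) use the unpooled-variance normal approximation for two
proportions, per-arm ceiling, equal arms.  Closed-form two-proportion sample
sizes differ by ≲1% across textbook variants; the package therefore treats a
Monte-Carlo power simulation of the z-test (10,000 trials) as the
correctness criterion, and the tests require simulated power within 0.02 of
nominal.

Mortality association: each selected combination, with its AKI-fitted
coefficients frozen, is standardized to unit sample SD and entered in a
logistic model for death at 1 or 3 years with center-specific intercepts;
reported as an odds ratio per SD with a Wald 95% CI, on complete cases for
that combination's own markers.

## Synthetic cohort generator

No subject-level data ship with the package; the generator reproduces the
structure the method must cope with, with defaults frozen to the study
conditions the pipeline targets:

* n = 1219 subjects over six centers with proportions
  (0.09, 0.05, 0.09, 0.44, 0.04, 0.29);
* log-normal biomarkers with per-marker log-scale locations/scales anchored
  to observed cohort medians and IQRs; exchangeable correlation ρ = 0.3 among
  transformed predictors (no documented covariance exists; 0.3 induces
  realistic selection competition);
* per-center additive shifts on the transformed scale (SD 0.3 in units of
  each marker's SD) *and* center-specific outcome intercepts anchored to
  observed per-center event rates — so center adjustment is genuinely needed;
* assay detection floors for EGF (0.90 pg/mL) and VEGF (4.5 pg/mL), attained
  with substantial frequency;
* CPB time as a zero-truncated normal (mean 114.2, SD 59.9 min) and a signed
  change-in-creatinine variable (mean ≈ 0, SD 0.156 mg/dL);
* a sparse true signal — log NT-proBNP (β = 0.60), log h-FABP (β = 1.30),
  change in creatinine (β = 4.5 per mg/dL), i.e. ~0.7–0.8 SD of log-odds
  each — sized by a power calculation so the panel is decisively recoverable
  at the cohort's ~100 events, mirroring the strong markers such cohorts
  report; the mild-AKI intercept is calibrated by root-finding to a 9.6%
  expected prevalence on each draw;
* severe AKI thresholds a *shared* latent severity (the mild-AKI uniform
  plus N(0, 0.95) jitter, intercept calibrated to 4.9% prevalence), making
  ~92% of severe cases also mild cases rather than an independent draw;
* death at 1 and 3 years (4.4% and 9.5%) with log-odds slope 0.5 per SD of
  the latent risk score;
* missingness is per-predictor MCAR at 0.0132, chosen so the expected
  complete-case fraction on all 23 predictors is 899/1219 (the observed
  diagnostic — similar prevalence among subjects with and without missing
  data — is consistent with MCAR).

What the generator does **not** emulate: exact marginal medians/IQRs of
every marker (only skew, floors, shifts and prevalences are targeted),
block-structured missingness (real assays fail in panels, so real complete-
case counts differ between marker subsets more than MCAR predicts),
measurement error, or any treatment effects.  Passing tests therefore
demonstrate that the *procedures* behave correctly under realistic
multicenter structure — not that any particular biomarker panel is
clinically validated.

## Problem sizes used in the checks

The automated checks run the oracle-equivalence comparison at p = 10 on 50
cohorts of n = 900; the null-data optimism study at p = 10, n = 900 with
B = 200 replicates over 20 cohorts; panel recovery on 50 full default
cohorts (p = 23); the half-split comparison pooled over 4 cohorts × 20
splits; and 10,000-trial power simulations.  The acceptance script defaults
to B = 200 replicates and 40 half-splits on one default cohort.  These sizes
give Monte-Carlo error comfortably inside the asserted tolerances while
keeping a full run at desk scale.

## Known limitations

* The BIC approximation ignores prior scale on coefficients; exact
  integrated likelihoods (or MCMC over model space) are out of scope.
* The Occam-window ratio, `nbest`, and the screening slack are conventions,
  not estimated quantities; all are configurable.
* Center-adjusted combinations do not produce individual predicted risks;
  calibration and external validation are explicitly downstream work.
* The mortality analysis is logistic at fixed horizons (outcomes observed
  without censoring); no time-to-event modelling.
* Multiple imputation for missing predictors is not implemented; analyses
  are complete-case by design.
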