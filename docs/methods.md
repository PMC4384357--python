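# Methods

## Model and estimation

The survival model throughout is the Cox proportional-hazards model
λ(t|Z) = λ₀(t)·e^{Zβ} for right-censored death times, with independent
censoring assumed conditional on the modelled covariates. β is estimated by
Newton–Raphson maximization of the partial likelihood with the **Breslow
approximation for tied event times**; the same convention is used in the
Breslow estimator of the cumulative baseline hazard,
Λ̂₀(t) = Σ_{t_j ≤ t} d_j / Σ_{i at risk} e^{Z_i β̂}, so that predicted
survival π̂(t|Z) = exp(−Λ̂₀(t) e^{Zβ̂}) is internally consistent. One tie
convention everywhere keeps the fitted likelihood, the baseline and the
predictions mutually coherent; day-scale data make heavy ties routine.

Numerical conventions: convergence at score sup-norm < 1e−9 (well inside
the 1e−8 contract), monotone step-halving, and divergence detection —
a standardized coefficient exceeding 15 (|β·sd| > 15, i.e. a per-SD hazard
ratio above e¹⁵) is treated as monotone likelihood (separation in the risk
sets) and raised as a convergence error rather than returned. Standard
errors come from the observed information; Wald p-values are reported for
unpenalized fits only.

### Penalized fits

L1-family fits maximize logPL(β) − λ Σⱼ wⱼ|βⱼ| on internally standardized
covariates (unit variance), via proximal-Newton: cyclic coordinate descent
on the local quadratic model of the partial likelihood, which yields exact
zeros; coefficients are reported on the original scale. The log partial
likelihood is **unscaled** (not divided by n), matching the tool's λ grid
{0.01, 0.1, 1, 10, 100} in which larger λ means a sparser model.

- lasso: wⱼ = 1.
- adaptive lasso: wⱼ = 1/max(|β̃ⱼ|, 1e−4) from a lightly ridge-penalized
  initial fit (ridge λ = 0.01 on the standardized scale), then **normalized
  to mean 1** so a given λ is commensurate between lasso and adaptive
  lasso; without the normalization the two penalties are on incomparable
  scales and the defining property — large coefficients shrunk less than
  under the lasso at the same λ — is not observable.
- SCAD: local linear approximation (three iterations of weighted lasso,
  warm-started at the lasso solution) with derivative weights
  p′_μ(|βⱼ|)/μ, a = 3.7, where μ = λ/n places the SCAD knots on the
  coefficient scale: coefficients below μ see the lasso slope, coefficients
  above aμ are unpenalized, giving SCAD its near-unbiasedness for strong
  effects.

`refit_unpenalized=True` turns any penalized family into pure selection:
the selected set is refitted by ordinary Cox (no shrinkage); an empty
selection yields the null model (linear predictor 0, Nelson–Aalen
baseline).

### Backward AIC and fractional polynomials

Backward elimination minimizes AIC = −2 logPL + 2p, dropping one covariate
at a time while the AIC decreases; it can end in the null model. Note the
implied retention probability of a single pure-noise covariate is
P(χ²₁ > 2) ≈ 0.157 — the test suite asserts the corresponding ~84% drop
rate, not a higher one.

Fractional polynomials use the conventional 8-power set
{−2, −1, −0.5, 0, 0.5, 1, 2, 3}, with x⁰ ≡ ln x and the repeated-power rule
(p, p) → (x^p, x^p ln x). Covariates are shifted so the minimum maps to a
tenth of the observed range and rescaled by the median of the shifted
values before transforming; both constants are frozen from the training
data and reapplied to new data. This conditioning matters: with an origin
shift that leaves values near zero, the negative powers explode and the
inner fits fail. MFP runs the per-covariate closed test — best-FP2 vs
exclusion at level `select` (χ², 4 df), best-FP2 vs linear at level `α`
(3 df), best-FP2 vs best-FP1 at `α` (2 df); binary covariates face only a
1-df inclusion test — cycling over covariates until forms stabilize or five
cycles. Failed candidate fits score −∞ (they lose), never abort the
procedure. The `select` × `α` grid ({0.05, 0.10, 0.15} × {0.05, …, 0.4}) is
exposed in full and models are named by the pair, since a flat 1–15 index
does not identify the combination.

## Resampling

Strategy **A** (patient-level, outcome-stratified): per repetition, events
and non-events are shuffled separately and dealt round-robin into k folds
(fold order re-permuted each repetition), so per-fold event counts differ by
at most one — the operational form of "equal event proportion per fold".
Strategy **B** (batch-level): batches are partitioned into k groups,
balancing **patient counts** greedily (largest batch into the currently
smallest fold, ties broken by the repetition's shuffled order); event
proportions are deliberately *not* balanced — their imbalance is what lets
batch-level folds expose batch-driven optimism. The greedy balancing rule is
this package's choice; nothing in the problem fixes how unequal batch sizes
should be split.

Inside every training fold the entire strategy — selection, functional
form, fitting, shrinkage — is re-run; test-fold patients only receive
predictions from models that never saw them. ΔCt normalization is *not*
re-run inside folds: it is a sample-by-sample operation and cannot leak
across patients. Training folds with zero events are skipped and logged,
never imputed; aggregation ignores them. Defaults k = 5, n_rep = 20.

## Performance indicators

- **Brier score** BS(t): Graf's IPCW estimate. Deaths by t contribute
  π̂²/Ĝ(T⁻), patients alive past t contribute (1−π̂)²/Ĝ(t), patients
  censored before t contribute 0. Ĝ is the reverse Kaplan–Meier of the
  censoring distribution **estimated on the set being scored** (fold for
  averaged, pooled repetition set for pooled), with deaths taken to precede
  censorings at tied times. Ĝ = 0 at the needed point yields a missing
  value with a warning — no truncation rule is invented.
- **C-index** (Harrell): over pairs whose smaller time is an event time and
  whose times differ, the fraction where the earlier death has the larger
  marker; tied markers score 0.5; tied event times make a pair unusable.
- **Cumulative/dynamic sensitivity/specificity**: Bayes inversion with
  Kaplan–Meier survival within the two marker strata,
  sens(c;t) = (1 − Ŝ(t|M>c))·P̂(M>c)/(1 − Ŝ(t)), analogously for
  specificity, clipped to [0,1]. This variant is deterministic and
  parameter-free and reduces exactly to empirical fractions without
  censoring. Known limitation: under censoring it can be *locally
  non-monotone* in the threshold (observed wiggles ~0.01); no smoothing or
  isotonization is applied. AUC(t) integrates the ROC path in **threshold
  order** (trapezoid); ordering by false-positive rate instead lets
  floating-point jitter cut staircase corners.
- **Pooling vs averaging**: pooled concatenates a repetition's test-fold
  scores, computes once, then averages over repetitions; averaged computes
  per fold first. Linear predictors are comparable across folds, so pooling
  them is safe under either resampling strategy; pooled *predicted-survival*
  scores under strategy B are biased downward when batches are
  outcome-unbalanced (fold-specific baselines) — the package computes them
  on request but emits an explicit bias warning.
- **Optimism / validation surprise**: apparent (training-fold) minus
  test-fold indicator, averaged over folds and repetitions. At the study
  level the package compares the *mean* cross-validated AUC with the
  independent-test AUC over simulation replicates — a bias comparison;
  per-replicate absolute deviations are dominated by Monte-Carlo variance at
  n ≈ 156 and say little about the systematic surprise.
- **Calibration**: patients grouped by predicted-survival quantiles; per
  group, mean π̂(t) vs the group's KM at t (KM at last follow-up, flagged,
  when a group's follow-up ends before t).

## Selection diagnostics

The Kuncheva index (r − s²/N)/(s − s²/N) is computed only when all fits
selected the same number of covariates (it is undefined otherwise);
selection frequencies are always reported. The Martingale-residual check
averages each patient's residuals over all training folds containing them
and summarizes the association with an omitted covariate by a Spearman rank
correlation (robust, parameter-free) plus a lowess smooth (frac = 0.6)
exported for plotting only — the smooth is descriptive, never a test. The
logistic sensitivity/specificity analysis uses as default cutoffs the inner
deciles (10%–90%) of the pooled linear predictor, restricts to patients with
known vital status at t, and reports raw p-values and the proportion below
0.05 per cutoff with no multiplicity correction — an indicator, not a formal
test; cells with a single-class response or separation are reported missing
with the reason.

## Validation

The Schoenfeld event count uses a one-sided α as written (pass α/2 for a
two-sided design). Bootstrap confidence intervals resample **patients** of
the test set with replacement (B = 1000 default, percentile method, no
BCa), never refitting the model; resamples with undefined indicators are
skipped and counted, and the interval is flagged unstable above 20%
skipped. A batch-level bootstrap is available as an option for users who
regard the plate as the sampling unit.

## Synthetic cohorts: what they emulate, and what they do not

The generator draws patients in near-equal batches (defaults: 156 train /
95 test over 14 + 9 batches), gene covariates as biological signal (standard
normal, ΔCt scale) plus an additive batch shift shared within a batch
(SD `batch_sd`, default 0.5 Ct, scaled by per-gene loadings U(0.5, 1.5))
plus measurement noise (SD 0.3 Ct), and batch-free clinical covariates.
Event times follow a Weibull-baseline proportional-hazards law (shape 1.2,
covering the exponential at shape 1) driven by the *biological* signal — the
technical shift perturbs the measurement, not the hazard — plus a per-batch
normal log-frailty whose SD (`batch_event_dispersion`, default 0.5) creates
the batch-to-batch outcome imbalance; at the defaults the interquartile
range of per-batch event proportions averages ≈ [0.17, 0.35]. The baseline
scale is calibrated by root finding so the expected event proportion at the
day-14 administrative censoring horizon equals `target_event_rate`
(default 0.28); optional uniform early dropout is off by default. Default
effect sizes β = (0.5, −0.45, 0.4, 0, 0, 0, 0.45, 0.35, 0) give three
informative genes and two informative clinical covariates with day-7
oracle AUCs around 0.7–0.8 — a realistic signal strength for a viable
prognostic panel.

`batch_sd` and `batch_event_dispersion` have no empirical anchor — the
real between-batch technical variance of such assays is not public — and
are documented modelling choices. The generator does not simulate
amplification curves or crossing-point calling (generation starts at the Ct
value), non-additive batch effects, covariate-dependent censoring, or
batch–covariate confounding beyond the shift/frailty mechanism; passing
tests therefore demonstrate the machinery's behavior under a plausible
batch model, not performance guarantees on any particular clinical assay.

## Problem sizes

Simulation-backed checks use cohorts of 150–2000 patients and 20–50
replicates per property: 50 replicates for penalization orderings, the
no-signal strategy-A-vs-B comparison and the diagnostic calibration guards;
30 for the validation-surprise bias comparison; 20 for optimism ordering;
n = 1000 for parameter recovery and n = 2000 for distributional identities.
The "strong batch effect" condition is batch_sd = 3.0 Ct with frailty SD
1.0 — technical variability clearly dominating the biological signal. These
sizes keep every property estimable with comfortable Monte-Carlo margins
while the full suite stays quick to run.

## Known limitations

No time-varying covariates, left truncation, competing risks, elastic-net
or group penalties, 0.632+ bootstrap, or missing-data handling; the
proportional-hazards assumption is taken as given (the day-14 censoring
horizon of the emulated design is itself a PH-protection device). Strategy
B's estimates are noisier than strategy A's (unequal fold event counts) —
its advantage is bias, not variance. The Kuncheva index is silent for
selection methods with varying set sizes; only frequencies are reported
there.
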