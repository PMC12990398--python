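# Methods

This note documents the models behind `ppdnet`, the defaults and why
they were chosen, the numerical choices, and what the synthetic-data
validation does and does not demonstrate.

## Censored-normal group-based trajectory model

Each subject belongs to one of K latent groups; group j has a
polynomial mean trajectory μ_j(t) = Σ_d β_jd t^d over the wave codes
t = 0, 1, 2, 3 (the four assessments treated as equally spaced ordinal
occasions — the instrument defines no metric time scale).  The outcome
is normal around μ_j(t) with a shared residual SD σ and is censored to
the instrument range [0, 21]: observations at a bound contribute the
corresponding normal tail probability, Φ((L−μ)/σ) at the floor and
1−Φ((U−μ)/σ) at the ceiling.  Within-group variation in the growth
parameters is fixed at zero, so all heterogeneity is between groups.
Subjects enter the likelihood with their observed waves only
(full-information maximum likelihood); no listwise deletion.

**Fitting.**  EM with an exact E-step and a quasi-Newton (L-BFGS-B)
M-step on the censored-normal weighted log-likelihood with analytic
gradients.  Multi-start: quantile partitions of (jittered) subject
mean scores alternating with random partitions; the best final
log-likelihood wins.  Convergence is declared when the log-likelihood
gain per iteration falls below `tol` (1e-8 for final fits; the model-
selection path uses 1e-6 and an iteration cap of 120, since candidate
comparisons differ by far more than the resulting log-likelihood
error).  The log-likelihood trace is stored on every fit, and the test
suite asserts its monotonicity.  Groups are canonically relabelled by
fitted baseline mean, descending, so "group 0" is the worst-sleep
group on every run.

**Parameter count.**  k = Σ_j (d_j + 1) trajectory coefficients + 1
shared residual SD + (K − 1) membership logits.  All criteria are
reported on the log-likelihood scale — AIC = LL − k,
BIC_N = LL − (k/2)·ln N for N subjects or N observations — so "lower
absolute value / closest to zero" is better, matching the reporting
convention of the trajectory-modelling literature this package
follows.  Normalized entropy is 1 − Σ_i Σ_j (−p_ij ln p_ij)/(N ln K).

**Adequacy diagnostics.**  AvePP_j is the mean posterior probability
among subjects assigned to group j by the maximum-probability rule
(ties to the lower index); OCC_j = [AvePP_j/(1−AvePP_j)] / [π_j/(1−π_j)]
computed from unrounded quantities; |EP − P| compares the estimated
group probability with the assigned share.

**Order selection.**  Two backward-pruning procedures are provided.
`wald_prune_orders` drops each group's highest-order term while its
Wald p-value (observed-information standard errors, obtained by
central differences of the analytic mixture score) is ≥ 0.05,
refitting after every drop, with a likelihood-ratio fallback when the
information matrix is singular.  `select_model` defaults to pruning by
subject-count BIC instead: a term is dropped whenever the reduced
model's BIC is at least as good.  The BIC route is the default because
α = 0.05 testing falsely retains a noise term roughly 5% of the time
per test, which compounds over groups and orders; BIC's implicit
threshold (a log-likelihood gain of ½·ln N per parameter) keeps false
retention near 1.5% per term and is the standard information-criterion
recommendation for trajectory-shape selection.  Candidate models over
K = 2..4 are then screened by the 5% minimum group share and ranked by
subject-count BIC, with near-ties (within 1e-6) resolved toward higher
entropy; every decision is recorded in a human-readable rule trace.

## Association statistics

The Bayes-factor t-test is the two-sample Jeffreys–Zellner–Siow test:
Cauchy(0, r) prior on the standardized group difference with
r = √2/2 (the common software default; configurable), Jeffreys prior
on the variance.  BF₁₀ is computed by adaptive quadrature over the
variance-mixing parameter g (inverse-gamma(1/2, r²/2)), on a [0, 1]
transform of the half-line.  The test suite checks it against an
independent quadrature on the effect-size scale (noncentral-t
likelihood against the Cauchy prior) to 1e-6 relative error, and
against `pingouin`'s implementation.

Logistic and linear models go through statsmodels (`Logit`, `OLS`).
The depression flag is total ≥ 13.  Odds-ratio intervals are Wald on
the log-odds scale, exponentiated.  Complete separation raises an
error rather than returning a clipped estimate.  Covariate encoding:
age continuous; education as two indicator columns (three levels);
the remaining demographics binary.  Income and education are treated
as categorical, not ordinal.  The coefficient-difference test is
z = (B₁ − B₂)/√(SE₁² + SE₂²) with a two-sided normal p.

## eLasso Ising networks

Items scored 0–3 are binarized (0 ↦ absent, 1–3 ↦ present).  Each
node is regressed on the other p − 1 by L1-penalized logistic
regression over a descending penalty path: 100 log-spaced values from
λ_max (the maximum absolute score covariance, with a 1e-6 relative
headroom so the first path point is exactly the empty model) down to
0.01·λ_max.  Per node, λ minimizes EBIC = −2ℓ + s·ln n +
2γ·s·ln(p−1) with s the number of nonzero coefficients and γ = 0.25.
The AND rule keeps an edge only when both directed coefficients are
nonzero, with their mean as the weight (OR rule available).
Coefficients below 1e-6 in magnitude are treated as exact zeros
before EBIC counting — they are solver dust, not edges.  Constant
columns are dropped with a warning; their thresholds come from the
clipped marginal rate and they carry no edges.

The path solver is a proximal-Newton coordinate-descent kernel
(numba): each outer step solves a penalized quadratic model built from
the exact gradient plus a lazily refreshed weighted-Gram curvature,
with a guaranteed-descent fallback using the global logistic curvature
bound 0.25.  Because the fixed point is determined by the exact
gradient, the lazy curvature affects speed only.  The stopping rule is
a penalized-objective improvement below 1e-7 together with a
coefficient-step guard; the resulting coefficient accuracy is about
1e-4–1e-5 against a tightly converged reference (cross-checked against
scikit-learn's saga solver in the tests), which is far below the scale
of any reported edge weight or EBIC difference.

Strength centrality is the sum of absolute incident weights (absolute,
not signed — the standard convention); the maximal-strength node is
reported as the core symptom.

**Stability.**  Case-dropping bootstrap over drop proportions 10%–70%
in 10% steps, 250 subsets per proportion by default, Pearson
correlation between subset and full-sample strengths (Spearman behind
a flag).  Subset fits with no edges have an undefined correlation and
count as failures.  The CS coefficient is the largest grid proportion
q such that P(correlation ≥ 0.7) ≥ 0.95 for all proportions up to q.

**Comparison.**  The permutation network-comparison test pools the
two groups' rows, permutes group membership at fixed group sizes, and
re-estimates both networks per permutation.  Statistics: M, the
maximum absolute edge difference, and S, the absolute global-strength
difference.  p = (1 + #{perm ≥ observed})/(1 + n_perm), the
add-one-corrected estimator, which is a valid p-value for any
statistic under exchangeability.  Default 1000 permutations.  The
calibration study in the test suite runs 200 replicates of 200
permutations with 120 cases per group and a 30-point penalty grid
inside the refits; permutation exactness holds for any fixed
statistic, so the coarser grid tests the same machinery at a fraction
of the cost (a pilot at the default grid gave indistinguishable
rejection rates).

## Gibbs sampling and simulated interventions

The sampler runs one independent chain per retained vector: a uniform
random start followed by `sweeps` (default 100) full sequential
passes, node i resampled from logistic(τ_i + Σ_j ω_ij x_j).  All
chains advance in lockstep, so the whole sampler is a few vectorized
operations per node update; retained vectors are independent draws up
to burn-in error (the suite checks that doubling the sweeps leaves the
expected sum unchanged within Monte-Carlo error, and that the
two-node distribution matches exact enumeration).

An intervention on node i shifts τ_i by ±c·SD(τ) with c = 2, the
population SD taken over the *reference* network's thresholds (and
carried through metadata, so an aggravating shift followed by the
alleviating shift restores the original network exactly).  Under the
0/1 coding a larger threshold means a higher presence probability, so
aggravating = +shift.  If all thresholds are equal the magnitude is
zero and a warning is raised — no silent fallback.  Effects are the
change in the expected number of present symptoms over 10,000 samples,
with common random numbers across conditions so condition contrasts
are paired.  Aggravating interventions rank by descending change,
alleviating by ascending, ties toward the original item order.  The
expected sum is reported once per network; panels that would share a
network share its baseline.

## Synthetic cohorts

Defaults reproduce the study conditions: n = 372 subjects, four waves,
group proportions 58.6%/41.4%, linear trajectories — "stably good"
3.5 + 0.5t, "increasingly poor" 6.5 + 1.0t — with shared residual SD
1.5, so the groups are three residual SDs apart at the final wave;
scores censored to [0, 21] (continuous by default; an option rounds to
integers as a realism stressor); follow-up waves missing completely at
random (baseline always observed, mirroring a
completed-baseline-at-least design).  Symptom items are drawn from
chain-graph Ising distributions (couplings 0.8) with uniformly higher
thresholds in the poor-sleep group; present symptoms get a uniform
severity in {1, 2, 3}.  Covariates default to the marginal rates of a
middle-class urban Chinese perinatal cohort (mean age 29.7 ± 4.1,
72.9% employed, 89.3% planned pregnancies, and so on).

What the generator does *not* emulate: informative dropout (missing-
ness is MCAR), the instrument's seven component subscores, item-level
measurement error, and the real cohort's exact symptom-burden contrast
— the default group difference in totals is larger than the published
one, so synthetic-cohort association estimates (odds ratio, Bayes
factor) are systematically stronger than the real-data values, which
are in any case not a reproduction target because the cohort is not
deposited.  Passing tests therefore demonstrate estimator correctness
under the stated generating model, not agreement with the original
data.

## Problem sizes and numerical choices

Simulation studies in the test suite are sized to run comfortably on a
single core: 20 replicate cohorts for trajectory recovery
(select_model with 3 starts per fit), 20 seeds for network recovery
and specificity at n = 2000, a 200 × 200-permutation comparison-test
calibration at 120 cases per group, and 25,000–50,000 Gibbs samples
for sampler checks.  Monte-Carlo tolerances are stated as multiples of
the binomial standard error.  Degenerate inputs are handled loudly:
empty groups are flagged, not dropped; separated logistic fits raise;
constant items warn; posterior underflow is prevented with
log-sum-exp throughout.

## Known limitations

- Per-group residual SDs are implemented but the shared-SD default is
  the only configuration exercised by the validation suite.
- The EM ridge between equivalent overparameterized solutions (K
  larger than the true number of groups) converges slowly; selection
  runs cap iterations, which is harmless for model comparison but
  means such fits can carry a `converged=False` flag.
- The Wald pruning route reproduces the sequential-testing procedure
  faithfully, including its multiple-testing behaviour; it is not the
  default for shape selection for exactly that reason.
- The intervention simulation perturbs thresholds only; edge
  (coupling) interventions are out of scope.
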