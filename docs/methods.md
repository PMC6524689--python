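# Methods

## The generative model

The simulator implements the independent horse-race model of response
inhibition. On every trial a go process races toward a response; on stop
trials a stop process starts at the stop-signal delay (SSD) and, if it
finishes first, cancels the response:

* **Go finishing times** are ex-Gaussian, `Normal(mu, sigma) + Exp(tau)`,
  the standard parametric family for empirical RT distributions (unimodal,
  right-skewed). Draws are floored at 1 ms.
* **Stop latencies** are `Normal(ssrt_mean, ssrt_sd)` truncated at zero by
  rejection sampling. A response is emitted on a stop trial iff the go
  finishing time is below `ssd + stop latency` (stochastic independence of
  the two runners is assumed — the classical tractable case).
* **Strategic slowing**: participants slow their go responses once stop
  signals can occur. This is modelled multiplicatively on the ex-Gaussian
  location parameters (mu and tau scale by `slowing_factor`, sigma does
  not), so mean RT scales by the factor, matching a slowing *index* defined
  as a ratio of mean RTs. Slowing applies in the stop-signal block only.
* **Lapses**: a trial is omitted (no response, even on stop trials) with
  probability `omission_rate`; a given response lands on the wrong side with
  probability `choice_error_rate`.

The task structure reproduces the administered design: a 48-trial two-choice
block (no slowing), then 288 trials with exactly 25% stop trials in
uniformly shuffled positions, SSD starting at 100 ms and tracked
one-up/one-down in 50 ms steps. The staircase is clipped to [0, 900] ms;
the task itself states no bounds, and these prevent degenerate excursions
without ever binding at realistic parameter values. Because the initial SSD
(100 ms) sits below the tracking equilibrium, early stop trials are easy;
the observed per-session stop-trial response rate therefore sits slightly
below 0.5 (~0.48 at study conditions) while the long-run rate converges to
0.50 — both are asserted in the tests at their own scales.

### Cohort generation

`simulate_cohort` derives one child seed per participant from the master
seed via `numpy.random.SeedSequence`, making cohorts reproducible and
participants independent under reordering. Between-subject variability
enters as Normal offsets on the go location and the stop-latency mean,
correlated across effectors (`cross_effector_rho`, default 0.6) so that
individual differences produce the hand-foot SSRT correlation seen in such
cohorts.

`study_cohort_spec()` freezes the study conditions: group stop-latency means
229/262 ms (hands) and 260/277 ms (feet) for experts/controls; go
parameters giving mean two-choice RTs of ~408 ms (hands) and ~424 ms (feet)
with no group difference; slowing factors 1.298 and 1.239; 2% choice errors
and 1% omissions (typical healthy-adult rates); between-subject SDs of
30 ms (go location) and 32 ms (stop latency), chosen so that *observed*
group SDs — which add estimation noise on top — land near the published
33–42 ms.

What the generator does **not** emulate: between-subject variation in the
slowing factor (so the simulated slowing-index SD, ~0.03, is far below the
empirically observed ~0.26), trigger failures of the stop process, context
dependence of SSRT, sequential effects (post-stop slowing), or fatigue.
Passing tests therefore certify the estimator and inference machinery under
the race model's assumptions, not the full richness of human data.

## SSRT estimation

The integration method ranks the no-signal RTs of the stop-signal block
ascending and takes the RT at rank `ceil(basis × p)` (floored at 1), where
`p` is the fraction of stop trials with a response; SSRT is that RT minus
the mean SSD over all stop trials. Numerical choices:

* the product `basis × p` is rounded to nine decimals before the ceiling so
  that decimal inputs such as 288 × 0.6 = 172.8 are not pushed across an
  integer boundary by binary float error (the rank must be 173, not 174);
* go-trial **omissions** are assigned the maximum observed go RT before
  ranking (the standard correction; omitting them would bias the quantile);
* **choice errors** stay in the ranking by default (switchable);
* ties need no breaking: a stable ascending sort is indexed directly;
* if the rank exceeds the number of rankable RTs (possible under the
  total-trials basis at high `p`), the maximum RT is used and the estimate
  is flagged `rank_clamped`; `p = 0` yields rank 1 and a `low_p_warning`.

Two rank bases are provided. `total_trials` divides by all stop-signal-block
trials (288), mirroring the arithmetic of the original analysis and its
worked example; under tracking at p ≈ 0.5 it reads the go distribution near
its 2/3 quantile and so overestimates SSRT by roughly 35 ms at study
conditions. `go_trials` (the consensus-standard basis, default for cohort
summaries) reads the median and recovers the generative stop latency with a
small negative bias of about 7–9 ms at 288 trials — a known property of
integration-style estimators under staircase tracking with skewed RTs,
within the ±10 ms band the recovery tests assert. Group *differences* are
insensitive to the basis because the bias is common to both groups.

Two-choice RT means/SDs (and the no-signal RT mean used in the slowing
index) are computed over correct responses only, matching how such data are
conventionally summarized and plotted.

## Inference layer

* **Cohen's d** uses the pooled SD; its CI inverts the noncentral-*t*
  distribution of `t = d·sqrt(n1 n2 / (n1+n2))` (bounds via
  `scipy.special.nctdtrinc`, verified to reproduce the requested tail
  probabilities to 1e-6, with a Brent root-finding fallback).
* **t-tests** are Student (pooled-variance); the directional one-tailed
  variant reports the upper tail. Pooled rather than Welch matches both the
  df = 58 reported with n = 30/30 and the d/CI arithmetic.
* **Mixed ANOVA** implements the classical split-plot decomposition in
  closed form, vectorized across replicate axes so that 10⁴-dataset
  calibration simulations run in well under a second. The between effect is
  tested against subjects-within-groups, the within and interaction effects
  against the measure × subject error; partial η² = SS_eff/(SS_eff+SS_err).
  An effect whose SS is zero up to float noise reports F = 0 even when the
  error stratum is itself degenerate (exactly additive data). Marginal
  means are group-size weighted; the intended use is (near-)balanced
  designs, and the implementation is cross-checked against an independent
  library oracle in the tests.
* **Bayes factors** place a Cauchy(location, scale) prior on the
  standardized effect size, truncated and renormalized to a half-line for
  directional hypotheses. BF₁₀ is the prior-marginalized noncentral-*t*
  likelihood over the central-*t* likelihood, integrated by adaptive
  quadrature (absolute tolerance 1e-12, relative 1e-10, integration split
  at the prior center; the quadrature's error estimate is propagated to the
  BF scale). A Monte-Carlo prior-simulation oracle agrees within 1% across
  a t grid in the tests. No multiple-testing correction is applied anywhere:
  the mirrored analysis reports planned one-tailed contrasts.
* **Correlations** use the Fisher-*z* transform with SE 1/sqrt(n−3); the
  one-sided interval reports a lower bound with the upper bound pinned at 1.
  Two independent correlations are compared on the z scale.
* **Sample-size planning** for the between-groups effect of a
  between-within design uses the noncentral-F approximation with
  λ = f²·N·m/(1 + (m−1)ρ). The repeated-measures correlation ρ is an
  explicit argument because published sample-size claims of this kind are
  not reproducible without it; with the conventional ρ = 0.5, f = 0.33,
  α = 0.05 and power 0.80 the routine returns N = 58, and its formula is
  validated against a direct simulation of the design (±0.03).

## Reproduction surface and known limitations

The deterministic reproduction layer (`stopsig.reference`) recomputes every
statistic that follows from the published group summaries. Cohort-level
quantities that require raw trial data (per-trial RT distributions, the
two-choice Bayesian comparisons, the exact slowing-table values) are outside
that surface; the simulator stands in for them at the distribution level
only. One genuine discrepancy is documented by the acceptance tests rather
than hidden: the published feet-condition Bayes factors are jointly
consistent only with t ≈ 1.62, while the published feet group summaries
imply t ≈ 1.67, so recomputing the feet Bayes factors from the summaries
yields values ~7% above the published ones (1.56 vs 1.46 and 1.76 vs 1.64);
the hands Bayes factors reproduce to four significant figures.

Problem sizes used by the statistical guarantee tests: 10⁴ stop trials for
staircase convergence, 500 sessions of 288 trials for estimator recovery,
10⁴ null datasets for ANOVA calibration, 10⁶ Monte-Carlo draws per grid
point for the Bayes-factor oracle, and 10⁴ replicates for CI coverage —
sizes at which Monte-Carlo error is several times smaller than each
asserted tolerance.
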