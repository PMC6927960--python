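# Methods

This note documents the generative model, the statistical machinery, the
calibration of the synthetic cohorts, and the numerical choices made
where the design was genuinely open.

## Task environment

A session is `n_trials` (default 200) two-stage trials. The transition
structure is fixed and known to the agents: first-stage option 0 leads to
second-stage state 0 with probability `p_common` (default 0.70) and to
state 1 otherwise; option 1 mirrors it. Each of the four second-stage
options pays a unit reward with a probability that performs an
independent Gaussian random walk (increment SD `walk_sd` = 0.025) across
trials.

Open choices the task description leaves unstated, and how they were
fixed:

* **Walk bounds and boundary behavior.** Bounds [0.25, 0.75] with
  reflection (p′ = 2·bound − p when a raw step crosses a bound) follow
  the canonical laboratory implementation of this task; they prevent
  degenerate always/never-rewarded options and keep the stationary
  distribution spread across the interval rather than piled at the
  edges. Both bounds are configurable.
* **Walk initialization** is uniform within the bounds — agnostic, so
  early learning is not biased toward any option.
* **The four walks are mutually independent**, the simplest reading of
  "each option's probability drifts"; independence is verified by a
  property test on increment correlations.
* **One walk step per trial**, applied after reward delivery, including
  on trials the agent misses: the drift models the environment, not the
  agent.
* **Random-number contract.** Every subject owns five named substreams
  (walks, transitions, rewards, choices, RTs) spawned from the master
  seed, so any single component can be replayed bit-identically without
  re-running the others.

## Agents

Agents are data generators, not estimators — nothing in the package fits
learner parameters to behavior. The learner is the standard hybrid for
this paradigm:

* stage 2: delta rule, q₂(s,c) ← q₂ + α(r − q₂);
* stage 1 (model-free): SARSA(λ),
  q_mf(c₁) ← q_mf + α(q₂_old − q_mf) + αλ(r − q₂_old);
* stage 1 (model-based): planning through the known transition matrix,
  q_mb(a) = p·max_o q₂(common(a), o) + (1−p)·max_o q₂(other(a), o);
* choice: softmax over q_net = w·q_mb + (1−w)·q_mf with inverse
  temperature β₁ and a perseveration bonus for repeating the previous
  first-stage choice; stage 2 is a softmax over q₂ with β₂ and no
  perseveration.

The one non-standard ingredient is the **valence-dependent weight**: the
effective w on a given trial is `w_pos` if the previous trial was
rewarded, `w_neg` if it was not (midpoint on the first trial). Setting
`w_pos = w_neg` recovers the standard hybrid; `w_pos = w_neg = 0` and
`= 1` give the pure model-free and pure model-based agents used in the
signature tests. This is the package's *mechanism for generating* a
loss-specific planning deficit; it is not a claim about the mechanism in
any clinical population — reduced planning weight and distorted
transition beliefs, among others, can produce similar signatures, and
the package takes no position between them.

Initial action values are 0.5, the midpoint of the reward range, since
walk probabilities are bounded away from 0 and 1.

**Response times** are `rt_floor + Lognormal(log median, σ)` with
condition effects additive on the median: the stage-1 median drops by
`delta_loss` when the previous trial was unrewarded, and the stage-2
median rises by `delta_rare · w_eff` on rare transitions. Scaling the
slowing by the current effective model-based weight encodes the standard
interpretation that rare-transition slowing reflects model-based
processing — a pure model-free agent shows none — and lets the group
difference in slowing emerge from the weight difference without a
separate knob. Lognormal with additive median effects was chosen for
positive support and a heavy right tail with only two shape parameters;
no drift-diffusion or ex-Gaussian structure is attempted.

**Missed deadlines.** Each stage is missed with probability `p_miss`
(also when a drawn RT exceeds the 3-s deadline, which at default
parameters is vanishingly rare). A missed stage aborts the trial: no
choice, no reward, no learning update, and the trial is excluded from
lagged pairs downstream. This is the conservative reading of an
unspecified procedure.

## Synthetic cohorts

`default_specs()` defines 45 PG and 33 CP. Subject-level parameters are
truncated-normal draws; severity is an integer DSM-style symptom count
on 3–9 (mean 6, SD 1.4) in PG, 0 in CP. The group contrasts are:

| parameter | PG | CP | carries |
|---|---|---|---|
| w_pos | 0.82 (0.10) | 0.82 (0.10) | no deficit after reward |
| w_neg | 0.15 (0.10) | 0.82 (0.10) | planning deficit after non-reward |
| delta_loss (ms) | 37 (18) + 8·(sev−6) | 3 (20) | post-loss speeding, severity-coupled |
| delta_rare (ms) | 50 (12) | 50 (12) | slowing contrast emerges via w_eff |

Shared distributions: α 0.65 (0.12), λ 0.75 (0.12), β₁ 7.0 (1.2),
β₂ 4.0 (1.0), perseveration 0.9 (0.3), p_miss 0.015 (0.008), stage-1
median 330 ms and stage-2 median 495 ms above a 100-ms floor, lognormal
σ 0.22. Clinical covariate scores (urgency, depression) differ between
groups at the subject level but are generated independently of task
behavior, so covariate-by-behavior interactions are null by
construction.

**Calibration.** The defaults were fixed by pilot simulation so that
default cohorts reproduce the qualitative clinical profile reliably at
this sample size: the group × outcome × transition stay term in the
attenuated-PG direction, a group × transition term after non-reward but
not after reward, mean rare-transition slowing near 42 ms (CP) vs 24 ms
(PG), a PG post-loss speed-up near 37 ms that is absent in CP, and a
severity correlation near r ≈ 0.45. The `w_neg` contrast is deliberately
wider than the modest coefficients a comparably sized human study
reports: a three-way interaction of that size has roughly coin-flip
power at n = 78, and the generator's purpose is a cohort whose contrasts
are *recoverable* in most seeded replicates, not a maximum-likelihood
mimic of any dataset. Severity couples only to `delta_loss` (the only
severity relationship carried), with coupling to `w_neg` available but
off by default.

**What the generator does not emulate.** Real two-step data contain
practice and fatigue trends, RT autocorrelation, lapses that are not
simple misses, belief distortions about the transition structure, and
demographic structure; none of these are modeled. Passing the emulation
suite therefore shows that the analysis chain detects the intended
contrasts under this idealized data-generating process — not that the
analysis would behave identically on human data. A small mechanical
side effect of the valence mechanism: because PG agents rely more on
model-free values after losses, the generator also induces a modest
group × outcome coupling that a null-group design would not show.

## Preprocessing

Engagement filters (a subject is removed iff at least one rule fires;
both thresholds strict):

1. rate of repeating a previously rewarded second-stage response < 50%.
   "Previously rewarded" is operationalized within-state: the choice made
   at the last completed visit to the same second-stage state, given that
   visit was rewarded — the only reading that is well-defined when states
   alternate;
2. more than 20 missed deadlines, counting stages (a trial can time out
   at either stage);
3. some response option never tried (both first-stage options and all
   four state × option second-stage responses must occur); a subject with
   zero completed trials falls here and is reported distinctly.

The lagged table has one row per pair of *consecutive, fully completed*
trials; a missed stage on either member, or a gap in trial indices,
drops the pair. Predictors are effect-coded ±1 (o: +1 reward; τ: +1
common; g: +1 CP), so main effects are averages over the other factors,
model-based behavior appears as a positive o×τ coefficient, and in the
after-non-reward stratum a model-based population shows a *negative* τ
coefficient (switching after an unrewarded common transition). All sign
statements in tests and documentation are under this coding.

## Mixed logistic estimation

`mixedlogit.py` fits logit P(stay) = Xβ + Z b_i with independent
per-subject Gaussian random effects (diagonal covariance) by the Laplace
approximation: random effects are standardized (b = σu), the joint
penalized likelihood in (β, u) is maximized by Newton's method using the
Schur complement on the fixed effects (PIRLS), and the profiled Laplace
log-likelihood is maximized over the log-SDs by bounded Powell search
(log σ ∈ [−6, 2], start log 0.3, xtol 10⁻³). Wald SEs come from the
fixed-effects block of the inverse joint curvature at the optimum;
p-values are standard normal. This is the glmer (nAGQ = 1) algorithm
with one variant: β is profiled inside PIRLS rather than carried in the
outer optimizer. Against glmer with uncorrelated random effects on a
2,400-row fixture the difference is ≈ 0.2 SE on the intercept and
< 0.05 SE elsewhere, with random-effect SDs matching to three decimals
(verified in the test suite by calling Rscript/lme4 as an independent
oracle).

Model ladder: the default random-effects structure is a per-subject
intercept plus slopes for every within-subject term (o, τ, o×τ for the
full model; τ for the valence splits). On non-convergence the fit falls
back to intercept-only and then to plain logistic regression, logging
and flagging each step. A single-subject table degenerates directly to
fixed effects. Possible separation (inflated coefficients/SEs in the
fixed-effects path) is flagged in the result warnings. No
multiple-testing correction is applied anywhere.

Covariate models replace g by a z-scored subject-level clinical score;
a zero-variance covariate is an error.

## RT analyses

Both ANOVAs are classical mixed designs computed on per-subject cell
means (so dfs are subject-based: 1 and N−2), with partial
η² = SS_effect/(SS_effect+SS_error); the implementation delegates the
decomposition to pingouin and is verified exactly against hand-computed
sums of squares on an integer fixture. Stage-2 cell means use the
*current* trial's transition over completed trials; stage-1 cell means
condition on the *previous* trial's outcome and require the previous
trial completed and consecutive. Subjects with an empty cell are dropped
from that ANOVA and logged. No RT outlier trimming is applied — a
documented choice, not an inference about any particular study's
procedure. Post-hoc contrasts: pooled-variance two-sample t on
difference scores with Cohen's d_s (Welch variant behind a flag), and
paired t with d_z = t/√n; zero-variance paired contrasts are flagged
degenerate. The severity correlation is a Pearson r (t-based two-sided
p) between the symptom count and the per-subject post-loss speed-up
(mean stage-1 RT after reward minus after non-reward) among PG.

The reward-rate comparison is a one-way between-group ANOVA on
per-subject reward rates (rewarded / completed trials), reporting F, df,
p and partial η²; zero within-group variance is flagged degenerate.

## Problem sizes and determinism

The signature suite uses 200 agents × 200 trials per weight level and
the recovery suite 20 seeded replicates of the 78-subject default cohort
(plus 20 negative-control replicates with the valence gap removed) —
sizes at which the targeted effects are comfortably detectable while
the whole suite stays inside a desktop-scale run. All randomness flows
from named SeedSequence spawns of a master seed; rerunning any pipeline
configuration with the same seed reproduces the output bundle
byte-for-byte.

## Known limitations

* The variance components are independent (no random-effect
  correlations), matching the `||` syntax of lme4 rather than the full
  covariance model.
* Wald inference only; no likelihood-ratio or parametric-bootstrap
  tests.
* The Laplace approximation is known to bias variance components
  slightly downward for binary data with few observations per subject;
  at 200 trials per subject this is negligible.
* The agent layer deliberately omits forgetting/decay of unchosen
  values and any fitting of agent parameters to data.
* The reward-rate advantage of model-based control in this task is
  intrinsically small (≈ 0.5 percentage points between the default
  groups), so single-cohort comparisons of reward rate are noisy; only
  its direction, averaged over cohorts, is meaningful.
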