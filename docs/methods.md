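# Methods

## Task model

One latent expectation `EXP_c` is maintained per (agent × ability)
condition `c`.  On a trial of condition `c` with feedback `FB_t` (an
integer percentile) the learner updates

    PE_t      = FB_t − EXP_c,t
    EXP_c,t+1 = EXP_c,t + α(context) · PE_t

and the observed expectation rating is `EXP_c,t` plus Gaussian noise with
subject-level scale `noise_sd`, truncation-free in the likelihood
(ratings live comfortably inside [0, 100] at realistic noise levels).
The learning rate `α(context)` is looked up from the model's slot rule:

| model        | slots | keyed on                      |
|--------------|-------|-------------------------------|
| M1_unity     | 1     | nothing                       |
| M2_ability   | 2     | ability (high/low)            |
| M3_valence   | 2     | PE sign (+/−)                 |
| M4_unity_SO  | 2     | agent (self/other)            |
| M5_ability_SO| 4     | agent × ability               |
| M6_valence_SO| 4     | agent × PE sign               |
| M_mean       | 0     | constant mean per condition   |

Agent experiments compare all seven models; audience experiments (self
conditions only) compare M1–M3 plus a two-mean Mean model.

Two deliberate conventions:

* **Latent-state updating.**  PEs are computed against the model's own
  latent expectation, and ratings are noisy readouts.  This is the
  standard generative reading; it makes simulation and fitting symmetric
  (a model can generate exactly the data it is fitted to).  The
  alternative — anchoring the state on the observed rating — exists in
  the space as the `fixed_first_rating` init scheme for the starting
  values, but trial-to-trial updating is always latent.
* **Zero PE routes to the positive-valence slot.**  Arbitrary but fixed;
  with integer feedback and continuous latent states exact zeros are
  rare, and the noise model makes them measure-zero.

Initial expectations are fitted parameters, one per condition by default
(`fitted_per_condition`); `fitted_combined` ties them per agent.

## Feedback generator

The delivered feedback in each condition is stated in terms of its
realized statistics: mean ≈ 35 (low) / 65 (high), SD ≈ 16, hard ranges
[1, 60] / [40, 99].  Truncating N(35, 16) to [1, 60] would deliver mean
≈ 33.7 and SD ≈ 13.4 — truncation both shifts the mean and shrinks the
SD — so the generator instead solves for the parent normal whose
*truncated* mean and SD equal the stated values (fsolve on the
truncated-normal moment equations, cached per condition), draws by
rejection, and rounds to whole percentiles as displayed.  Rejection
sampling (rather than clipping) avoids piling mass at the bounds.

Condition orders are built sequentially: at each position a condition is
drawn among those with trials remaining that would not create a run of
three, with probability proportional to remaining count; the rare dead
end restarts the sequence.  Exact per-cell counts (25 agent / 30
audience) and the run-cap of two hold for every seed by construction.

## Synthetic cohorts

Per-subject true learning rates are Beta-distributed with moments set per
slot; the shipped defaults echo the fitted group values of the paradigm's
experiments (self: α_PE+ 0.12 ± 0.06, α_PE− 0.14 ± 0.09; other: 0.11 ±
0.08, 0.10 ± 0.07; audience variant 0.07 ± 0.05 / 0.10 ± 0.08), initial
expectations are truncated-normal around the scale midpoint (50 ± 8), and
the observation noise SD defaults to 10 rating points.  Trait scores
(self-esteem on an SDQ-like scale 6 ± 1, social anxiety on a SIAS-like
scale 20 ± 12) are generated through a Gaussian copula on the rank-normal
score of each subject's true Valence Bias Score, with default target
correlations +0.44 (self-esteem) and −0.39 (social anxiety, public
contexts only) — the values needed to exercise the trait-association
analyses.  All subjects share one fixed design per cohort by default,
mirroring the fixed feedback orders of the task
(`shared_design=False` gives independent designs).

What the generator does *not* emulate: response times, rating
discretization and anchoring habits, drifting attention, the deception /
cover-story layer, and any true correlation structure among a subject's
learning-rate slots (slots are drawn independently).  Passing tests
therefore demonstrate correctness of the machinery under the assumed
generative model, not validity of that model for real participants.

## Inference

Fits are per subject and per model, no pooling.  Priors: α ~ Uniform(0,1);
initial values and condition means ~ Normal(50, 20) truncated to
[0, 100]; noise SD ~ Half-Normal(20).  Sampling runs on an unconstrained
scale (logit for rates and rating-scale values, log for the noise SD,
with Jacobian corrections) using componentwise random-walk Metropolis
whose proposal scales adapt toward 44 % acceptance during warmup only.
Defaults mirror common practice for this task family: 3 chains × (1000
warmup + 2400 post-warmup iterations thinned by 3), i.e. 2400 retained
draws total.  The backend is pluggable (`backend(model, data, cfg) →
(draws, pointwise_loglik)`); the bundled sampler is numba-compiled and
fits one subject-model pair in well under a second at default settings.

Diagnostics are rank-normalized split-R̂ and bulk ESS per parameter
(degenerate constant chains yield R̂ = NaN / ESS = 0 and are flagged).
Subjects with any parameter's R̂ > 1.1 in any fitted model are excluded
with a reasoned report; implausible posterior means (> n SD from the
cohort mean) are only ever *flagged*, never auto-excluded, since that
judgment was a manual step in the original workflow.

Posterior central tendency is the mean (median available).  Known
limitation: with ~25 trials per condition and noise SD 10, the marginal
posterior of a small learning rate is right-skewed under the uniform
prior, so posterior-mean point estimates over-estimate small α by
roughly +0.03–0.04.  This shrinkage halves when trials are quadrupled and
is not a sampler artifact (identical under 4× longer chains and under the
median).  Group-mean learning-rate *contrasts* (valence asymmetries,
agent differences) are largely unaffected because the bias is shared
across slots.

## Model selection

Per subject, PSIS-LOO approximates leave-one-trial-out cross-validation
from the retained draws' pointwise log-likelihoods.  Importance weights
are smoothed with arviz's Pareto-smoothed importance sampling (top
min(0.2 S, 3 √S) weights replaced by generalized-Pareto quantiles); each
trial's k̂ is kept, trials with k̂ > 0.7 are flagged, and a sensitivity
variant removes flagged trials (union across models per subject, to keep
scores comparable) before re-running the selection.  A point posterior
makes importance sampling exact; such trials get k̂ = −∞ by convention.
The per-subject elpd sum is used directly as the log-evidence proxy — no
complexity penalty, which is the rationale for using LOO in the first
place.

Group-level selection is random-effects: Dirichlet(1,…,1) over population
model frequencies, updated by fixed-point variational iteration
(tolerance 1e−8); exceedance probabilities by Monte-Carlo over the
Dirichlet posterior (10⁵ draws by default, seeded); the Bayesian omnibus
risk compares the random-effects free energy against the equal-frequency
null, and pxp = (1 − BOR)·xp + BOR/K.  Correctness anchors in the tests:
exact LOO on a conjugate normal-mean model (analytic leave-one-out), and
the K = 2 closed form xp = P(Beta(α₁, α₂) > ½).

## Group statistics

The Valence Bias Score (α_PE+ − α_PE−)/(α_PE+ + α_PE−) is scale-invariant
and odd under swapping its arguments; it is undefined when both rates are
zero (flagged NaN, excluded listwise from correlations, never imputed).
ANOVAs use Yates' weighted-cell-means sums of squares with subject as a
random blocking factor — each within effect is tested against its own
effect-by-subject interaction, the between factor against
subjects-within-groups — which coincides with Type III on these balanced
designs and handles any number of within factors plus one between factor
(needed for the audience analyses).  No sphericity correction is applied:
the learning-rate factors have two levels, where the correction is
vacuous.  Two-sided p values throughout, no multiplicity correction, as
in the original analysis plan.  Partial correlations are Pearson
correlations of residuals after linear removal of the controls.
Posterior predictive checks report, per subject, the squared correlation
between observed ratings and the trajectory predicted at the posterior
mean (per condition and overall), and repeat the model-free
trial-by-condition ANOVA on the predictions.

## Simulation sizes in the test suite

Recovery studies run at reduced but informative sizes chosen to keep the
default suite fast: sampler settings of 2 chains × (400 warmup + 600
retained) for simulation studies, cohorts of 15–25 subjects, 5 seeds per
recovery claim, and 600 Dirichlet draws for quick exceedance checks.
Model recovery (unity / valence / self-other-valence generators, 15
subjects each) selects the generating model in 5/5 seeds under these
settings; the full-size sampler defaults are used for the worked example
in the README.
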