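# Methods

`setshift` models trial-level choice behaviour on two set-shifting
paradigms — probabilistic reversal learning (PRL) and the Wisconsin Card
Sorting Task (WCST) — the pair of tasks used to dissociate probabilistic
from deterministic feedback learning in clinical populations such as youths
with obsessive-compulsive disorder. This note documents the models, the
inference machinery, the synthetic-data generator and the numerical choices,
in that order.

## Task environments

**PRL.** Two stimuli, A and B. The optimal stimulus returns positive
feedback with probability `p_good = 0.8`, the other with `p_bad = 0.2`.
After `n_acquisition = 40` trials the contingencies reverse once, for
`n_reversal` further trials. The total session length is not fixed by the
task description we model, so the default is a symmetric 80-trial session
(`n_reversal = 40`), configurable. The reversal is trial-count-triggered;
performance-criterion reversal schedules are out of scope. Screen position
of the stimuli is not modelled: choices are over stimulus identities.

**WCST.** Response cards vary on color × shape × number (4 × 4 × 4 = 64
combinations); four fixed key decks (1 red triangle, 2 green stars, 3 yellow
crosses, 4 blue circles). Feedback is deterministic under the active rule
dimension; after `criterion_consecutive = 10` consecutive correct sorts the
set completes and the rule advances, for `max_sets = 9` sets. The
administered deck size, trial cap and rule order are not documented for the
data the analysis emulates, so we adopt the classic conventions: the full
64-card deck in a seeded shuffle redealt cyclically, rule order
color → shape → number cycled three times, and a `max_trials = 128` cap
(two deck passes) so sessions terminate even for agents that never reach
criterion. Cards identical to a key card are retained; their correct choice
matches all three dimensions and is unambiguous.

## Generative models

**PRL — four-parameter reinforcement learner.** Stimulus values start at
Q = 0.5 (the uninformative midpoint of the {0,1} outcome scale) and update
by the delta rule with valence-specific learning rates,

    Q_c ← Q_c + α_rew (o − Q_c)   if o = 1
    Q_c ← Q_c + α_pun (o − Q_c)   if o = 0,

only for the chosen stimulus. Choice is softmax with reinforcement
sensitivity β and an additive stickiness bonus κ for the previous choice:

    P(a) ∝ exp( β Q_a + κ · 1[a = previous choice] ).

Design choices that were genuinely open: stickiness is a one-trial
indicator (no decay), it is zero on trial 1, and β multiplies Q only —
κ enters the logit additively rather than being scaled by β. These are the
canonical readings of "stickiness describes the extent to which previous
choices are repeated irrespective of feedback".

**WCST — three-parameter sequential attention learner.** A weight vector
over the three dimensions starts uniform on the simplex. The match signal
of deck k for card c is the attention mass on the dimensions they share,
floored at ε = 1e-6; choice is the power rule

    P(k) ∝ m(k)^d,

with decision consistency d ≥ 0 (d = 0 is uniform choice). After feedback
the attention is reallocated toward the feedback-consistent dimension set S
(the matched dimensions after reward, their complement after punishment):

    a ← (1 − λ) a + λ · a|_S / Σ_S a,   λ = r (reward) or p (punishment).

The ε floor is what gives observed *unique errors* (zero-match choices)
finite likelihood; it is the one sensitivity knob of this model. No
attention-focus exponent is introduced — the model has exactly three free
parameters. If S has negligible mass the reallocation target falls back to
uniform over S; if S is empty the attention is left unchanged.

A property worth knowing: across a full multi-set session, the likelihood of
a perfectly rule-following sorter is *decreasing* in d, because immediately
after each rule change correct sorts contradict the learned attention.
Monotone increase in d holds only for pre-switch (single-set) data.

## Behavioural measures

PRL, per phase: proportion correct (choices of the phase-optimal stimulus);
switching after *spurious negative* feedback (negative feedback on an
optimal choice); staying after *veridical positive* feedback; and the
perseveration proportion — the unbroken run of previously-optimal choices
from the first reversal trial, divided by the reversal trial count (the
denominator was not documented; reversal-trial count chosen over error
count). Events on the final trial have no successor and leave switch/stay
denominators. Empty denominators yield `None` (unavailable), never 0.

WCST error taxonomy (mutually exclusive, precedence order): *unique* —
the chosen deck matches the card on no dimension; *perseverative* — from
set 2 on, the choice matches the previous set's rule but not the active
rule (choices matching both old and new rule are correct, hence never
errors; a simultaneous match of the old rule and an irrelevant third
dimension still counts as perseverative); *nonperseverative* — everything
else. First-set errors are never perseverative. A *set-maintenance failure*
is an error after ≥ 5 consecutive correct sorts in the current set (the
"rule established" criterion is not documented; 5 is the classic convention
and is configurable). Error proportions use total session trials as the
denominator. Heaton-style "perseverated-to principle" subtleties are not
implemented; the simpler stated definitions are.

## Hierarchical Bayesian inference

Each group is fitted independently (control, patient, and medication
subgroups each get their own fit); contrasts subtract whole posteriors, so
a joint model with group offsets is not needed and is not implemented.

Subject parameters are transformed to latent space: probit links for
unit-interval rates, scaled probit for bounded-positive parameters
(β = 20·Φ(z), d = 10·Φ(z)), identity for κ. The β bound of 20 is standard
for softmax sensitivities on a 0–1 value scale; the d bound of 10 was
chosen to cover the plausible consistency range with room to spare. Latents
are population-normal, `z ~ N(μ_p, σ_p)`, with priors `μ_p ~ N(0,1)` and
`σ_p ~ half-Normal(0.5)`. The SD prior scale of 0.5 was set so that the
latent heterogeneity implied by realistic natural-scale spreads (≈ 0.25–0.4
after the links) is comfortably inside the prior; a much tighter scale would
shrink group SDs a priori and narrow group-mean posteriors artificially.
All links and prior scales are config-exposed.

**Sampler.** No probabilistic-programming backend is assumed; the sampler
is a purpose-built Metropolis-within-Gibbs scheme with numba-compiled trial
likelihoods. Per sweep:

1. per-coordinate random-walk Metropolis on each subject-latent column,
   all subjects updated in parallel (subjects are conditionally independent
   given the group level), step sizes adapted to ≈ 0.44 acceptance;
2. a joint per-subject proposal from a Haario-style adapted covariance,
   which handles within-subject trade-offs (e.g. β vs κ);
3. conjugate Gibbs draws of the group means;
4. a *group translation* move shifting μ_p and every subject's z_p together
   (group-mean mixing then does not wait on the slow diffusion of subject
   latents);
5. a *group scale* move rescaling residuals and σ_p jointly, followed by a
   random-walk refresh of log σ_p.

Defaults: 4 chains, 500 warmup + 500 kept draws, all adaptation frozen
after warmup. A fit emits a convergence *warning* (never an error) when any
split R-hat exceeds 1.01; diagnostics (split R-hat, bulk ESS) come from
arviz. Identical data, config and seed reproduce draws bit-for-bit.

**Group means and contrasts.** The reported "group mean on the natural
scale" is the population mean of link(Z), which is closed-form for every
link used (probit: upper·Φ(μ/√(1+σ²))). A contrast differences the
natural-scale group-mean draws of two *independently fitted* groups — the
pairing of draws is arbitrary, so the larger draw set is deterministically
strided down to match; critically, the two fits must use different sampler
seeds, or paired differencing cancels shared MCMC noise and collapses the
interval (the pipeline derives per-group seeds automatically). The package
convention is **patient minus control**: positive reward-rate MD means
patients learn faster from reward.

**HDI.** `hdi(draws, mass)` is the exact narrowest contiguous window
containing ⌈mass·n⌉ sorted draws, leftmost on ties, verified against
exhaustive search. Exact minimal windows of different masses need not nest
on tied or multimodal samples (observed in ≈ 4% of small random samples),
so the contrast path uses `hdi_nested`: the 90% window is searched within
the 95% window, which guarantees the reported pair nests and coincides with
the unconstrained answer except in those degenerate cases.

## Model comparison

Marginal likelihoods are estimated by bridge sampling with the optimal
bridge: posterior draws are split half/half (seed-fixed), a moment-matched
multivariate normal proposal is fitted on one half, and the fixed-point
iteration runs on the other half against an equal number of fresh proposal
draws, to tolerance 1e-8 or 1000 iterations (non-convergence flags the
estimate rather than raising). Warp transformations are not implemented.
The reported MC error is the usual relative-variance approximation under an
independence assumption — an order-of-magnitude gauge, not a calibrated
interval. The estimator reproduces closed-form evidence on normal-normal
and beta-binomial testbeds to well under 0.1 nats at 4000 draws.

The model family compared is the full model plus nested reductions obtained
by clamping or tying one parameter: PRL without stickiness (κ ≡ 0) and
WCST with a single shared learning rate — the compared families were not
enumerated in the analysis we emulate, so these minimal nested alternatives
stand in.

## Synthetic cohorts and recovery

The generator mirrors the fitted hierarchy: per group, subject latents are
drawn from a normal population and pushed through the links into the task
simulators. Group means and SDs are specified on the **natural** scale;
the matching latent moments are solved numerically by Gauss–Hermite
moment-matching, because the link nonlinearity makes latent gaps differ
from natural gaps. Default natural-scale population SDs: 0.15 for
unit-interval rates, 2.0 for β, 0.3 for κ, 0.8 for d — plausible
between-subject heterogeneity for these tasks; the true population spreads
of any real cohort are unknown, and all of these are config-exposed.

Two presets define the study conditions the package validates against:

* `paper_like_prl` — control means (α_rew 0.35, α_pun 0.45, β 9.0, κ 0.6)
  and patient-minus-control gaps (+0.21, −0.29, −4.91, −0.35): patients
  learn more from reward, less from punishment, choose more randomly and
  are less sticky. The control means themselves are unpublished; these
  values produce control behaviour in the healthy range (reversal accuracy
  ≈ 0.85, low post-reversal switching) while keeping the patient group
  inside all link ranges.
* `paper_like_wcst` — two groups from identical populations
  (r 0.35, p 0.45, d 2.5; zero gaps), the null configuration used to
  calibrate contrast false-positive rates.

`run_recovery` generates, refits each group (independent seeds), and scores
truth-vs-estimate Spearman correlations (pooled across groups), 95% HDI
coverage of the generating group means, and contrast sign agreement.
Recovery at the scale used in the tests (20 subjects/group × 80 PRL trials;
25 subjects/group WCST; 4 chains × 500 draws) gives pooled rank correlations
of roughly 0.6–0.9 for the PRL parameters and 0.6–0.95 for the WCST
parameters, correct mean-difference signs in every replicate tried, and
zero-gap 95% exclusion rates at or below the nominal 5%. Stickiness is the
least identified PRL parameter: in a high-β group, choices saturate on the
better option and κ barely moves behaviour, so its within-group correlation
fluctuates (≈ 0.35–0.8 across replicates) — an information limit of the
design, not of the sampler.

**What the generator does not emulate:** response times are optional
log-normal filler, never analysed; there is no comorbidity, symptom
severity, attention lapsing, trial omissions, or model mismatch (data are
generated by the same model family that is fitted). Passing recovery
therefore shows the inference machinery is correct and the design is
informative at these sample sizes — not that real cohorts obey the model.

## Problem sizes and determinism

The test suite and examples use deliberately scaled-down problems: cohorts
of 6–25 subjects per group, 4 chains × 500 kept draws, 5 recovery
replicates. These sizes were chosen as the smallest at which the validated
properties are stable across seeds. Every stochastic stage (task feedback,
cohort draws, sampler, bridge splits) consumes an explicit seed, and
pipeline artifacts embed the config hash, so any reported number is exactly
regenerable.

## Known limitations

* Groups are fitted independently; shrinkage across groups (a joint model
  with offsets) might sharpen small-subgroup contrasts.
* The MH sampler's ESS per draw is far below a gradient-based sampler's;
  the defaults compensate with cheap likelihoods rather than clever moves.
* Bridge-sampling MC error assumes independent draws; with autocorrelated
  MCMC output it understates the true error.
* Alternative model families (counterfactual updating, Bayesian-observer,
  drift-diffusion) and response-time likelihoods are out of scope.
* The exact priors, links and total PRL session length of the study the
  presets emulate are not public; all stand-in choices above are explicit
  and configurable.
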