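# Methods

This note documents the modelling and numerical choices behind the package:
what each model assumes, how the raw tables are turned into model inputs,
what the synthetic-population generator does and does not emulate, and where
design was genuinely open.

## State process for tactic transitions

Each male occupies one of four states per oestrus event of his group:
subordinate (reproductively inactive), sneaker, guard, dead. For live origin
state *n*, the probability of dying before the next event is `1 − s_n` with a
per-origin survival probability `s_n` (logit-scale intercept, no covariates:
survival is status-related only). Conditional on surviving, the destination
among the three live states follows a multinomial logit with subordinate as
the reference category:

    eta[n, m] = x' β[n, m] + u_male + u_group + u_event,  m ∈ {sneaker, guard}

Death is absorbing with probability 1. The covariate vector `x` is an
intercept, age rank, group-centred weight and group sex ratio, standardized
as below. Optional sex-ratio × age-rank and sex-ratio × weight products can
be included; with `interactions="auto"` they are fitted, tested against the
credibility rule, dropped when not credible, and the model refitted — an
automated version of the usual fit-then-prune procedure. Age rank and weight
products are never formed (the two are substantially correlated and their
product would amplify collinearity).

**Random-effect placement.** One scalar effect per male, group and event is
added to *both* non-reference linear predictors. Adding the same term to
every destination (including the reference) would cancel in the softmax and
be unidentifiable; per-destination effects would double the random-effect
count and are weakly identified at realistic sample sizes. The shared term
is interpretable as an "activity propensity": it moves probability between
inactivity and the two active tactics.

## Outcome models

* **Weight change** — Gaussian; cell-means coding of the three-level tactic
  factor, so the posterior directly reports the mean percentage change per
  tactic; residual SD on the log scale; random effects for male, group,
  event. Contrasts between tactics are computed from the draws.
* **Siring success** — Bernoulli logit per suitor trial; guard coded 1,
  sneaker 0; fixed effects for the number of suitors of the same female
  ("competitors", including the focal male) and the proportion of the
  *other* suitors using the focal male's tactic; random effects for female,
  male, event. Tactic × competitors and tactic × proportion-same terms are
  auto-pruned as above.
* **Mate choice** — Bernoulli logit per (male-day with ≥ 1 interaction) ×
  (adult female present); fixed effects for group-centred relatedness, male
  and female age rank, their product (assortativity), tactic and its rank
  interactions up to the three-way product (tactic differences in
  assortativity; the sneaker rank-lag appears as a weaker sneaker slope),
  the droppable tactic × relatedness term, and the number of adult females
  present; random effects for male, female, event. Day-level records are
  the default unit; `unit="event"` collapses repeated days.

## Derivation rules

* **Tactic per event**: guard if the male guarded on any day and never
  sneaked; sneaker if the reverse; if both occurred, the behaviour shown on
  more days; a day-count tie goes to sneaker by default (`tie_rule="guard"`
  flips it — the field definitions support either reading); subordinate if
  inactive throughout. Males under 180 days never enter any table.
* **Age ranks**: 1 = oldest; equal ages share the minimum rank and the next
  younger rank skips by the tie-group size.
* **Oestrus weight**: mean of weights in [event start − 60 d, event end +
  60 d] (the window anchors at the start backwards and the end forwards; all
  intervals are closed whole days). Weights are centred on the group-event
  mean over observed males, so centred values sum to zero by construction.
* **Imputation**: missing oestrus weights are predicted from the male's own
  weight-on-age regression, fitted locally (points within 120 d of the
  target age, widening to 240 d, then the whole lifetime, until three points
  exist) because growth is only locally linear; males with fewer than three
  weights get a pooled-slope line through their own mean; males with no
  weights stay missing. Imputed values are flagged and used only as
  transition-model covariates, never in weight-loss records.
* **Weight change**: 60-day pre-event average versus the single nearest
  post-event weight, usable up to 9 days after the event end (day 9
  inclusive); percentage change is 100·(post − prior)/prior; raw weights
  only.
* **Relatedness**: pairwise relatedness to each adult female present,
  centred on the male's mean over those females; dyads with unknown
  relatedness are dropped and logged.
* **Litters**: linked to the event of the mother's group whose end fell
  44–74 days (a gestation, 59 ± 15 d) before the birth; with two candidates
  the nearer event end wins; unlinked litters are excluded. Siring trials
  require the mother to have been pursued by at least one guard and one
  sneaker, and the litter is dropped (logged) if no assigned sire was among
  her suitors.
* **Sex ratio**: males ≥ 1 year over females ≥ 1 year on the event roster;
  an event with no adult females is excluded with a log entry.

## Inference

Priors are weakly informative and overridable: Normal(0, 10²) on
coefficients and survival logits (the latter is near-flat on the probability
scale), half-Normal(0, 5²) on random-effect SDs. The sampler is an adaptive
random-walk Metropolis-within-Gibbs: scalar coordinate updates for fixed
effects (recomputing only the rows a coordinate touches), vectorised
all-levels updates for each random-effect vector (levels are conditionally
independent), log-scale updates for each SD, plus an interweaving move that
rescales a whole random-effect vector together with its SD — without it the
SD coordinates mix pathologically in the funnel. Proposal scales adapt
toward 44% acceptance during burn-in only, so retained draws come from a
fixed kernel; chains are deterministic given the seed, and chains start from
the posterior mode (random effects at zero) found by L-BFGS. Default chain
settings per model follow the conventions of the original analyses
(transitions 3 × 20 000/2 500/100; weight loss 3 × 50 000/5 000/100; siring
3 × 100 000/10 000/100; mate choice 3 × 20 000/2 000/100); tests and the
acceptance script use shorter chains (typically 3 × 1 200–1 800 iterations,
thin 1) that these well-mixing updates support.

Covariates whose observed range leaves [0, 1] are z-scored; proportions and
indicators are left alone; scaling metadata is retained so curves are drawn
on the raw scale. Split-chain R̂ < 1.1 on every parameter defines
convergence (floored at 1.0, so identical chains report exactly 1.0).
Credible intervals are 2.5/97.5 percentiles with linear interpolation —
summaries are exactly recomputable from saved draws — and an effect is
credible when the share of draws on one side of zero is ≥ 0.975 (boundary
inclusive).

## Synthetic populations

The generator mirrors the study system: 1–7 adult females per group, about
2.2 males per female (groups of 3–25 males), roughly quarterly oestrus
events of 1–7 days (mean ≈ 3), males entering as subordinates at 180 days,
tactics evolving by the transition kernel above with its random effects,
logistic individual growth to a ~1.8 kg asymptote with 25 g measurement
noise, a tactic-dependent percentage weight change after each event (defaults
+0.3% subordinate, −2.3% sneaker and guard, SD 4%) that decays linearly over
three weeks, 6.6% of oestrus windows deleted completely at random (from a
separate random stream, so datasets differing only in the missingness rate
share all other data), kin-structured relatedness drawn from
{0, 0.125, 0.25, 0.5}, guards choosing one female per day and sneakers
pursuing females by the mate-choice logit, litters born ~59 ± 6 days after
the event, and sires drawn among the mother's suitors with a guard advantage
and negative frequency dependence on the logit scale.

What it does **not** emulate: observation error in behaviour (focals record
the true tactic), female mortality and dispersal, between-group encounters,
seasonal effects, and informative weight missingness. Passing recovery tests
therefore show the estimators are correct under the assumed data-generating
process — not that field data meet those assumptions. Two known, intended
artefacts of the more realistic pieces: extracted weight-change means are
attenuated relative to the generating values (the prior window overlaps the
previous event's recovery period, and post-event weights are taken 1–9 days
into the recovery decay), and the realised missing-weight fraction sits
slightly above the nominal 6.6% because deleted windows overlap neighbours.

Recovery studies in the tests use 12 groups × 8 events (~120 males, ~950
transitions) per replicate and 20 replicates — large enough for stable
coverage statistics while keeping the suite quick — and compare posterior
intervals against the truth mapped onto the fitted (standardized) scale,
which is an exact linear map.

## Known limitations

* The multinomial-logit kernel is first-order Markov in the tactic state;
  longer memory (e.g. tenure effects) is not modelled.
* Survival depends on origin state only; covariate effects on survival are
  not estimated.
* Random-effect level values are not stored by default (only their SDs);
  pass `store_re=True` to keep them.
* The MAP used for chain initialisation sets random effects to zero; for
  heavily unbalanced designs the first iterations still need the burn-in.
* With very sparse origin states (a handful of sneaker rows) the
  origin-specific coefficients lean on the prior, as any hierarchical
  model's would.
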