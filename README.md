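# mongoose-arts

Bayesian models of **alternative reproductive tactics (ARTs)** in cooperatively
breeding banded mongoose (*Mungos mungo*) groups, built as a tested, reusable
pipeline from daily field observations to posterior inference.

Banded mongoose groups hold several breeding females and even more adult
males. During a group's short, synchronous oestrus events each male either
**guards** one female (following her within metres and repelling rivals),
**sneaks** copulations from guarded females, or stays reproductively inactive
(**subordinate**). This package asks, with models rather than anecdote: when
do males switch tactics, what does each tactic cost, and what does it buy?

## The models

**Tactic transitions.** Male *i*'s tactic at oestrus event *t* is a state
`z[i, t] ∈ {subordinate, sneaker, guard, dead}`. The transition kernel Ω is,
for live origin *n* and live destination *m*,

    ω(n → dead) = 1 − s_n
    ω(n → m)    = s_n · softmax_m( x' β[n, m] + u_male + u_group + u_event )

with subordinate the reference destination (linear predictor 0), `x` holding
an intercept, within-group **age rank** (1 = oldest; ties share the minimum
rank and leave gaps), **group-centred weight** (individual oestrus weight
minus the group male mean) and group **sex ratio** (adult males per adult
female); `s_n` is origin-specific survival and death is absorbing
(ω(dead → dead) = 1). Crossed random effects for male, group and oestrus
event enter each non-reference predictor.

**Outcomes.** Three hierarchical models quantify consequences:
percentage weight change over an event (Gaussian, three-level tactic factor);
siring success per suitor (Bernoulli, guard coded 1, with the number of
competing suitors and the proportion of competitors using the same tactic —
negative frequency dependence); and day-level mate choice (Bernoulli per
male-day × female present, with group-centred relatedness, male × female age
rank and their tactic interactions — assortative guarding and the sneaker
rank-lag).

Inference is MCMC (adaptive Metropolis-within-Gibbs with an interweaving
move for the random-effect scales). Numeric covariates whose range leaves
[0, 1] are z-scored. Convergence requires split-chain R̂ < 1.1, and an effect
is **credible** when ≥ 97.5% of its posterior lies on one side of zero.

A synthetic-population generator simulates whole study datasets (groups,
demography, daily focals, weights, relatedness, litters) from known true
parameters, so every preprocessing rule and model is validated by parameter
recovery.

## Worked example

```python
from mongoose_arts import (
    McmcConfig, SimConfig, derive_all, generate_population,
)
from mongoose_arts.transitions import TacticTransitionModel

dataset = generate_population(SimConfig(n_groups=6, n_events_per_group=10, seed=11))
derived = derive_all(dataset.tables())

model = TacticTransitionModel(derived.transitions, interactions="none")
result = model.fit(McmcConfig(chains=3, iterations=1600, burnin=600, thin=1, seed=7))
print(f"max R-hat {result.rhat_max:.3f}")
mat = result.transition_matrix()
for o, origin in enumerate(("subordinate", "sneaker", "guard")):
    row = "  ".join(f"{p:.3f}" for p in mat["mean"][o])
    print(f"from {origin:<12} {row}")
```

Output from this exact script (columns: to subordinate, sneaker, guard, dead):

```
max R-hat 1.043
from subordinate  0.717  0.134  0.137  0.012
from sneaker      0.586  0.159  0.243  0.013
from guard        0.565  0.156  0.230  0.049
```

Read: at the sample-mean covariates an inactive subordinate usually stays
inactive (0.717); sneaking is unstable (retained 0.159) — a sneaker more
often moves back to inactivity or on to guarding (0.243) than keeps
sneaking — and these are the generator's built-in dynamics recovered from
the raw synthetic tables end to end. `summary()` on any
result gives the per-parameter table (mean, 95% CI, R̂, credibility), and
`transition_curves` / `plot_curves` trace each transition probability along
age rank or weight.

The same pipeline runs from a shell:

```bash
mongoose-arts simulate --config sim.yaml --out raw/
mongoose-arts preprocess --in raw/ --out derived/
mongoose-arts fit-transitions --in derived/ --out fits/ --iterations 1800 --burnin 600 --thin 1
mongoose-arts report --in fits/
```

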