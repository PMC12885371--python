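# Methods

## Task model

The environment is a two-alternative forced-choice bandit with 8
stimuli. Four stimuli pay out on the trial they are chosen
(immediate class); the other four pay out exactly two trials later
(delayed class), regardless of what happens in between. The delayed
queue is indexed by trial, not by response: an omitted response never
shifts the lag. Each class contains one stimulus per start value in
{4, 1, −1, −4}.

Rewards evolve as latent Gaussian random walks started at the start
values. The per-step spread `step_scale` is a standard deviation with
default 0.5 (step variance 0.25). We read the walk notation N(0, .25)
as mean–variance, the standard convention; because the alternative
(SD 0.25) is plausible, `step_scale` is an explicit parameter and the
other reading is one argument away. The *delivered* reward each trial
is the latent state rounded to the nearest integer, halves away from
zero (symmetric around the negative start values and therefore
bit-stable in tests); the latent walk itself accumulates unrounded.

A session offers every one of the C(8,2) = 28 unordered pairs exactly
`n_repeats` = 12 times in a uniformly shuffled order: 336 trials.
Feedback is rendered per condition: **conjoint** shows only the sum of
whatever lands on the trial (current immediate payout + delayed payout
from t−2); **disjoint** shows the two components in separate boxes.
An empty box is treated as an absent component that contributes 0 to
the total.

## Learning models

State is initialized at zero (v = e = Q = 0) at the start of every
session, and every session is fitted independently.

*Eligibility trace.* One prediction error per trial between the
displayed **total** (in both conditions) and the value of the current
choice. Traces are *replacing*: the chosen action's trace is set to 1,
all others decay by λ_elg, bounding traces in [0, 1]; all actions are
then updated by α_elg · δ · e. On omitted-response trials time still
passes: traces decay, nothing else changes, and the trial contributes
no likelihood term.

*Tabular.* Values are indexed by delay slot d ∈ {0, 2}; the one-trial
slot does not exist, so credit to the previous trial's choice is
structurally zero. Slot d=0 of the current choice and slot d=2 of the
choice from two trials back are updated each trial; the d=2 update is
scaled by α_tab·λ_tab, the d=0 update by α_tab alone. In conjoint both
prediction errors share the displayed total as target; in disjoint
each uses its own displayed component. By default an empty disjoint
box still generates an update with target 0 (both prediction errors
are computed unconditionally); `skip_absent_components=True` updates
only delivered components. The decision value of an action is
Σ_d Q(d, a): the delay slots encode *when credit is assigned*, not a
stimulus property, so every action owns both slots.

*Normalization.* Because the walks and the two feedback conditions put
values on different scales, each strategy's value vector is z-scored
at decision time against its own recent history: the pool is every
entry (8 actions × up to `window` prior trials) of the decision-time
value snapshots, population-variance convention, each strategy
normalized separately. Window defaults to 5 trials; 0 disables
scaling and `None`/`all` pools over the whole task so far. On trial 0
the buffer is empty and raw values are used (the softmax is
shift-tolerant); a zero spread falls back to centering only. Snapshots
are the decision-time vectors (the values actually compared on each
prior trial).

*Decision rule.* Softmax over the two offered options of
β_elg·z(v) + β_tab·z(ΣQ). The hybrid model carries both weights; the
single-strategy models are the exact β=0 reductions (verified to
1e-10 relative likelihood error in the tests). Shared-parameter
variants tie the learning rate (hybrid-1L) or learning and decay rates
(hybrid-1D) across strategies.

## Fitting

The objective is the session negative log-likelihood over responded
trials minus the log density of penalization priors: Gamma(shape 1.25,
scale 1) on each strategy weight, Beta(1.25, 1.25) on each learning
and decay rate. These densities vanish at the rate bounds, keeping
fitted rates strictly inside (0, 1). Bounds are α, λ ∈ [1e−6, 1−1e−6]
and β ∈ [0, 20] (20 saturates a two-option softmax on z-scored
values); a probability floor of 1e−12 inside the log keeps the
objective finite during optimizer exploration.

Optimization is differential evolution (scipy), population 15 ×
dimension, seeded, with L-BFGS-B polish. The reference configuration
runs 300 generations at relative tolerance 1e−8; the recovery studies
and the acceptance script use a scaled configuration (60 generations,
tolerance 1e−6) that we verified reaches the same optima on this
likelihood to well within the recovery tolerances. The likelihood is
evaluated for the whole candidate population in one vectorized pass
over trials per generation, which is what makes desk-scale recovery
studies practical.

AIC = 2k + 2·NLL and BIC = k·ln n + 2·NLL use the **unpenalized**
likelihood at the optimum — the penalty is a regularizer, not part of
the data likelihood (a documented choice; the penalized alternative is
a one-line change). Pseudo-R² = 1 − NLL/(n·ln 2) against the
coin-flip null over responded trials. Model comparison reports
per-condition mean AIC, flags the lowest, and attaches paired Wilcoxon
signed-rank p-values against the best variant (p = 1 for identical AIC
vectors, where the test is undefined).

## Synthetic agents

The generator emulates the study design: per participant, one session
per feedback condition with the order counterbalanced (even-indexed
participants start disjoint, giving an exact ±1 split), three shared
random walks with an independent uniform walk assignment per session
(so ~1/3 of participants see the same walk twice), a fresh shuffled
pair schedule per session, and independent generative parameters per
session drawn from Beta(1, 2) for learning rates, Gamma(shape 3,
scale 1) for strategy weights, and Beta(2, 3) for decay rates
(shape–scale convention). A `shared_params` flag supports
order-effect experiments; `beta_min` rejection-samples weights above a
floor when deliberately informative agents are wanted (recovery
studies use β > 2). Posterior-predictive replays regenerate choices
25 times per session by default on the *same* pair sequence and walk.

What the generator does **not** emulate: reaction times, fatigue or
order effects, response omissions (synthetic agents always respond;
the omission path is exercised by hand-built fixtures), perseveration,
or any individual-difference structure beyond the parameter priors.
Passing tests therefore certify the machinery — identifiability,
recovery, signature direction — under the model's own assumptions, not
any claim about human data.

## Recovery studies

Parameter recovery simulates N sessions from prior draws (cycling
conditions), refits the generating variant, and reports Pearson r and
mean bias per parameter. Model recovery simulates from each of
eligibility / tabular / hybrid, fits all three to every simulated
session, and tabulates the winner by AIC and BIC; ties break toward
the model with fewer parameters. The tabular learning rate is known
to recover weakly and is recorded but never gated on.

Problem sizes: the test suite runs 50 datasets per variant for
parameter recovery and 15 simulations per generating model for model
recovery; the acceptance script defaults to 30 and 10 (sizes are
recorded in its JSON output and adjustable via flags); the CLI default
is 50 with `--full` switching to the reference 300 / 25.

## Signature analyses

*Stay/switch events.* A delayed-class choice at trial t whose stimulus
is offered again at exactly t+3 (and answered) yields one event; the
valences are the feedback seen at t (0F) and at t+2 (2F, when the
origin's delayed payout lands), coded positive iff strictly > 0.
Default valence is the **displayed total** at each time point in both
conditions. The component reading (immediate box at t, delayed box at
t+2) is available as `valence_source="component"`, but it is not the
default because a delayed-class origin choice never shows an immediate
component — under that coding the disjoint 0F valence is structurally
negative and the full condition × time × reward design is singular.

*Regressions.* Stay ~ condition × time × reward and
choice ~ condition × (elg + tab) are pooled fixed-effects logistic
regressions (statsmodels), optionally with subject-clustered standard
errors — a deliberate simplification of random-slope multilevel
models, which are out of scope. Constant predictors are dropped and
reported; complete separation propagates as an error rather than being
silently smoothed over.

*Credit gradient.* For each trial (from the 4th) whose last four
selections are responded and pairwise distinct, the one-step value
change applied to the options selected at lags 0–3 is recorded,
grouped by the sign of the current prediction error and condition.
For the eligibility model successive lag means are in exact ratio λ
(the trace is λ^k after k non-reselections); for the tabular model
lags 1 and 3 are exactly zero.

*Metrics and contrasts.* Optimal choice counts trials where the chosen
stimulus's delivered walk value is at least the alternative's (ties
count optimal — there is no wrong answer); average outcome is the mean
delivered value of the chosen stimulus at the choice trial. Parameter
condition contrasts are two-tailed paired t-tests (conjoint − disjoint)
with 95% CIs and Cohen's d; zero-variance differences are flagged
degenerate instead of reported as huge t-values.

## Numerical and design choices

- Round-half-away-from-zero for delivered rewards (ties in optimality
  are class-symmetric).
- 0-based trial indices; the delayed lag is exactly 2 trials.
- Seeds: every source of randomness flows from `numpy`
  `SeedSequence`s; the CLI expands one master seed into per-component
  children via `SeedSequence([master, crc32(label)])`.
- The uninformed model (both weights 0) has NLL = n·ln 2 and
  pseudo-R² = 0 exactly; this anchors the likelihood scale.

## Known limitations

- Fixed-effects signature regressions understate uncertainty relative
  to multilevel fits when subjects are heterogeneous; use the
  clustered-SE option for inference.
- Strategy weights are only weakly identified once the softmax
  saturates (deterministic agents): recovered weights compress toward
  the informative range even when the generating weight is larger.
- The tabular learning rate trades off against its decay rate in
  conjoint sessions, where both prediction errors share one target;
  its recovery is correspondingly weak.
- With scaling disabled (`window=0`) the strategy weights live on the
  raw reward scale and are not comparable across conditions.
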