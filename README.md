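# creditrl

Temporal credit assignment in delayed-reward bandits: a task simulator,
two reinforcement-learning strategies (eligibility trace and tabular
delay-indexed Q-learning) plus their hybrid, penalized maximum-likelihood
fitting, recovery studies, and behavioral signature analyses.

## The problem

When a reward arrives two trials after the choice that caused it — and
is possibly summed together with the payout of the current choice — a
learner has to decide *which* past action to credit. `creditrl`
implements a two-alternative learning task that poses exactly this
problem: 8 stimuli (4 paying immediately, 4 with a 2-trial delay) whose
integer rewards start at {4, 1, −1, −4} and drift as rounded Gaussian
random walks (step SD 0.5); every one of the 28 stimulus pairs is
offered 12 times (336 trials per session). Feedback is rendered either
**conjoint** (one summed total) or **disjoint** (separate immediate and
delayed components), manipulating how much information the learner gets.

## The models

Both strategies score each action `a` and choose via softmax.

**Eligibility trace** (retrospective) — a single prediction error on the
displayed total, propagated backwards through a replacing trace:

    δ_t = r_t − v_t(a_t)
    e_t(a) = 1 if a = a_t else λ_elg · e_{t−1}(a)
    v_{t+1}(a) = v_t(a) + α_elg · δ_t · e_t(a)

**Tabular** (prospective) — delay-indexed values Q(d, a), d ∈ {0, 2},
with two prediction errors that update the current choice and the
choice from two trials back, skipping the (task-irrelevant) one-trial
lag; the delayed slot is decay-scaled:

    δ_t(0) = r_t(0) − Q_t(0, a_t)          Q ← Q + α_tab · δ_t(0)
    δ_t(2) = r_t(2) − Q_t(2, a_{t−2})      Q ← Q + α_tab · λ_tab · δ_t(2)

In conjoint both errors use the same displayed total; in disjoint each
uses its own displayed component.

**Hybrid decision rule** — each strategy's values are z-scored against
a rolling 5-trial window of their own history and combined:

    π_t(a) ∝ exp[ β_elg · z(v_t(a)) + β_tab · z(Σ_d Q_t(d, a)) ]

Setting β_tab = 0 (or β_elg = 0) reduces the hybrid exactly to the
single-strategy model. Shared-parameter hybrids (tied learning rate,
or tied learning and decay rates) are available as variants.

Fitting minimizes the penalized negative log-likelihood (MAP) by
differential evolution, with Gamma(1.25, 1) priors on weights and
Beta(1.25, 1.25) priors on rates; AIC/BIC/pseudo-R² use the
unpenalized likelihood.

## Worked example

```python
import creditrl as c

stim  = c.make_stimulus_set(seed=1)
sched = c.generate_schedule(8, 12, seed=2)          # 336 trials
walk  = c.generate_reward_walk(stim, sched.n_trials, seed=3)

true = c.ParamSet.from_free(c.Variant.ELIGIBILITY, [0.3, 0.5, 8.0])
sess = c.simulate_session(true, sched, walk, stim, c.Condition.DISJOINT, seed=5)

fit = c.fit_session(sess, c.Variant.ELIGIBILITY,
                    optimizer=c.OptimizerConfig(maxiter=60, tol=1e-6), seed=7)
print(round(fit.nll, 2), [round(float(v), 3) for v in fit.params.free_values])
print(round(fit.aic, 1), round(fit.pseudo_r2, 3))
```

prints

```
53.39 [0.3, 0.5, 5.306]
112.8 0.771
```

i.e. the learning rate (0.3) and decay (0.5) of the generating agent
are recovered essentially exactly; the fitted weight (5.3) sits on the
flat upper shoulder of the likelihood that an almost-deterministic
agent (true weight 8) induces; the fit explains ~77% of the choice
log-likelihood relative to a coin-flip model (pseudo-R²).

A CLI wraps the pipeline:

```sh
creditrl simulate --participants 8 --seed 1 --out study/
creditrl fit study/sessions.csv --model elg --seed 1 --out fits/
creditrl signatures study/ --out sigs/
creditrl recover --mode params --model tab --n 50 --seed 1 --out rec/
```

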