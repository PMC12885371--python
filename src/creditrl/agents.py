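"""Synthetic choice-making agents on the delayed-reward task.

Generative parameters are drawn from the study-level distributions
(Beta(1, 2) learning rates, Gamma(shape 3, scale 1) strategy weights,
Beta(2, 3) decay rates), agents are simulated forward through the task
with the full two-trial delayed-feedback queue, and whole
counterbalanced synthetic studies can be assembled.  These simulations
are the package's data source: no behavioral recordings ship with it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .models import (
    EligibilityState,
    NormalizationWindow,
    ParamSet,
    TabularState,
    Variant,
    choice_probabilities,
    elig_step,
    tab_prediction_errors,
    tab_update,
)
from .task import (
    Condition,
    N_STIMULI,
    RewardWalk,
    SessionData,
    StimulusSet,
    Trial,
    TrialSchedule,
    generate_reward_walk,
    generate_schedule,
    make_stimulus_set,
    render_feedback,
)

SeedLike = Union[int, np.random.Generator, np.random.SeedSequence]


def _as_seedseq(seed: SeedLike) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, np.random.Generator):
        return np.random.SeedSequence(int(seed.integers(2**63)))
    return np.random.SeedSequence(int(seed))


@dataclass(frozen=True)
class GenerativePrior:
    """Distributions the generative parameters are drawn from.

    The Gamma is shape-scale parameterized (scale = theta).
    """

    alpha_a: float = 1.0
    alpha_b: float = 2.0
    beta_shape: float = 3.0
    beta_scale: float = 1.0
    lambda_a: float = 2.0
    lambda_b: float = 3.0

    @property
    def alpha_dist(self):
        return stats.beta(self.alpha_a, self.alpha_b)

    @property
    def beta_dist(self):
        return stats.gamma(self.beta_shape, scale=self.beta_scale)

    @property
    def lambda_dist(self):
        return stats.beta(self.lambda_a, self.lambda_b)


def _draw_beta_weight(prior: GenerativePrior, rng: np.random.Generator,
                      beta_min: float) -> float:
    """One strategy-weight draw, rejection-sampled above ``beta_min``
    (used when deliberately informative agents are wanted)."""
    while True:
        b = float(prior.beta_dist.rvs(random_state=rng))
        if b > beta_min:
            return b


def sample_params(
    prior: GenerativePrior,
    variant: Variant,
    seed: SeedLike = 0,
    beta_min: float = 0.0,
) -> ParamSet:
    """Independent draws for each free parameter of ``variant``.

    Shared-parameter hybrids draw the tied parameter once.  Draws are
    made in the fixed order of ``variant.free_param_names`` so results
    are seed-deterministic.
    """
    rng = np.random.default_rng(seed)
    values = []
    for name in variant.free_param_names:
        if name.startswith("alpha"):
            values.append(float(prior.alpha_dist.rvs(random_state=rng)))
        elif name.startswith("lambda"):
            values.append(float(prior.lambda_dist.rvs(random_state=rng)))
        else:
            values.append(_draw_beta_weight(prior, rng, beta_min))
    return ParamSet.from_free(variant, values)


def simulate_session(
    params: ParamSet,
    schedule: TrialSchedule,
    walk: RewardWalk,
    stimset: StimulusSet,
    condition: Condition,
    seed: SeedLike = 0,
    participant_id: str = "sim",
    stage: int = 1,
    norm_window: Optional[int] = 5,
    skip_absent_components: bool = False,
) -> SessionData:
    """Run the model forward over a schedule, sampling every choice
    from its softmax distribution and rendering feedback (including
    the two-trial delayed queue)."""
    rng = np.random.default_rng(seed)
    elig = EligibilityState.zeros()
    tab = TabularState.zeros()
    win_v = NormalizationWindow(norm_window)
    win_q = NormalizationWindow(norm_window)
    trials: list[Trial] = []
    choices: list[Optional[int]] = []

    for t, pair in enumerate(schedule.pairs):
        ia, ib = pair
        zv = win_v.normalize(elig.v)
        qsum = tab.summed
        zq = win_q.normalize(qsum)
        pr = choice_probabilities(
            (zv[ia], zv[ib]), (zq[ia], zq[ib]), params.beta_elg, params.beta_tab
        )
        win_v.push(elig.v)
        win_q.push(qsum)
        choice = ia if rng.random() < pr[0] else ib
        a_tm2 = choices[t - 2] if t >= 2 else None
        fb = render_feedback(choice, a_tm2, walk, t, stimset, condition)
        elig = elig_step(elig, choice, fb.total, params.alpha_elg, params.lambda_elg)
        d0, d2 = tab_prediction_errors(tab, choice, a_tm2, fb, skip_absent_components)
        tab = tab_update(tab, choice, a_tm2, d0, d2, params.alpha_tab, params.lambda_tab)
        trials.append(Trial(t, pair, choice, fb))
        choices.append(choice)

    return SessionData(
        participant_id=participant_id,
        condition=condition,
        stage=stage,
        walk_id=walk.walk_id,
        trials=trials,
        stimset=stimset,
        walk=walk,
    )


def simulate_posterior_iterations(
    fitted: Sequence[ParamSet],
    sessions: Sequence[SessionData],
    n_iter: int = 25,
    seed: SeedLike = 0,
    norm_window: Optional[int] = 5,
) -> list[SessionData]:
    """Posterior-predictive regeneration: for each session, replay the
    model ``n_iter`` times on the *same* pair sequence and reward
    trajectory with that session's fitted parameters, sampling fresh
    choices each iteration.  Participant ids are tagged
    ``<id>@iter<k>``."""
    if len(fitted) != len(sessions):
        raise ValueError("need one ParamSet per session")
    child_seeds = _as_seedseq(seed).spawn(len(sessions) * n_iter)
    out: list[SessionData] = []
    idx = 0
    for params, src in zip(fitted, sessions):
        if src.walk is None or src.stimset is None:
            raise ValueError("source sessions must carry their walk and stimulus set")
        schedule = TrialSchedule(tuple(tr.pair for tr in src.trials), seed=-1)
        for it in range(n_iter):
            sim = simulate_session(
                params, schedule, src.walk, src.stimset, src.condition,
                seed=child_seeds[idx],
                participant_id=f"{src.participant_id}@iter{it}",
                stage=src.stage,
                norm_window=norm_window,
            )
            out.append(sim)
            idx += 1
    return out


@dataclass
class ParticipantRecord:
    participant_id: str
    sessions: list[SessionData]     # stage order: [stage 1, stage 2]
    params: list[ParamSet]          # generative parameters per session


@dataclass
class SyntheticStudy:
    stimset: StimulusSet
    walks: list[RewardWalk]
    participants: list[ParticipantRecord]

    @property
    def sessions(self) -> list[SessionData]:
        return [s for p in self.participants for s in p.sessions]


def generate_study(
    n_participants: int,
    n_walks: int = 3,
    seed: SeedLike = 0,
    variant: Variant = Variant.HYBRID,
    prior: GenerativePrior = GenerativePrior(),
    n_repeats: int = 12,
    step_scale: float = 0.5,
    norm_window: Optional[int] = 5,
    shared_params: bool = False,
    beta_min: float = 0.0,
) -> SyntheticStudy:
    """Assemble a counterbalanced synthetic study.

    Each participant completes one session per condition; half the
    cohort (rounded up) starts with disjoint.  Every session draws an
    independent uniform walk assignment and (unless ``shared_params``)
    an independent generative parameter set.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    stim_ss, walk_ss, part_ss = _as_seedseq(seed).spawn(3)
    n_stim = N_STIMULI
    n_trials = n_stim * (n_stim - 1) // 2 * n_repeats
    stimset = make_stimulus_set(int(stim_ss.generate_state(1)[0]) % 2**31)
    walk_seeds = walk_ss.spawn(n_walks)
    walks = [
        generate_reward_walk(stimset, n_trials, step_scale, seed=ws, walk_id=i + 1)
        for i, ws in enumerate(walk_seeds)
    ]
    participants: list[ParticipantRecord] = []
    for i, pss in enumerate(part_ss.spawn(n_participants)):
        rng = np.random.default_rng(pss)
        disjoint_first = i % 2 == 0
        order = (
            (Condition.DISJOINT, Condition.CONJOINT)
            if disjoint_first
            else (Condition.CONJOINT, Condition.DISJOINT)
        )
        shared = sample_params(prior, variant, rng, beta_min) if shared_params else None
        sessions, plist = [], []
        for stage, cond in enumerate(order, start=1):
            params = shared if shared is not None else sample_params(prior, variant, rng, beta_min)
            schedule = generate_schedule(n_stim, n_repeats, seed=int(rng.integers(2**31)))
            walk = walks[rng.integers(n_walks)]
            sessions.append(
                simulate_session(
                    params, schedule, walk, stimset, cond,
                    seed=rng, participant_id=f"p{i:03d}", stage=stage,
                    norm_window=norm_window,
                )
            )
            plist.append(params)
        participants.append(ParticipantRecord(f"p{i:03d}", sessions, plist))
    return SyntheticStudy(stimset, walks, participants)
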