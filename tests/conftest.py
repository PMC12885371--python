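import numpy as np
import pytest

from creditrl.task import (
    Condition,
    DelayClass,
    RewardWalk,
    SessionData,
    Stimulus,
    StimulusSet,
    Trial,
    generate_reward_walk,
    generate_schedule,
    make_stimulus_set,
    render_feedback,
)


@pytest.fixture(scope="session")
def canonical_stimset() -> StimulusSet:
    """Deterministic stimulus set: ids 0-3 immediate, 4-7 delayed, start
    values (4, 1, -1, -4) in id order within each class."""
    vals = (4, 1, -1, -4)
    stimuli = tuple(
        Stimulus(i, DelayClass.IMMEDIATE if i < 4 else DelayClass.DELAYED, vals[i % 4])
        for i in range(8)
    )
    return StimulusSet(stimuli)


@pytest.fixture(scope="session")
def flat_walk(canonical_stimset) -> RewardWalk:
    """Zero-drift walk: rewards stay at the start values forever."""
    n = 40
    latent = np.tile(canonical_stimset.start_values.astype(float), (n, 1))
    return RewardWalk(1, latent, latent.astype(int), step_scale=0.5)


def build_session(stimset, walk, choices, pairs, condition) -> SessionData:
    """Hand-build a session from explicit choices, rendering feedback
    with the real delayed queue."""
    trials = []
    for t, (pair, choice) in enumerate(zip(pairs, choices)):
        a_tm2 = choices[t - 2] if t >= 2 else None
        fb = None
        if choice is not None:
            fb = render_feedback(choice, a_tm2, walk, t, stimset, condition)
        trials.append(Trial(t, pair, choice, fb))
    return SessionData("hand", condition, 1, walk.walk_id, trials,
                       stimset=stimset, walk=walk)


@pytest.fixture(scope="session")
def hand_session_factory(canonical_stimset, flat_walk):
    """Five-trial hand-built session mixing immediate (0, 1) and
    delayed (4, 5) stimuli, for either condition."""

    def make(condition: Condition) -> SessionData:
        pairs = [(0, 4), (1, 5), (0, 5), (1, 4), (0, 4)]
        choices = [4, 1, 5, 4, 0]
        return build_session(canonical_stimset, flat_walk, choices, pairs, condition)

    return make


@pytest.fixture(scope="session")
def simulated_session_factory():
    """Prior-style simulated sessions on freshly generated task objects."""
    from creditrl.agents import simulate_session
    from creditrl.models import ParamSet, Variant

    def make(seed: int, condition=Condition.DISJOINT, params=None, n_repeats=12):
        stimset = make_stimulus_set(seed)
        schedule = generate_schedule(8, n_repeats, seed=seed + 1)
        walk = generate_reward_walk(stimset, schedule.n_trials, seed=seed + 2)
        if params is None:
            params = ParamSet(0.3, 0.6, 3.0, 0.35, 0.5, 3.0, Variant.HYBRID)
        return simulate_session(params, schedule, walk, stimset, condition, seed=seed + 3)

    return make
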