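"""Delayed-reward two-alternative task environment.

Eight stimuli, four paying out immediately and four with a two-trial
delay, carry integer rewards that drift over the session as rounded
Gaussian random walks.  Every unique pair of stimuli is offered a fixed
number of times in random order; feedback is rendered either as a single
summed total (*conjoint*) or as separate immediate and delayed
components (*disjoint*).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

START_VALUES = (4, 1, -1, -4)
N_STIMULI = 8
DELAY_TRIALS = 2  #: lag, in trials, of delayed-class payouts


class DelayClass(Enum):
    IMMEDIATE = 0
    DELAYED = 2


class Condition(Enum):
    CONJOINT = "conjoint"
    DISJOINT = "disjoint"


@dataclass(frozen=True)
class Stimulus:
    id: int
    delay_class: DelayClass
    start_value: int


@dataclass(frozen=True)
class StimulusSet:
    """The 8 task stimuli: 4 immediate and 4 delayed, start values
    {4, 1, -1, -4} each used once within each delay class."""

    stimuli: tuple[Stimulus, ...]

    def __post_init__(self) -> None:
        if len(self.stimuli) != N_STIMULI:
            raise ValueError(f"expected {N_STIMULI} stimuli, got {len(self.stimuli)}")
        for cls in DelayClass:
            vals = sorted(s.start_value for s in self.stimuli if s.delay_class is cls)
            if vals != sorted(START_VALUES):
                raise ValueError(
                    f"start values within {cls.name} must be a permutation of {START_VALUES}"
                )

    def __getitem__(self, stimulus_id: int) -> Stimulus:
        return self.stimuli[stimulus_id]

    def is_delayed(self, stimulus_id: int) -> bool:
        return self.stimuli[stimulus_id].delay_class is DelayClass.DELAYED

    @property
    def start_values(self) -> np.ndarray:
        return np.array([s.start_value for s in self.stimuli])

    @property
    def delayed_ids(self) -> tuple[int, ...]:
        return tuple(s.id for s in self.stimuli if s.delay_class is DelayClass.DELAYED)


@dataclass(frozen=True)
class RewardWalk:
    """Latent Gaussian random-walk reward states and their integer
    (delivered) projection, one column per stimulus."""

    walk_id: int
    latent: np.ndarray  # (n_trials, 8) float
    delivered: np.ndarray  # (n_trials, 8) int
    step_scale: float

    @property
    def n_trials(self) -> int:
        return self.latent.shape[0]


@dataclass(frozen=True)
class TrialSchedule:
    pairs: tuple[tuple[int, int], ...]
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class FeedbackRecord:
    """What the feedback screen showed on one trial.

    ``immediate_component`` is the current choice's payout when that
    choice was immediate-class; ``delayed_component`` is the payout of a
    delayed-class choice made two trials earlier, arriving now.  In the
    conjoint condition only ``total`` is visible to the learner; in
    disjoint both components are shown separately.
    """

    immediate_component: Optional[int]
    delayed_component: Optional[int]
    total: int
    condition: Condition

    def __post_init__(self) -> None:
        expect = (self.immediate_component or 0) + (self.delayed_component or 0)
        if self.total != expect:
            raise ValueError(f"total {self.total} != sum of components {expect}")


@dataclass(frozen=True)
class Trial:
    t: int
    pair: tuple[int, int]
    choice: Optional[int]
    feedback: Optional[FeedbackRecord]

    def __post_init__(self) -> None:
        if self.choice is not None and self.choice not in self.pair:
            raise ValueError(f"choice {self.choice} not in offered pair {self.pair}")


@dataclass
class SessionData:
    participant_id: str
    condition: Condition
    stage: int
    walk_id: int
    trials: list[Trial]
    stimset: StimulusSet = None  # type: ignore[assignment]
    walk: Optional[RewardWalk] = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_responded(self) -> int:
        return sum(1 for tr in self.trials if tr.choice is not None)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (symmetric around
    the negative start values; numpy's default rounds halves to even)."""
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


def make_stimulus_set(seed: int) -> StimulusSet:
    """Build the 8-stimulus set with a seed-determined assignment of
    delay classes to ids and of start values within each class."""
    rng = np.random.default_rng(seed)
    ids = rng.permutation(N_STIMULI)
    imm_ids, del_ids = ids[:4], ids[4:]
    stimuli: list[Optional[Stimulus]] = [None] * N_STIMULI
    for class_ids, cls in ((imm_ids, DelayClass.IMMEDIATE), (del_ids, DelayClass.DELAYED)):
        values = rng.permutation(START_VALUES)
        for sid, val in zip(class_ids, values):
            stimuli[sid] = Stimulus(int(sid), cls, int(val))
    return StimulusSet(tuple(stimuli))  # type: ignore[arg-type]


def generate_reward_walk(
    stimset: StimulusSet,
    n_trials: int,
    step_scale: float = 0.5,
    seed: int = 0,
    walk_id: int = 1,
) -> RewardWalk:
    """Gaussian random walk of each stimulus's reward.

    The latent walk starts at the stimulus start values and accumulates
    i.i.d. zero-mean Gaussian steps with standard deviation
    ``step_scale`` (default 0.5, i.e. step variance 0.25); the delivered
    rewards are the latent states rounded to the nearest integer, halves
    away from zero.
    """
    if step_scale <= 0:
        raise ValueError("step_scale must be positive")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, step_scale, size=(n_trials - 1, N_STIMULI))
    latent = np.vstack([stimset.start_values.astype(float), steps]).cumsum(axis=0)
    return RewardWalk(walk_id, latent, _round_half_away(latent), step_scale)


def generate_schedule(n_stimuli: int = 8, n_repeats: int = 12, seed: int = 0) -> TrialSchedule:
    """Uniformly shuffled schedule containing every distinct unordered
    pair of stimuli exactly ``n_repeats`` times (8 stimuli x 12 repeats
    gives the default 336-trial session)."""
    if n_stimuli < 2:
        raise ValueError("need at least 2 stimuli")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(range(n_stimuli), 2)) * n_repeats
    order = rng.permutation(len(pairs))
    return TrialSchedule(tuple(pairs[i] for i in order), seed)


def render_feedback(
    choice_t: Optional[int],
    choice_tm2: Optional[int],
    walk: RewardWalk,
    t: int,
    stimset: StimulusSet,
    condition: Condition,
) -> FeedbackRecord:
    """Render one trial's feedback screen.

    The immediate component is the current choice's delivered reward at
    ``t`` when that choice is immediate-class; the delayed component is
    the ``t-2`` choice's delivered reward *at t-2* when that earlier
    choice is delayed-class.  Absent components are ``None`` (shown as
    an empty box / contributing 0 to the total).
    """
    if not 0 <= t < walk.n_trials:
        raise IndexError(f"trial {t} outside walk of length {walk.n_trials}")
    imm: Optional[int] = None
    dly: Optional[int] = None
    if choice_t is not None and not stimset.is_delayed(choice_t):
        imm = int(walk.delivered[t, choice_t])
    if choice_tm2 is not None and stimset.is_delayed(choice_tm2):
        if t - DELAY_TRIALS < 0:
            raise ValueError("delayed-class choice supplied before trial 2")
        dly = int(walk.delivered[t - DELAY_TRIALS, choice_tm2])
    return FeedbackRecord(imm, dly, (imm or 0) + (dly or 0), condition)


# ---------------------------------------------------------------------------
# Trial-table I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "participant_id", "condition", "stage", "walk_id", "t",
    "pair_a", "pair_b", "choice", "imm_feedback", "del_feedback", "total_feedback",
]


def sessions_to_frame(sessions: Iterable[SessionData]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for tr in s.trials:
            fb = tr.feedback
            rows.append({
                "participant_id": s.participant_id,
                "condition": s.condition.value,
                "stage": s.stage,
                "walk_id": s.walk_id,
                "t": tr.t,
                "pair_a": tr.pair[0],
                "pair_b": tr.pair[1],
                "choice": tr.choice,
                "imm_feedback": None if fb is None else fb.immediate_component,
                "del_feedback": None if fb is None else fb.delayed_component,
                "total_feedback": None if fb is None else fb.total,
            })
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_sessions(sessions: Sequence[SessionData], path) -> None:
    """Write sessions as a trial-level CSV (empty cell = absent
    component / omitted choice)."""
    sessions_to_frame(sessions).to_csv(path, index=False)


def stimset_to_frame(stimset: StimulusSet) -> pd.DataFrame:
    return pd.DataFrame(
        [{"id": s.id, "delay_class": s.delay_class.name.lower(), "start_value": s.start_value}
         for s in stimset.stimuli]
    )


def frame_to_stimset(df: pd.DataFrame) -> StimulusSet:
    stimuli = [None] * len(df)
    for _, row in df.iterrows():
        stimuli[int(row.id)] = Stimulus(
            int(row.id), DelayClass[str(row.delay_class).upper()], int(row.start_value)
        )
    return StimulusSet(tuple(stimuli))  # type: ignore[arg-type]


def walks_to_frame(walks: Sequence[RewardWalk]) -> pd.DataFrame:
    rows = []
    for w in walks:
        for t in range(w.n_trials):
            for s in range(w.latent.shape[1]):
                rows.append({"walk_id": w.walk_id, "t": t, "stimulus": s,
                             "latent": w.latent[t, s], "delivered": w.delivered[t, s],
                             "step_scale": w.step_scale})
    return pd.DataFrame(rows)


def frame_to_walks(df: pd.DataFrame) -> list[RewardWalk]:
    walks = []
    for wid, grp in df.groupby("walk_id", sort=True):
        piv_lat = grp.pivot(index="t", columns="stimulus", values="latent").sort_index()
        piv_del = grp.pivot(index="t", columns="stimulus", values="delivered").sort_index()
        walks.append(RewardWalk(int(wid), piv_lat.to_numpy(float),
                                piv_del.to_numpy(int), float(grp.step_scale.iloc[0])))
    return walks


def _opt_int(value) -> Optional[int]:
    return None if pd.isna(value) else int(value)


def read_sessions(path) -> list[SessionData]:
    """Read a trial-level CSV back into :class:`SessionData` objects.

    Raises ``ValueError`` naming the offending row on schema violations
    (missing columns, a choice outside the offered pair, or an unknown
    condition label).
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    sessions: list[SessionData] = []
    for (pid, cond, stage, walk_id), grp in df.groupby(
        ["participant_id", "condition", "stage", "walk_id"], sort=False
    ):
        try:
            condition = Condition(cond)
        except ValueError:
            raise ValueError(f"unknown condition label {cond!r}") from None
        trials = []
        for idx, row in grp.sort_values("t").iterrows():
            pair = (int(row.pair_a), int(row.pair_b))
            choice = _opt_int(row.choice)
            if choice is not None and choice not in pair:
                raise ValueError(f"row {idx}: choice {choice} not in pair {pair}")
            total = _opt_int(row.total_feedback)
            fb = None
            if total is not None:
                fb = FeedbackRecord(
                    _opt_int(row.imm_feedback), _opt_int(row.del_feedback), total, condition
                )
            trials.append(Trial(int(row.t), pair, choice, fb))
        sessions.append(SessionData(str(pid), condition, int(stage), int(walk_id), trials))
    return sessions
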