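"""Eligibility-trace, tabular, and hybrid learning models.

Two strategies for assigning credit when rewards arrive with a delay:

* **Eligibility trace** (retrospective): a single prediction error
  between the displayed total reward and the value of the current
  choice, propagated backwards over recent selections through a
  replacing trace that decays geometrically (``lambda_elg``).
* **Tabular** (prospective): delay-indexed values ``Q(d, a)`` for
  ``d in {0, 2}``.  Two prediction errors update the current choice
  (``d=0``) and the choice made two trials back (``d=2``), skipping the
  one-trial lag entirely; the ``d=2`` update is scaled by
  ``lambda_tab``.

At decision time each strategy's value vector is z-scored against a
short window of its own recent history, and a softmax combines the two
normalized values through per-strategy weights ``beta_elg`` and
``beta_tab``.  Setting either weight to zero reduces the hybrid to the
other single-strategy model.

The module exposes the individual update steps (reference path) plus a
population-vectorized likelihood used by the fitting routines; the two
paths are interchangeable and agree to machine precision.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .task import Condition, FeedbackRecord, SessionData, N_STIMULI

PROB_FLOOR = 1e-12  #: floor inside log() during optimizer exploration

_SLOT = {0: 0, 2: 1}  # delay d -> row of the Q table


class Variant(Enum):
    """Model variants; the shared-parameter hybrids tie learning rates
    (1L) or learning and decay rates (1D) across strategies."""

    ELIGIBILITY = "eligibility"
    TABULAR = "tabular"
    HYBRID = "hybrid"
    HYBRID_1L = "hybrid_1l"
    HYBRID_1D = "hybrid_1d"

    @property
    def free_param_names(self) -> tuple[str, ...]:
        return _FREE_PARAMS[self]

    @property
    def k(self) -> int:
        return len(_FREE_PARAMS[self])


_FREE_PARAMS = {
    Variant.ELIGIBILITY: ("alpha_elg", "lambda_elg", "beta_elg"),
    Variant.TABULAR: ("alpha_tab", "lambda_tab", "beta_tab"),
    Variant.HYBRID: ("alpha_elg", "lambda_elg", "beta_elg",
                     "alpha_tab", "lambda_tab", "beta_tab"),
    Variant.HYBRID_1L: ("alpha", "lambda_elg", "beta_elg", "lambda_tab", "beta_tab"),
    Variant.HYBRID_1D: ("alpha", "lambda", "beta_elg", "beta_tab"),
}


@dataclass(frozen=True)
class ParamSet:
    """The six model parameters.

    Learning rates (``alpha``) and decay rates (``lambda``) live in
    [0, 1]; strategy weights (``beta``) are non-negative softmax
    inverse-temperature-like coefficients.
    """

    alpha_elg: float = 0.0
    lambda_elg: float = 0.0
    beta_elg: float = 0.0
    alpha_tab: float = 0.0
    lambda_tab: float = 0.0
    beta_tab: float = 0.0
    variant: Variant = Variant.HYBRID

    def __post_init__(self) -> None:
        for name in ("alpha_elg", "lambda_elg", "alpha_tab", "lambda_tab"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
        if self.beta_elg < 0 or self.beta_tab < 0:
            raise ValueError("strategy weights must be non-negative")
        if self.variant is Variant.ELIGIBILITY and self.beta_tab != 0.0:
            raise ValueError("eligibility variant requires beta_tab = 0")
        if self.variant is Variant.TABULAR and self.beta_elg != 0.0:
            raise ValueError("tabular variant requires beta_elg = 0")
        if self.variant in (Variant.HYBRID_1L, Variant.HYBRID_1D):
            if self.alpha_elg != self.alpha_tab:
                raise ValueError(f"{self.variant.value} requires a shared learning rate")
        if self.variant is Variant.HYBRID_1D and self.lambda_elg != self.lambda_tab:
            raise ValueError("hybrid_1d requires a shared decay rate")

    @property
    def free_values(self) -> np.ndarray:
        vals = []
        for name in self.variant.free_param_names:
            if name == "alpha":
                vals.append(self.alpha_elg)
            elif name == "lambda":
                vals.append(self.lambda_elg)
            else:
                vals.append(getattr(self, name))
        return np.array(vals)

    @classmethod
    def from_free(cls, variant: Variant, values: Sequence[float]) -> "ParamSet":
        """Expand a free-parameter vector (ordering per
        ``variant.free_param_names``) into a full ParamSet."""
        names = variant.free_param_names
        if len(values) != len(names):
            raise ValueError(f"expected {len(names)} values for {variant.value}")
        d = dict(zip(names, (float(v) for v in values)))
        kw = dict(alpha_elg=0.0, lambda_elg=0.0, beta_elg=0.0,
                  alpha_tab=0.0, lambda_tab=0.0, beta_tab=0.0)
        if "alpha" in d:
            kw["alpha_elg"] = kw["alpha_tab"] = d.pop("alpha")
        if "lambda" in d:
            kw["lambda_elg"] = kw["lambda_tab"] = d.pop("lambda")
        kw.update(d)
        return cls(variant=variant, **kw)

    def as_vector(self) -> np.ndarray:
        """Full 6-vector (alpha_elg, lambda_elg, beta_elg, alpha_tab,
        lambda_tab, beta_tab) regardless of variant."""
        return np.array([self.alpha_elg, self.lambda_elg, self.beta_elg,
                         self.alpha_tab, self.lambda_tab, self.beta_tab])


@dataclass
class EligibilityState:
    v: np.ndarray  # (8,) action values
    e: np.ndarray  # (8,) replacing traces in [0, 1]

    @classmethod
    def zeros(cls, n_actions: int = N_STIMULI) -> "EligibilityState":
        return cls(np.zeros(n_actions), np.zeros(n_actions))


@dataclass
class TabularState:
    Q: np.ndarray  # (2, 8): row 0 = delay slot d=0, row 1 = d=2

    @classmethod
    def zeros(cls, n_actions: int = N_STIMULI) -> "TabularState":
        return cls(np.zeros((2, n_actions)))

    @property
    def summed(self) -> np.ndarray:
        """Decision value per action: sum over delay slots."""
        return self.Q.sum(axis=0)


def elig_step(
    state: EligibilityState, chosen: int, total_reward: float, alpha: float, lam: float
) -> EligibilityState:
    """One eligibility-trace update.

    The prediction error ``delta = r - v(chosen)`` uses pre-update
    values; the chosen action's trace is replaced with 1 while all
    other traces decay by ``lam``; every action is then updated by
    ``alpha * delta * e``.
    """
    delta = total_reward - state.v[chosen]
    e = state.e * lam
    e[chosen] = 1.0
    v = state.v + alpha * delta * e
    return EligibilityState(v, e)


def decay_traces(state: EligibilityState, lam: float) -> EligibilityState:
    """Trace decay for an omitted-response trial: time passes but no
    selection replaces a trace and no value update occurs."""
    return EligibilityState(state.v.copy(), state.e * lam)


def tab_prediction_errors(
    state: TabularState,
    a_t: Optional[int],
    a_tm2: Optional[int],
    feedback: FeedbackRecord,
    skip_absent_components: bool = False,
) -> tuple[Optional[float], Optional[float]]:
    """The tabular model's two prediction errors.

    Conjoint: both errors compare the same displayed total against
    ``Q(0, a_t)`` and ``Q(2, a_tm2)``.  Disjoint: the displayed
    immediate component (0 when the box is empty) is compared with
    ``Q(0, a_t)`` and the displayed delayed component with
    ``Q(2, a_tm2)``.  With ``skip_absent_components`` an empty disjoint
    box produces no error instead of a 0-target one.
    """
    delta0 = delta2 = None
    conjoint = feedback.condition is Condition.CONJOINT
    if a_t is not None:
        if conjoint:
            delta0 = feedback.total - state.Q[0, a_t]
        elif feedback.immediate_component is not None or not skip_absent_components:
            delta0 = (feedback.immediate_component or 0) - state.Q[0, a_t]
    if a_tm2 is not None:
        if conjoint:
            delta2 = feedback.total - state.Q[1, a_tm2]
        elif feedback.delayed_component is not None or not skip_absent_components:
            delta2 = (feedback.delayed_component or 0) - state.Q[1, a_tm2]
    return delta0, delta2


def tab_update(
    state: TabularState,
    a_t: Optional[int],
    a_tm2: Optional[int],
    delta0: Optional[float],
    delta2: Optional[float],
    alpha: float,
    lam: float,
) -> TabularState:
    """Apply the tabular updates: full-rate at ``d=0``, decay-scaled
    (``alpha * lam``) at ``d=2``; the one-trial lag is never touched."""
    Q = state.Q.copy()
    if delta0 is not None and a_t is not None:
        Q[0, a_t] += alpha * delta0
    if delta2 is not None and a_tm2 is not None:
        Q[1, a_tm2] += alpha * lam * delta2
    return TabularState(Q)


class NormalizationWindow:
    """Rolling z-normalization of a value vector against its own recent
    history.

    The buffer holds the decision-time value vectors of the previous
    ``window`` trials; z-scoring pools the mean and (population)
    standard deviation over every entry in the buffer.  ``window=0``
    disables scaling; ``window=None`` pools over the whole task so far.
    An empty buffer leaves values raw and a zero spread falls back to
    centering only.
    """

    def __init__(self, window: Optional[int] = 5):
        if window is not None and window < 0:
            raise ValueError("window must be >= 0 (or None for whole-task)")
        self.window = window
        self.buffer: deque[np.ndarray] = deque(maxlen=window if window else None)

    @property
    def disabled(self) -> bool:
        return self.window == 0

    def normalize(self, current: np.ndarray) -> np.ndarray:
        if self.disabled or not self.buffer:
            return np.asarray(current, dtype=float).copy()
        pool = np.concatenate([snap.ravel() for snap in self.buffer])
        m = pool.mean()
        s = pool.std()
        if s == 0.0:
            s = 1.0
        return (np.asarray(current, dtype=float) - m) / s

    def push(self, snapshot: np.ndarray) -> None:
        if self.disabled:
            return
        self.buffer.append(np.asarray(snapshot, dtype=float).copy())

    def copy(self) -> "NormalizationWindow":
        new = NormalizationWindow(self.window)
        new.buffer.extend(snap.copy() for snap in self.buffer)
        return new


def choice_probabilities(
    z_elg: Sequence[float], z_tab_sum: Sequence[float], beta_elg: float, beta_tab: float
) -> np.ndarray:
    """Softmax over the two offered options of the weighted sum of the
    normalized strategy values."""
    util = beta_elg * np.asarray(z_elg, dtype=float) + beta_tab * np.asarray(z_tab_sum, dtype=float)
    if not np.all(np.isfinite(util)):
        raise ValueError("non-finite decision utilities")
    util = util - util.max()
    expu = np.exp(util)
    return expu / expu.sum()


@dataclass
class ModelRun:
    """Per-trial output of a forward model pass over a session.

    ``v_traj``/``qsum_traj`` hold decision-time value vectors for each
    trial plus the post-session state in the last row, so
    ``traj[t + 1] - traj[t]`` is the update applied between trials.
    """

    probs: np.ndarray          # (n, 2) choice probabilities for (pair_a, pair_b)
    p_chosen: np.ndarray       # (n,) probability of the made choice; nan if omitted
    v_traj: np.ndarray         # (n + 1, 8)
    e_traj: np.ndarray         # (n + 1, 8)
    qsum_traj: np.ndarray      # (n + 1, 8)
    delta_elg: np.ndarray      # (n,) eligibility prediction error; nan if omitted
    delta_tab0: np.ndarray     # (n,) tabular d=0 prediction error; nan if absent

    @property
    def nll(self) -> float:
        p = self.p_chosen[~np.isnan(self.p_chosen)]
        return float(-np.log(np.maximum(p, PROB_FLOOR)).sum())


def run_model(
    session: SessionData,
    params: ParamSet,
    norm_window: Optional[int] = 5,
    skip_absent_components: bool = False,
) -> ModelRun:
    """Forward pass of the hybrid model over a recorded session.

    Iterates trials in order: normalize each strategy's decision values
    over its own recent-history window, form choice probabilities, then
    apply the eligibility update with the displayed total (both
    conditions) and the tabular updates with condition-appropriate
    targets.  Omitted-response trials contribute no likelihood term and
    no value update; traces still decay.  Single-strategy variants are
    the special cases ``beta_tab = 0`` / ``beta_elg = 0``.
    """
    n = session.n_trials
    elig = EligibilityState.zeros()
    tab = TabularState.zeros()
    win_v = NormalizationWindow(norm_window)
    win_q = NormalizationWindow(norm_window)
    probs = np.full((n, 2), np.nan)
    p_chosen = np.full(n, np.nan)
    v_traj = np.zeros((n + 1, N_STIMULI))
    e_traj = np.zeros((n + 1, N_STIMULI))
    qsum_traj = np.zeros((n + 1, N_STIMULI))
    delta_elg = np.full(n, np.nan)
    delta_tab0 = np.full(n, np.nan)

    for t, trial in enumerate(session.trials):
        v_traj[t] = elig.v
        e_traj[t] = elig.e
        qsum = tab.summed
        qsum_traj[t] = qsum
        zv = win_v.normalize(elig.v)
        zq = win_q.normalize(qsum)
        ia, ib = trial.pair
        pr = choice_probabilities(
            (zv[ia], zv[ib]), (zq[ia], zq[ib]), params.beta_elg, params.beta_tab
        )
        probs[t] = pr
        win_v.push(elig.v)
        win_q.push(qsum)

        if trial.choice is None:
            elig = decay_traces(elig, params.lambda_elg)
            continue
        p_chosen[t] = pr[0] if trial.choice == ia else pr[1]
        fb = trial.feedback
        if fb is None:
            raise ValueError(f"trial {t}: responded trial without feedback")
        delta_elg[t] = fb.total - elig.v[trial.choice]
        elig = elig_step(elig, trial.choice, fb.total, params.alpha_elg, params.lambda_elg)
        a_tm2 = session.trials[t - 2].choice if t >= 2 else None
        d0, d2 = tab_prediction_errors(tab, trial.choice, a_tm2, fb, skip_absent_components)
        if d0 is not None:
            delta_tab0[t] = d0
        tab = tab_update(tab, trial.choice, a_tm2, d0, d2,
                         params.alpha_tab, params.lambda_tab)

    v_traj[n] = elig.v
    e_traj[n] = elig.e
    qsum_traj[n] = tab.summed
    return ModelRun(probs, p_chosen, v_traj, e_traj, qsum_traj, delta_elg, delta_tab0)


# ---------------------------------------------------------------------------
# Population-vectorized likelihood (fast path for the evolutionary fit)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionArrays:
    """Flat per-trial arrays extracted once from a session, so the
    likelihood can be evaluated for a whole candidate population in a
    single pass over trials."""

    n_trials: int
    conjoint: bool
    pair_a: np.ndarray
    pair_b: np.ndarray
    choice: np.ndarray       # -1 for omitted responses
    choice_tm2: np.ndarray   # -1 when no two-back choice exists
    responded: np.ndarray    # bool
    r_total: np.ndarray
    r_imm: np.ndarray        # 0 when the immediate box is empty
    has_imm: np.ndarray      # bool
    r_del: np.ndarray
    has_del: np.ndarray

    @classmethod
    def from_session(cls, session: SessionData) -> "SessionArrays":
        n = session.n_trials
        pair_a = np.empty(n, dtype=int)
        pair_b = np.empty(n, dtype=int)
        choice = np.full(n, -1, dtype=int)
        r_total = np.zeros(n)
        r_imm = np.zeros(n)
        r_del = np.zeros(n)
        has_imm = np.zeros(n, dtype=bool)
        has_del = np.zeros(n, dtype=bool)
        for t, tr in enumerate(session.trials):
            pair_a[t], pair_b[t] = tr.pair
            if tr.choice is not None:
                choice[t] = tr.choice
                fb = tr.feedback
                if fb is not None:
                    r_total[t] = fb.total
                    if fb.immediate_component is not None:
                        r_imm[t] = fb.immediate_component
                        has_imm[t] = True
                    if fb.delayed_component is not None:
                        r_del[t] = fb.delayed_component
                        has_del[t] = True
        choice_tm2 = np.full(n, -1, dtype=int)
        choice_tm2[2:] = choice[:-2]
        return cls(
            n_trials=n,
            conjoint=session.condition is Condition.CONJOINT,
            pair_a=pair_a, pair_b=pair_b,
            choice=choice, choice_tm2=choice_tm2, responded=choice >= 0,
            r_total=r_total, r_imm=r_imm, has_imm=has_imm,
            r_del=r_del, has_del=has_del,
        )


def _pooled_z_cols(cur: np.ndarray, buf: np.ndarray, count: int,
                   cols: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """z-score of two columns of ``cur`` (S, 8) against the filled part
    of a (W, S, 8) snapshot buffer, pooled over window x actions."""
    ia, ib = cols
    if count == 0:
        return cur[:, ia], cur[:, ib]
    sub = buf[:count]
    m = sub.mean(axis=(0, 2))
    s = sub.std(axis=(0, 2))
    s = np.where(s > 0.0, s, 1.0)
    return (cur[:, ia] - m) / s, (cur[:, ib] - m) / s


def population_nll(
    theta: np.ndarray,
    arrays: SessionArrays,
    norm_window: Optional[int] = 5,
    skip_absent_components: bool = False,
) -> np.ndarray:
    """Negative log-likelihood of one session for a population of full
    parameter vectors.

    ``theta`` has shape (S, 6) with columns (alpha_elg, lambda_elg,
    beta_elg, alpha_tab, lambda_tab, beta_tab).  Semantically identical
    to summing ``-log p_chosen`` from :func:`run_model` per row; kept
    separate purely for speed during optimization.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    S = theta.shape[0]
    a_e, l_e, b_e = theta[:, 0], theta[:, 1], theta[:, 2]
    a_t, l_t, b_t = theta[:, 3], theta[:, 4], theta[:, 5]
    n = arrays.n_trials
    disabled = norm_window == 0
    W = n if (norm_window is None or disabled) else norm_window
    v = np.zeros((S, N_STIMULI))
    e = np.zeros((S, N_STIMULI))
    Q0 = np.zeros((S, N_STIMULI))
    Q2 = np.zeros((S, N_STIMULI))
    buf_v = np.empty((W, S, N_STIMULI))
    buf_q = np.empty((W, S, N_STIMULI))
    count = 0
    head = 0
    logp = np.zeros(S)
    conjoint = arrays.conjoint
    skip = skip_absent_components

    for t in range(n):
        ia = arrays.pair_a[t]
        ib = arrays.pair_b[t]
        responded = arrays.responded[t]
        if responded:
            qsum = Q0 + Q2
            if disabled:
                zv_a, zv_b = v[:, ia], v[:, ib]
                zq_a, zq_b = qsum[:, ia], qsum[:, ib]
            else:
                zv_a, zv_b = _pooled_z_cols(v, buf_v, count, (ia, ib))
                zq_a, zq_b = _pooled_z_cols(qsum, buf_q, count, (ia, ib))
            u_a = b_e * zv_a + b_t * zq_a
            u_b = b_e * zv_b + b_t * zq_b
            ch = arrays.choice[t]
            gap = (u_b - u_a) if ch == ia else (u_a - u_b)
            p = 1.0 / (1.0 + np.exp(gap))
            logp += np.log(np.maximum(p, PROB_FLOOR))
        if not disabled:
            qsum = Q0 + Q2
            buf_v[head] = v
            buf_q[head] = qsum
            head = (head + 1) % W
            count = min(count + 1, W)
        if not responded:
            e *= l_e[:, None]
            continue
        ch = arrays.choice[t]
        delta = arrays.r_total[t] - v[:, ch]
        e *= l_e[:, None]
        e[:, ch] = 1.0
        v += (a_e * delta)[:, None] * e
        if conjoint:
            Q0[:, ch] += a_t * (arrays.r_total[t] - Q0[:, ch])
        elif arrays.has_imm[t] or not skip:
            Q0[:, ch] += a_t * (arrays.r_imm[t] - Q0[:, ch])
        tm2 = arrays.choice_tm2[t]
        if tm2 >= 0:
            if conjoint:
                Q2[:, tm2] += a_t * l_t * (arrays.r_total[t] - Q2[:, tm2])
            elif arrays.has_del[t] or not skip:
                Q2[:, tm2] += a_t * l_t * (arrays.r_del[t] - Q2[:, tm2])
    return -logp
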