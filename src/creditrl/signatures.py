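"""Behavioral metrics and credit-assignment signature analyses.

Covers: optimal-choice / average-outcome metrics, extraction of
delayed-choice reappearance ("stay/switch") events and their logistic
regression on condition x time x reward valence, per-pair-type
predictive accuracy of model-generated choices, regression of observed
choices on model-predicted probabilities, the credit-assignment
gradient over recent selections, and paired condition contrasts of
fitted parameters.

The regressions here are pooled fixed-effects logistic models (with
the option of subject-clustered standard errors), a deliberate
simplification of random-slope multilevel structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .fitting import FitResult
from .models import ParamSet, Variant, run_model
from .task import Condition, SessionData

PARAM_NAMES = ("alpha_elg", "lambda_elg", "beta_elg", "alpha_tab", "lambda_tab", "beta_tab")


# ---------------------------------------------------------------------------
# Behavioral metrics
# ---------------------------------------------------------------------------


def behavioral_metrics(session: SessionData) -> dict[str, float]:
    """Proportion of optimal choices and mean obtained outcome.

    A trial is optimal when the chosen stimulus's delivered walk value
    at that trial is at least the other option's (ties count as
    optimal: no wrong answer exists).  The average outcome is the
    chosen option's generative reward at the choice trial, averaged
    over responded trials.
    """
    if session.walk is None:
        raise ValueError("session must carry its reward walk")
    delivered = session.walk.delivered
    n_opt = 0
    outcomes = []
    n_resp = 0
    for tr in session.trials:
        if tr.choice is None:
            continue
        n_resp += 1
        other = tr.pair[1] if tr.choice == tr.pair[0] else tr.pair[0]
        chosen_r = delivered[tr.t, tr.choice]
        if chosen_r >= delivered[tr.t, other]:
            n_opt += 1
        outcomes.append(chosen_r)
    if n_resp == 0:
        raise ValueError("session has no responded trials")
    return {"optimal_choice": n_opt / n_resp, "average_outcome": float(np.mean(outcomes))}


# ---------------------------------------------------------------------------
# Stay/switch events
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StayEvent:
    """A delayed-class choice at trial ``t`` whose stimulus is offered
    again at ``t + 3``, with the feedback valences the participant saw
    at ``t`` (0F) and at ``t + 2`` (2F, when the delayed payout of the
    origin choice lands)."""

    participant_id: str
    condition: Condition
    t: int
    stay: bool
    reward_0f_positive: bool
    reward_2f_positive: bool


def extract_stay_events(
    session: SessionData, valence_source: str = "total"
) -> list[StayEvent]:
    """Scan a session for delayed-choice reappearance events.

    Valence is strictly-positive feedback (zero counts negative).  With
    the default ``valence_source="total"`` it is the displayed total at
    ``t`` (0F) and at ``t + 2`` (2F) in both conditions — the reward the
    participant actually experienced at each time point.
    ``"component"`` reads the immediate box at ``t`` and the delayed box
    at ``t + 2`` instead; because a delayed-class origin choice never
    shows an immediate component, the 0F valence is then structurally
    negative in disjoint, which leaves the full condition x time x
    reward design rank-deficient — hence not the default.  Events with
    an omitted response or missing feedback anywhere in the window are
    dropped.
    """
    if valence_source not in ("total", "component"):
        raise ValueError("valence_source must be 'total' or 'component'")
    if session.stimset is None:
        raise ValueError("session must carry its stimulus set")
    stimset = session.stimset
    trials = session.trials
    events: list[StayEvent] = []
    for t, tr in enumerate(trials):
        if tr.choice is None or not stimset.is_delayed(tr.choice):
            continue
        if t + 3 >= len(trials):
            continue
        reappear = trials[t + 3]
        if tr.choice not in reappear.pair or reappear.choice is None:
            continue
        fb0 = tr.feedback
        fb2 = trials[t + 2].feedback
        if fb0 is None or fb2 is None:
            continue
        if valence_source == "component":
            r0 = fb0.immediate_component or 0
            r2 = fb2.delayed_component or 0
        else:
            r0 = fb0.total
            r2 = fb2.total
        events.append(
            StayEvent(
                participant_id=session.participant_id,
                condition=session.condition,
                t=t,
                stay=reappear.choice == tr.choice,
                reward_0f_positive=r0 > 0,
                reward_2f_positive=r2 > 0,
            )
        )
    return events


def stay_events_frame(events: Sequence[StayEvent]) -> pd.DataFrame:
    """Long-format expansion: each event contributes one row per time
    point (0F with its valence, 2F with its valence)."""
    rows = []
    for ev in events:
        for time, pos in (("0F", ev.reward_0f_positive), ("2F", ev.reward_2f_positive)):
            rows.append({
                "participant_id": ev.participant_id,
                "stay": int(ev.stay),
                "disjoint": int(ev.condition is Condition.DISJOINT),
                "time2f": int(time == "2F"),
                "pos": int(pos),
            })
    return pd.DataFrame(rows)


@dataclass
class SignatureTable:
    """A fitted signature regression: coefficient table with odds
    ratios and Wald CIs, cell-level means, and any dropped
    (rank-deficient) terms."""

    coef_table: pd.DataFrame
    cell_means: pd.DataFrame
    dropped_terms: list[str] = field(default_factory=list)

    def odds_ratio(self, term: str) -> float:
        row = self.coef_table[self.coef_table.term == term]
        if row.empty:
            raise KeyError(f"no term {term!r}")
        return float(row.odds_ratio.iloc[0])


def _logit_table(df: pd.DataFrame, formula: str,
                 cluster: Optional[str] = None) -> pd.DataFrame:
    model = smf.logit(formula, data=df)
    if cluster is not None:
        res = model.fit(disp=False, cov_type="cluster",
                        cov_kwds={"groups": df[cluster]})
    else:
        res = model.fit(disp=False)
    ci = res.conf_int()
    return pd.DataFrame({
        "term": res.params.index,
        "coef": res.params.values,
        "se": res.bse.values,
        "z": res.tvalues.values,
        "p": res.pvalues.values,
        "odds_ratio": np.exp(res.params.values),
        "or_ci_low": np.exp(ci[0].values),
        "or_ci_high": np.exp(ci[1].values),
    })


def stay_signature_regression(
    events: Sequence[StayEvent], cluster_by_subject: bool = False
) -> SignatureTable:
    """Fixed-effects logistic regression of stay on the full
    condition x time x reward interaction (treatment coding; reference
    cell conjoint / 0F / negative).

    Complete separation is reported by statsmodels as a
    ``PerfectSeparationError`` and propagates.
    """
    if not events:
        raise ValueError("no stay events to analyze")
    df = stay_events_frame(events)
    coef = _logit_table(
        df, "stay ~ disjoint * time2f * pos",
        cluster="participant_id" if cluster_by_subject else None,
    )
    cells = (
        df.groupby(["disjoint", "time2f", "pos"])["stay"]
        .agg(["mean", "count"]).reset_index()
        .rename(columns={"mean": "stay_rate", "count": "n"})
    )
    return SignatureTable(coef, cells)


# ---------------------------------------------------------------------------
# Pair-type predictive accuracy
# ---------------------------------------------------------------------------


def classify_pair(pair: tuple[int, int], stimset) -> str:
    a_del = stimset.is_delayed(pair[0])
    b_del = stimset.is_delayed(pair[1])
    if a_del and b_del:
        return "del_del"
    if not a_del and not b_del:
        return "imm_imm"
    return "mixed"


def pairtype_accuracy(
    generated: Sequence[SessionData], observed: Sequence[SessionData]
) -> pd.DataFrame:
    """Agreement between model-generated and observed choices by pair
    type (delayed-vs-delayed, immediate-vs-immediate, mixed).

    Generated sessions are matched to observed ones by participant id
    (the ``@iter<k>`` suffix of posterior-predictive replays is
    stripped), condition, and stage; their pair sequences must agree
    trial for trial.  Accuracy is pooled over iterations.
    """
    index = {(s.participant_id, s.condition, s.stage): s for s in observed}
    agree: dict[str, list[int]] = {"del_del": [], "imm_imm": [], "mixed": []}
    for g in generated:
        base_id = g.participant_id.split("@")[0]
        src = index.get((base_id, g.condition, g.stage))
        if src is None:
            raise ValueError(f"no observed session for generated {g.participant_id}")
        if len(src.trials) != len(g.trials):
            raise ValueError("schedule mismatch between generated and observed")
        stimset = src.stimset if src.stimset is not None else g.stimset
        for tr_g, tr_o in zip(g.trials, src.trials):
            if tr_g.pair != tr_o.pair:
                raise ValueError("schedule mismatch between generated and observed")
            if tr_g.choice is None or tr_o.choice is None:
                continue
            agree[classify_pair(tr_g.pair, stimset)].append(int(tr_g.choice == tr_o.choice))
    rows = [
        {"pair_type": k, "accuracy": float(np.mean(v)) if v else float("nan"), "n": len(v)}
        for k, v in agree.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Choice-prediction regression
# ---------------------------------------------------------------------------


def choice_prediction_regression(
    observed: Sequence[SessionData],
    prob_elg: Sequence[np.ndarray],
    prob_tab: Sequence[np.ndarray],
    cluster_by_subject: bool = False,
) -> SignatureTable:
    """Logistic regression of observed choices on both models'
    predicted choice probabilities, condition, and their interactions.

    ``prob_elg`` / ``prob_tab`` hold, per session, the (n_trials, 2)
    choice-probability arrays aligned with each trial's offered pair.
    The binary outcome codes choosing the first option of the pair.
    Constant predictor columns are dropped and reported rather than
    fitted.
    """
    if not (len(observed) == len(prob_elg) == len(prob_tab)):
        raise ValueError("one probability array per session required")
    rows = []
    for sess, pe, pt in zip(observed, prob_elg, prob_tab):
        pe = np.asarray(pe)
        pt = np.asarray(pt)
        if pe.shape[0] != sess.n_trials or pt.shape[0] != sess.n_trials:
            raise ValueError("probability arrays must align with session trials")
        if not (np.all(np.isfinite(pe)) and np.all(np.isfinite(pt))):
            raise ValueError("non-finite model predictors")
        for t, tr in enumerate(sess.trials):
            if tr.choice is None:
                continue
            rows.append({
                "participant_id": sess.participant_id,
                "choice": int(tr.choice == tr.pair[0]),
                "disjoint": int(sess.condition is Condition.DISJOINT),
                "elg": float(pe[t, 0]),
                "tab": float(pt[t, 0]),
            })
    df = pd.DataFrame(rows)
    dropped = [c for c in ("elg", "tab") if df[c].std() == 0.0]
    kept = [c for c in ("elg", "tab") if c not in dropped]
    if not kept:
        raise ValueError(
            f"rank-deficient design: constant predictor columns {dropped}"
        )
    terms = " + ".join(kept)
    if df["disjoint"].std() == 0.0:
        # single-condition input: no condition main effect or interactions
        dropped.append("disjoint")
        formula = f"choice ~ {terms}"
    else:
        formula = f"choice ~ disjoint * ({terms})"
    coef = _logit_table(
        df, formula, cluster="participant_id" if cluster_by_subject else None
    )
    cells = (
        df.groupby("disjoint")[["choice"] + kept].mean().reset_index()
    )
    return SignatureTable(coef, cells, dropped_terms=dropped)


# ---------------------------------------------------------------------------
# Credit-assignment gradient
# ---------------------------------------------------------------------------


def credit_gradient(
    sessions: Sequence[SessionData],
    params: ParamSet,
    variant: Variant,
    norm_window: Optional[int] = 5,
) -> pd.DataFrame:
    """Mean one-step value update ("credit difference") applied to the
    options selected at lags 0..3, by prediction-error valence and
    condition.

    Only windows whose last four selections are all responded and
    pairwise distinct are kept, isolating the gradient of credit over
    recent selections.  The value function is ``v`` for the eligibility
    model and the delay-summed ``Q`` for the tabular model; valence is
    the sign of the current trial's prediction error (eligibility
    delta, or the tabular d=0 delta).
    """
    if variant not in (Variant.ELIGIBILITY, Variant.TABULAR):
        raise ValueError("credit gradient is defined per single strategy")
    rows = []
    for sess in sessions:
        run = run_model(sess, params, norm_window)
        values = run.v_traj if variant is Variant.ELIGIBILITY else run.qsum_traj
        deltas = run.delta_elg if variant is Variant.ELIGIBILITY else run.delta_tab0
        choices = [tr.choice for tr in sess.trials]
        for t in range(3, sess.n_trials):
            window = choices[t - 3:t + 1]
            if any(c is None for c in window) or len(set(window)) < 4:
                continue
            if np.isnan(deltas[t]):
                continue
            valence = "+" if deltas[t] > 0 else "-"
            for lag in range(4):
                a = choices[t - lag]
                rows.append({
                    "condition": sess.condition.value,
                    "valence": valence,
                    "lag": lag,
                    "credit": float(values[t + 1, a] - values[t, a]),
                })
    df = pd.DataFrame(rows, columns=["condition", "valence", "lag", "credit"])
    return (
        df.groupby(["condition", "valence", "lag"])["credit"]
        .agg(["mean", "count"]).reset_index()
        .rename(columns={"mean": "mean_credit", "count": "n"})
    )


# ---------------------------------------------------------------------------
# Parameter condition contrasts
# ---------------------------------------------------------------------------


def parameter_condition_tests(
    fits_conjoint: Sequence[FitResult], fits_disjoint: Sequence[FitResult]
) -> pd.DataFrame:
    """Two-tailed paired t-tests (conjoint minus disjoint) per model
    parameter, with 95% CI of the mean difference and Cohen's d.

    Negative t means the parameter is larger in disjoint.  Zero
    within-pair variance with a nonzero shift is flagged degenerate
    (infinite t).
    """
    if len(fits_conjoint) != len(fits_disjoint):
        raise ValueError("paired inputs required: one fit per participant per condition")
    n = len(fits_conjoint)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    rows = []
    for i, name in enumerate(PARAM_NAMES):
        x = np.array([f.params.as_vector()[i] for f in fits_conjoint])
        y = np.array([f.params.as_vector()[i] for f in fits_disjoint])
        diff = x - y
        sd = diff.std(ddof=1)
        mean = diff.mean()
        # exact-zero spread up to float cancellation noise
        degenerate = sd <= 1e-10 * max(1.0, abs(mean))
        if degenerate:
            t = 0.0 if mean == 0.0 else float(np.inf) * np.sign(mean)
            p = 1.0 if mean == 0.0 else 0.0
            ci = (mean, mean)
            d = 0.0 if mean == 0.0 else float(np.inf) * np.sign(mean)
        else:
            t, p = stats.ttest_rel(x, y)
            sem = sd / np.sqrt(n)
            half = stats.t.ppf(0.975, n - 1) * sem
            ci = (mean - half, mean + half)
            d = mean / sd
        rows.append({
            "param": name, "df": n - 1, "t": float(t), "p": float(p),
            "ci_low": float(ci[0]), "ci_high": float(ci[1]),
            "cohens_d": float(d), "degenerate": bool(degenerate),
        })
    return pd.DataFrame(rows)
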