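"""Parameter- and model-recovery studies on synthetic data.

These validate the fitting machinery: simulate agents with known
parameters, refit, and check that (a) parameters come back correlated
with the truth and (b) the generating model wins the comparison
criterion more often than chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .agents import GenerativePrior, sample_params, simulate_session
from .fitting import FAST_OPTIMIZER, FitResult, OptimizerConfig, PenaltyPrior, fit_session
from .models import Variant
from .task import Condition, N_STIMULI, generate_reward_walk, generate_schedule, make_stimulus_set


@dataclass
class RecoveryReport:
    """True/recovered parameter pairs from refitting the generating
    variant to its own simulations."""

    variant: Variant
    table: pd.DataFrame  # columns: dataset, condition, param, true, recovered

    def correlations(self, condition: Optional[str] = None) -> dict[str, float]:
        """Pearson r between true and recovered values per parameter
        (pooled over conditions unless one is named)."""
        df = self.table
        if condition is not None:
            df = df[df.condition == condition]
        out = {}
        for param, grp in df.groupby("param"):
            if len(grp) < 2 or grp["true"].std() == 0 or grp["recovered"].std() == 0:
                out[param] = float("nan")
            else:
                out[param] = float(stats.pearsonr(grp["true"], grp["recovered"])[0])
        return out

    def bias(self, condition: Optional[str] = None) -> dict[str, float]:
        """Mean (recovered - true) per parameter."""
        df = self.table
        if condition is not None:
            df = df[df.condition == condition]
        return {
            param: float((grp["recovered"] - grp["true"]).mean())
            for param, grp in df.groupby("param")
        }


@dataclass
class ConfusionMatrix:
    """Rows: generating model; columns: winning model by criterion;
    cells: proportions (rows sum to 1)."""

    criterion: str
    table: pd.DataFrame

    @property
    def diagonal(self) -> dict[str, float]:
        return {v: float(self.table.loc[v, v]) for v in self.table.index}


def _task_instances(n: int, seed_seq: np.random.SeedSequence, n_repeats: int,
                    step_scale: float):
    """Fresh stimulus set, schedule, and walk per dataset."""
    n_trials = N_STIMULI * (N_STIMULI - 1) // 2 * n_repeats
    for ss in seed_seq.spawn(n):
        s1, s2, s3 = (int(c.generate_state(1)[0]) % 2**31 for c in ss.spawn(3))
        stimset = make_stimulus_set(s1)
        schedule = generate_schedule(N_STIMULI, n_repeats, seed=s2)
        walk = generate_reward_walk(stimset, n_trials, step_scale, seed=s3)
        yield stimset, schedule, walk, ss


def run_parameter_recovery(
    variant: Variant,
    n_datasets: int = 300,
    seed: int = 0,
    prior: GenerativePrior = GenerativePrior(),
    beta_min: float = 0.0,
    conditions: Sequence[Condition] = (Condition.CONJOINT, Condition.DISJOINT),
    n_repeats: int = 12,
    step_scale: float = 0.5,
    norm_window: Optional[int] = 5,
    penalty: PenaltyPrior = PenaltyPrior(),
    optimizer: OptimizerConfig = FAST_OPTIMIZER,
) -> RecoveryReport:
    """Simulate ``n_datasets`` sessions from prior-drawn parameters
    (cycling through ``conditions``), refit the same variant to each,
    and tabulate true/recovered pairs."""
    root = np.random.SeedSequence(seed)
    rows = []
    for i, (stimset, schedule, walk, ss) in enumerate(
        _task_instances(n_datasets, root, n_repeats, step_scale)
    ):
        cond = conditions[i % len(conditions)]
        p_ss, sim_ss, fit_ss = ss.spawn(3)
        true = sample_params(prior, variant, p_ss, beta_min=beta_min)
        session = simulate_session(
            true, schedule, walk, stimset, cond,
            seed=sim_ss, participant_id=f"rec{i:03d}", norm_window=norm_window,
        )
        fit = fit_session(
            session, variant, prior=penalty, optimizer=optimizer,
            seed=int(fit_ss.generate_state(1)[0]) % 2**31, norm_window=norm_window,
        )
        for name, tval, rval in zip(
            variant.free_param_names, true.free_values, fit.params.free_values
        ):
            rows.append({"dataset": i, "condition": cond.value, "param": name,
                         "true": float(tval), "recovered": float(rval)})
    columns = ["dataset", "condition", "param", "true", "recovered"]
    return RecoveryReport(variant, pd.DataFrame(rows, columns=columns))


def _winner(fits: dict[Variant, FitResult], criterion: str) -> Variant:
    """Strict argmin of the criterion; ties broken toward the simpler
    model (fewer free parameters)."""
    key = lambda v: (round(getattr(fits[v], criterion), 10), fits[v].k)
    return min(fits, key=key)


def run_model_recovery(
    variants: Sequence[Variant] = (Variant.ELIGIBILITY, Variant.TABULAR, Variant.HYBRID),
    n_sims_per_model: int = 25,
    seed: int = 0,
    prior: GenerativePrior = GenerativePrior(),
    beta_min: float = 0.0,
    conditions: Sequence[Condition] = (Condition.CONJOINT, Condition.DISJOINT),
    n_repeats: int = 12,
    step_scale: float = 0.5,
    norm_window: Optional[int] = 5,
    penalty: PenaltyPrior = PenaltyPrior(),
    optimizer: OptimizerConfig = FAST_OPTIMIZER,
) -> dict[str, ConfusionMatrix]:
    """Cross-model recovery: simulate from each variant, fit *all*
    variants to every simulated session, and tabulate which one wins by
    AIC and by BIC."""
    root = np.random.SeedSequence(seed)
    names = [v.value for v in variants]
    counts = {c: pd.DataFrame(0.0, index=names, columns=names) for c in ("aic", "bic")}
    gen_roots = root.spawn(len(variants))
    for gi, gen_variant in enumerate(variants):
        gen_root = gen_roots[gi]
        for i, (stimset, schedule, walk, ss) in enumerate(
            _task_instances(n_sims_per_model, gen_root, n_repeats, step_scale)
        ):
            cond = conditions[i % len(conditions)]
            p_ss, sim_ss, fit_ss = ss.spawn(3)
            true = sample_params(prior, gen_variant, p_ss, beta_min=beta_min)
            session = simulate_session(
                true, schedule, walk, stimset, cond,
                seed=sim_ss, participant_id=f"{gen_variant.value}{i:03d}",
                norm_window=norm_window,
            )
            fits = {
                fv: fit_session(
                    session, fv, prior=penalty, optimizer=optimizer,
                    seed=(int(fit_ss.generate_state(1)[0]) + j) % 2**31,
                    norm_window=norm_window,
                )
                for j, fv in enumerate(variants)
            }
            for crit in ("aic", "bic"):
                counts[crit].loc[gen_variant.value, _winner(fits, crit).value] += 1
    out = {}
    for crit, tab in counts.items():
        out[crit.upper()] = ConfusionMatrix(crit.upper(), tab.div(tab.sum(axis=1), axis=0))
    return out
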