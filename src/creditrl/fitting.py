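"""Penalized maximum-likelihood (MAP) fitting by differential evolution.

The objective is the session's negative log-likelihood minus the log
density of weakly-informative penalization priors — Gamma(1.25, 1) on
each strategy weight and Beta(1.25, 1.25) on each learning and decay
rate — which vanish at the rate bounds and gently discourage extreme
values.  Fit metrics (AIC, BIC, pseudo-R²) are computed from the
*unpenalized* likelihood at the optimum; the penalty is a regularizer,
not part of the data likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import ParamSet, SessionArrays, Variant, population_nll
from .task import SessionData

RATE_EPS = 1e-6           #: rate-parameter bounds [eps, 1-eps]; prior density -> 0 at 0/1
BETA_MAX = 20.0           #: saturates a two-option softmax on z-scored values


@dataclass(frozen=True)
class PenaltyPrior:
    """MAP penalization: Gamma(shape, scale) on weights, Beta(a, b) on
    learning and decay rates."""

    weight_shape: float = 1.25
    weight_scale: float = 1.0
    rate_a: float = 1.25
    rate_b: float = 1.25

    def log_density(self, variant: Variant, free_values: np.ndarray) -> np.ndarray:
        """Summed log prior density over the variant's free parameters.

        ``free_values`` is (k,) or (k, S); returns scalar array (S,).
        """
        x = np.atleast_2d(np.asarray(free_values, dtype=float).T).T  # (k, S)
        total = np.zeros(x.shape[1])
        for i, name in enumerate(variant.free_param_names):
            if name.startswith("beta"):
                total += stats.gamma.logpdf(x[i], self.weight_shape, scale=self.weight_scale)
            else:
                total += stats.beta.logpdf(x[i], self.rate_a, self.rate_b)
        return total


@dataclass(frozen=True)
class OptimizerConfig:
    """Differential-evolution settings (scipy backend).

    The defaults follow the package's reference configuration
    (population 15 x dimension, 300 generations, tight tolerance);
    :data:`FAST_OPTIMIZER` is the scaled configuration used by the
    recovery studies and acceptance checks.
    """

    popsize: int = 15
    maxiter: int = 300
    tol: float = 1e-8
    mutation: tuple[float, float] = (0.5, 1.0)
    recombination: float = 0.7
    polish: bool = True
    init: str = "sobol"


FAST_OPTIMIZER = OptimizerConfig(maxiter=60, tol=1e-6)


@dataclass(frozen=True)
class FitResult:
    params: ParamSet
    nll: float          # unpenalized, natural log
    objective: float    # nll - sum log prior at the optimum
    k: int
    n: int              # responded-trial count
    aic: float
    bic: float
    pseudo_r2: float
    optimizer: dict


def variant_bounds(variant: Variant) -> list[tuple[float, float]]:
    return [
        (0.0, BETA_MAX) if name.startswith("beta") else (RATE_EPS, 1.0 - RATE_EPS)
        for name in variant.free_param_names
    ]


def _free_to_full(variant: Variant, free: np.ndarray) -> np.ndarray:
    """Expand (S, k) free-parameter rows to (S, 6) full vectors."""
    free = np.atleast_2d(free)
    S = free.shape[0]
    full = np.zeros((S, 6))
    col = {"alpha_elg": 0, "lambda_elg": 1, "beta_elg": 2,
           "alpha_tab": 3, "lambda_tab": 4, "beta_tab": 5}
    for i, name in enumerate(variant.free_param_names):
        if name == "alpha":
            full[:, 0] = full[:, 3] = free[:, i]
        elif name == "lambda":
            full[:, 1] = full[:, 4] = free[:, i]
        else:
            full[:, col[name]] = free[:, i]
    return full


def negative_log_likelihood(
    session: SessionData,
    params: ParamSet,
    norm_window: Optional[int] = 5,
    skip_absent_components: bool = False,
) -> float:
    """-sum(ln pi(chosen)) over responded trials."""
    arrays = SessionArrays.from_session(session)
    theta = params.as_vector()[None, :]
    return float(population_nll(theta, arrays, norm_window, skip_absent_components)[0])


def fit_session(
    session: SessionData,
    variant: Variant,
    prior: PenaltyPrior = PenaltyPrior(),
    optimizer: OptimizerConfig = OptimizerConfig(),
    seed: int = 0,
    norm_window: Optional[int] = 5,
    skip_absent_components: bool = False,
) -> FitResult:
    """Globally minimize the penalized negative log-likelihood over the
    variant's bounded parameter space.

    The population's objective values are evaluated in one vectorized
    pass per generation; the best member is polished with L-BFGS-B.
    """
    n_resp = session.n_responded
    if n_resp < 1:
        raise ValueError("session has no responded trials")
    arrays = SessionArrays.from_session(session)
    bounds = variant_bounds(variant)

    def objective(x: np.ndarray) -> np.ndarray:
        # scipy passes (k,) during polish and (k, S) when vectorized
        single = x.ndim == 1
        free = x[None, :] if single else x.T           # (S, k)
        full = _free_to_full(variant, free)
        nll = population_nll(full, arrays, norm_window, skip_absent_components)
        obj = nll - prior.log_density(variant, free.T)
        return obj[0] if single else obj

    result = optimize.differential_evolution(
        objective,
        bounds,
        popsize=optimizer.popsize,
        maxiter=optimizer.maxiter,
        tol=optimizer.tol,
        mutation=optimizer.mutation,
        recombination=optimizer.recombination,
        polish=optimizer.polish,
        init=optimizer.init,
        seed=seed,
        vectorized=True,
        updating="deferred",
    )
    free = np.clip(result.x, [b[0] for b in bounds], [b[1] for b in bounds])
    params = ParamSet.from_free(variant, free)
    nll = float(population_nll(_free_to_full(variant, free[None, :]), arrays,
                               norm_window, skip_absent_components)[0])
    k = variant.k
    return FitResult(
        params=params,
        nll=nll,
        objective=float(result.fun),
        k=k,
        n=n_resp,
        aic=2.0 * k + 2.0 * nll,
        bic=k * math.log(n_resp) + 2.0 * nll,
        pseudo_r2=1.0 - nll / (n_resp * math.log(2.0)),
        optimizer={"seed": seed, "iterations": int(result.nit),
                   "converged": bool(result.success)},
    )


def compare_models(fits: dict[Variant, Sequence[FitResult]]) -> pd.DataFrame:
    """Model-comparison table over a common session set.

    One row per variant: mean AIC, mean BIC, mean pseudo-R², whether it
    is the best (lowest mean AIC) variant, and the paired Wilcoxon
    signed-rank p-value of its per-session AICs against the best
    variant's (p = 1 for the best variant itself and for identical AIC
    vectors).
    """
    lengths = {len(v) for v in fits.values()}
    if len(fits) < 2:
        raise ValueError("need fits from at least 2 variants")
    if len(lengths) != 1:
        raise ValueError("all variants must be fitted to the same sessions")
    aics = {var: np.array([f.aic for f in fl]) for var, fl in fits.items()}
    mean_aic = {var: a.mean() for var, a in aics.items()}
    best = min(mean_aic, key=mean_aic.get)
    rows = []
    for var, fl in fits.items():
        diffs = aics[var] - aics[best]
        if var is best or np.allclose(diffs, 0.0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(aics[var], aics[best]).pvalue)
        rows.append({
            "variant": var.value,
            "mean_aic": float(mean_aic[var]),
            "mean_bic": float(np.mean([f.bic for f in fl])),
            "mean_pseudo_r2": float(np.mean([f.pseudo_r2 for f in fl])),
            "best": var is best,
            "wilcoxon_p_vs_best": p,
            "median_aic_diff_vs_best": float(np.median(diffs)),
        })
    return pd.DataFrame(rows)
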