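"""Subjective-value models, likelihood, ML fitting and model comparison.

Two model families are supported, both with softmax (logistic) choice:

* hyperbolic delay discounting, ``SV = R / (1 + k * t)`` with discount
  rate ``k`` (1/days) — intertemporal choice;
* prospect-theory value for gains, ``SV = P * R**alpha`` with risk
  exponent ``alpha`` (alpha < 1 risk-averse) — risky choice.

Each family forms a 2x2 lattice of variants: one vs two value parameters
(shared across self/other or agent-specific) crossed with one vs two
softmax inverse temperatures.  Variants are fitted by maximum likelihood
(Nelder-Mead over log-parameters, multi-start) and compared by BIC summed
over subjects, with a BIC-based Bayes-factor approximation per subject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import qmc

from ._seeds import as_rng
from .errors import (
    IncompleteGridError,
    InsufficientDataError,
    InvalidParameterError,
)
from .types import (
    AGENTS,
    ChoiceTrial,
    Family,
    FitResult,
    InterTemporalOption,
    ModelVariant,
    ParamSet,
    RiskyOption,
    variants,
)

#: floor applied to per-trial choice probabilities before taking logs,
#: so perfectly-separated data yield a finite likelihood.
PROB_FLOOR = 1e-10

#: upper search bound on the inverse temperature (inverse dollars); at
#: separation the likelihood is flat in beta beyond this, so the bound
#: keeps the optimum finite without changing the fitted choice rule.
BETA_MAX = 1e3


def sv_hyperbolic(option: InterTemporalOption, k: float) -> float:
    """Subjective value of a delayed offer under hyperbolic discounting.

    ``SV = amount / (1 + k * delay)``; strictly decreasing in delay and in
    the discount rate k, linear in amount.
    """
    if not (k > 0 and math.isfinite(k)):
        raise InvalidParameterError(f"discount rate k must be > 0, got {k}")
    return option.amount / (1.0 + k * option.delay)


def sv_prospect(option: RiskyOption, alpha: float) -> float:
    """Subjective value of a probabilistic offer under prospect theory.

    ``SV = probability * amount**alpha`` (gains only, no loss aversion);
    alpha = 1 reduces to expected value.
    """
    if not (alpha > 0 and math.isfinite(alpha)):
        raise InvalidParameterError(f"risk exponent alpha must be > 0, got {alpha}")
    return option.probability * option.amount**alpha


def p_choose_right(sv_right: float, sv_left: float, beta: float) -> float:
    """Softmax probability of choosing the right option.

    Computed from the value difference, ``logistic(beta * (SVr - SVl))``,
    which is numerically stable for large ``beta * SV``.
    """
    if not (beta >= 0 and math.isfinite(beta)):
        raise InvalidParameterError(f"beta must be >= 0, got {beta}")
    if not (math.isfinite(sv_right) and math.isfinite(sv_left)):
        raise InvalidParameterError("subjective values must be finite")
    return float(expit(beta * (sv_right - sv_left)))


# ---------------------------------------------------------------------------
# vectorized trial representation


@dataclass(frozen=True)
class _TrialArrays:
    amount_l: np.ndarray
    attr_l: np.ndarray  # delay (days) or probability
    amount_r: np.ndarray
    attr_r: np.ndarray
    is_self: np.ndarray  # bool
    chose_right: np.ndarray  # bool
    family: Family

    @property
    def n(self) -> int:
        return self.amount_l.size


def _usable(trials: Sequence[ChoiceTrial]) -> list[ChoiceTrial]:
    return [t for t in trials if t.usable]


def _trial_arrays(trials: Sequence[ChoiceTrial], family: Family) -> _TrialArrays:
    usable = _usable(trials)
    if not usable:
        raise InsufficientDataError("no usable (non-dummy, non-error, chosen) trials")
    for t in usable:
        if t.family != family:
            raise InvalidParameterError(
                f"trial {t.trial_id} option kind {t.family} does not match family {family}"
            )
    attr = (
        (lambda o: o.delay) if family == "hyperbolic" else (lambda o: o.probability)
    )
    return _TrialArrays(
        amount_l=np.array([t.left.amount for t in usable], dtype=float),
        attr_l=np.array([attr(t.left) for t in usable], dtype=float),
        amount_r=np.array([t.right.amount for t in usable], dtype=float),
        attr_r=np.array([attr(t.right) for t in usable], dtype=float),
        is_self=np.array([t.agent == "self" for t in usable], dtype=bool),
        chose_right=np.array([t.chosen_side == "right" for t in usable], dtype=bool),
        family=family,
    )


def _sv_arrays(
    arrs: _TrialArrays, value_self: float, value_other: float
) -> tuple[np.ndarray, np.ndarray]:
    v = np.where(arrs.is_self, value_self, value_other)
    if arrs.family == "hyperbolic":
        sv_l = arrs.amount_l / (1.0 + v * arrs.attr_l)
        sv_r = arrs.amount_r / (1.0 + v * arrs.attr_r)
    else:
        sv_l = arrs.attr_l * arrs.amount_l**v
        sv_r = arrs.attr_r * arrs.amount_r**v
    return sv_l, sv_r


def _negll_arrays(arrs: _TrialArrays, params: ParamSet) -> float:
    sv_l, sv_r = _sv_arrays(arrs, params.value_self, params.value_other)
    beta = np.where(arrs.is_self, params.noise_self, params.noise_other)
    p_right = expit(beta * (sv_r - sv_l))
    p_obs = np.where(arrs.chose_right, p_right, 1.0 - p_right)
    p_obs = np.clip(p_obs, PROB_FLOOR, 1.0 - PROB_FLOOR)
    return float(-np.sum(np.log(p_obs)))


def neg_log_likelihood(trials: Sequence[ChoiceTrial], params: ParamSet) -> float:
    """Negative log likelihood (nats) of observed choices under ``params``.

    Dummy, error and choice-less trials are excluded.  Each trial uses the
    value and noise parameters matching its agent condition.  Per-trial
    probabilities are clipped to ``[PROB_FLOOR, 1 - PROB_FLOOR]``.
    """
    arrs = _trial_arrays(trials, params.variant.family)
    return _negll_arrays(arrs, params)


def bic(neg_log_likelihood: float, n_free_params: int, n_trials: int) -> float:
    """Bayesian information criterion, ``q * ln(n) + 2 * negLL`` (natural log)."""
    if n_trials < 1:
        raise InsufficientDataError("BIC requires n_trials >= 1")
    return n_free_params * math.log(n_trials) + 2.0 * neg_log_likelihood


def approx_bayes_factor(bic_a: float, bic_b: float) -> float:
    """BIC-based Bayes-factor approximation, ``exp((BIC_a - BIC_b) / 2)``.

    Values > 1 favor model B over model A.
    """
    if not (math.isfinite(bic_a) and math.isfinite(bic_b)):
        raise InvalidParameterError("BIC values must be finite")
    return math.exp((bic_a - bic_b) / 2.0)


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for :func:`fit_model`.

    Multi-start Nelder-Mead over log-transformed parameters.  Starting
    points are scrambled-Sobol draws in log space over k in [1e-3, 1],
    alpha in [0.2, 2], beta in [1e-2, 10].
    """

    n_restarts: int = 10
    maxiter: int = 2000
    fatol: float = 1e-6
    xatol: float = 1e-6
    seed: int = 0


_START_RANGES = {
    ("hyperbolic", "value"): (1e-3, 1.0),
    ("prospect", "value"): (0.2, 2.0),
    ("hyperbolic", "noise"): (1e-2, 10.0),
    ("prospect", "noise"): (1e-2, 10.0),
}


def _theta_to_params(theta: np.ndarray, variant: ModelVariant) -> ParamSet:
    nv = variant.n_value_params
    vals = np.exp(theta[:nv])
    noises = np.minimum(np.exp(theta[nv:]), BETA_MAX)
    v_s, v_o = (vals[0], vals[0]) if nv == 1 else (vals[0], vals[1])
    if variant.n_noise_params == 1:
        b_s = b_o = noises[0]
    else:
        b_s, b_o = noises[0], noises[1]
    return ParamSet(variant, float(v_s), float(v_o), float(b_s), float(b_o))


def _start_points(variant: ModelVariant, config: FitConfig) -> np.ndarray:
    q = variant.n_free_params
    sampler = qmc.Sobol(d=q, scramble=True, seed=config.seed)
    u = sampler.random(config.n_restarts)
    lo_v, hi_v = _START_RANGES[(variant.family, "value")]
    lo_b, hi_b = _START_RANGES[(variant.family, "noise")]
    lows = np.array(
        [math.log(lo_v)] * variant.n_value_params + [math.log(lo_b)] * variant.n_noise_params
    )
    highs = np.array(
        [math.log(hi_v)] * variant.n_value_params + [math.log(hi_b)] * variant.n_noise_params
    )
    return lows + u * (highs - lows)


def fit_model(
    trials: Sequence[ChoiceTrial],
    variant: ModelVariant,
    fit_config: FitConfig | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one model variant to one subject's trials.

    Minimizes :func:`neg_log_likelihood` over the variant's free parameters
    with the derivative-free Nelder-Mead simplex, restarted from
    ``n_restarts`` quasi-random log-space points; positivity is enforced by
    the log transform and the inverse temperature is capped at
    :data:`BETA_MAX`.  Returns the best restart with its BIC.
    """
    config = fit_config or FitConfig()
    arrs = _trial_arrays(trials, variant.family)
    if variant.n_value_params == 2 or variant.n_noise_params == 2:
        for agent, mask in zip(AGENTS, (arrs.is_self, ~arrs.is_self)):
            if not mask.any():
                raise InsufficientDataError(
                    f"variant {variant.label} needs usable {agent} trials"
                )

    nv = variant.n_value_params
    is_self = arrs.is_self
    chose_right = arrs.chose_right

    def objective(theta: np.ndarray) -> float:
        # inline of _negll_arrays over the log-parameterization (hot path)
        vals = np.exp(theta[:nv])
        noises = np.minimum(np.exp(theta[nv:]), BETA_MAX)
        v_s, v_o = (vals[0], vals[-1])
        sv_l, sv_r = _sv_arrays(arrs, v_s, v_o)
        beta = np.where(is_self, noises[0], noises[-1])
        p_right = expit(beta * (sv_r - sv_l))
        p_obs = np.where(chose_right, p_right, 1.0 - p_right)
        np.clip(p_obs, PROB_FLOOR, 1.0 - PROB_FLOOR, out=p_obs)
        return float(-np.sum(np.log(p_obs)))

    best = None
    any_success = False
    for x0 in _start_points(variant, config):
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "fatol": config.fatol,
                "xatol": config.xatol,
                "maxiter": config.maxiter,
            },
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    params = _theta_to_params(best.x, variant)
    negll = float(best.fun)
    n = arrs.n
    q = variant.n_free_params
    return FitResult(
        params=params,
        neg_log_likelihood=negll,
        n_trials_used=n,
        n_free_params=q,
        bic=bic(negll, q, n),
        converged=any_success,
        n_restarts=config.n_restarts,
    )


def fit_all_variants(
    trials: Sequence[ChoiceTrial],
    family: Family,
    fit_config: FitConfig | None = None,
) -> dict[ModelVariant, FitResult]:
    """Fit all four variants of a family to one subject's trials."""
    return {v: fit_model(trials, v, fit_config) for v in variants(family)}


@dataclass(frozen=True)
class SelectionResult:
    """Cohort-level model comparison: summed BIC per variant and winner."""

    winner: ModelVariant
    table: pd.DataFrame  # columns: variant, n_free_params, summed_bic, mean_bic


def select_model(
    fits_by_subject: Mapping[object, Mapping[ModelVariant, FitResult]],
) -> SelectionResult:
    """Pick the cohort-level winning variant by lowest summed BIC.

    Requires all four variants of one family for every subject; ties are
    broken toward fewer free parameters.
    """
    if not fits_by_subject:
        raise InsufficientDataError("no subjects to compare")
    families = {v.family for fits in fits_by_subject.values() for v in fits}
    if len(families) != 1:
        raise IncompleteGridError(f"mixed families in comparison: {families}")
    family = families.pop()
    grid = variants(family)
    for subject, fits in fits_by_subject.items():
        missing = [v.label for v in grid if v not in fits]
        if missing:
            raise IncompleteGridError(f"subject {subject!r} missing variants {missing}")
    n_subj = len(fits_by_subject)
    rows = []
    for v in grid:
        total = sum(fits[v].bic for fits in fits_by_subject.values())
        rows.append(
            {
                "variant": v.label,
                "n_free_params": v.n_free_params,
                "summed_bic": total,
                "mean_bic": total / n_subj,
            }
        )
    table = pd.DataFrame(rows)
    order = sorted(grid, key=lambda v: (table.loc[table.variant == v.label, "summed_bic"].iloc[0], v.n_free_params))
    return SelectionResult(winner=order[0], table=table)
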