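"""Simulation-based construction of trial sets and session assembly.

The decoding analyses downstream require trial sets engineered so that
(a) the per-trial absolute subjective-value difference |dSV| is
decorrelated between the two agents' preferences, and (b) a median split
of |dSV| yields clearly separated high/low classes for both agents.  The
learning task additionally requires that the two agents' deterministic
choices disagree on at least half of trials, and the risky task that the
riskier option be chosen on about half of trials.

The search strategy: candidate option pairs are drawn uniformly on a
discrete grid (amounts to the cent, delays in whole days, probabilities
in whole percent) and rejection-sampled into target |dSV| bands assigned
per trial, which decorrelates the two agents' value differences by
construction; every returned set is re-measured post hoc and the
generator retries (and ultimately fails loudly) if the constraints are
not met.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import spearmanr

from ._seeds import RNGLike, as_rng, spawn
from .errors import InfeasibleDesignError, InvalidRequestError
from .types import (
    Agent,
    ChoiceTrial,
    InterTemporalOption,
    ParamSet,
    RiskyOption,
    SessionPlan,
)


@dataclass(frozen=True)
class DesignConstraints:
    """Statistical targets and option ranges for trial-set generation.

    ``min_split_separation`` is a fraction: 4.0 means the high median-split
    class mean must exceed the low class mean by at least 400%, measured as
    (mean_high - mean_low) / mean_low.
    """

    n_trials: int = 240
    decorrelation_max_abs_r: float = 0.2
    min_split_separation: float = 4.0
    disagreement_min: float = 0.5
    risky_choice_target: float = 0.5
    risky_choice_tolerance: float = 0.05
    amount_range: tuple[float, float] = (0.01, 40.0)
    delay_range: tuple[float, float] = (1.0, 180.0)
    probability_range: tuple[float, float] = (0.20, 0.60)
    max_candidates: int = 2_000_000

    def __post_init__(self) -> None:
        if not 0 < self.amount_range[0] < self.amount_range[1] <= 40.0:
            raise InvalidRequestError("amount_range must lie within (0, 40]")
        if not 1.0 <= self.delay_range[0] < self.delay_range[1] <= 180.0:
            raise InvalidRequestError("delay_range must lie within [1, 180] days")
        if not 0.13 <= self.probability_range[0] < self.probability_range[1] <= 0.65:
            raise InvalidRequestError("probability_range must lie within [0.13, 0.65]")


@dataclass(frozen=True)
class SessionConfig:
    """Block layout for a scanning session: alternating single-agent
    blocks, each opening with dummy trials that are excluded from analysis."""

    n_blocks: int = 8
    trials_per_block: int = 30
    n_dummy_per_block: int = 1
    first_agent: Agent = "self"


def _value_param(params: ParamSet | float, agent: Agent) -> float:
    if isinstance(params, ParamSet):
        return params.value_for(agent)
    return float(params)


# ---------------------------------------------------------------------------
# intertemporal sets


def _hyp_sv(amount: np.ndarray, delay: np.ndarray, k: float) -> np.ndarray:
    return amount / (1.0 + k * delay)


def _draw_it_candidates(
    m: int, constraints: DesignConstraints, rng: np.random.Generator
) -> tuple[np.ndarray, ...]:
    """m candidate smaller-sooner / larger-later pairs on the discrete grid."""
    c_lo = max(1, int(round(constraints.amount_range[0] * 100)))
    c_hi = int(round(constraints.amount_range[1] * 100))
    d_lo = int(round(constraints.delay_range[0]))
    d_hi = int(round(constraints.delay_range[1]))
    a = np.sort(rng.integers(c_lo, c_hi + 1, size=(m, 2)), axis=1) / 100.0
    # log-uniform delays: short delays carry most of the discounting
    # information, so they get proportionally more proposal mass
    d = np.sort(
        np.rint(np.exp(rng.uniform(np.log(d_lo), np.log(d_hi + 1), size=(m, 2)))),
        axis=1,
    ).clip(d_lo, d_hi)
    ok = (a[:, 0] < a[:, 1]) & (d[:, 0] < d[:, 1])
    return a[ok, 0], d[ok, 0].astype(float), a[ok, 1], d[ok, 1].astype(float)


def _separation(values: np.ndarray) -> float:
    """High/low mean separation of a sorted-half median split, as a fraction."""
    v = np.sort(np.asarray(values, dtype=float))
    low, high = v[: v.size // 2], v[v.size // 2 :]
    m_low = low.mean()
    if m_low <= 0:
        return math.inf if high.mean() > 0 else 0.0
    return float((high.mean() - m_low) / m_low)


def measure_intertemporal_design(
    trials: Sequence[ChoiceTrial],
    self_params: ParamSet | float,
    other_params: ParamSet | float,
) -> dict[str, float]:
    """Post-hoc constraint measurement on a generated intertemporal set.

    Returns the Spearman correlation between per-trial |dSV| under the two
    agents' discount rates and the median-split separation fraction of
    |dSV| for each agent.
    """
    k_s = _value_param(self_params, "self")
    k_o = _value_param(other_params, "other")
    scored = [t for t in trials if not t.is_dummy]
    a_l = np.array([t.left.amount for t in scored])
    d_l = np.array([t.left.delay for t in scored])
    a_r = np.array([t.right.amount for t in scored])
    d_r = np.array([t.right.delay for t in scored])
    dsv_s = np.abs(_hyp_sv(a_r, d_r, k_s) - _hyp_sv(a_l, d_l, k_s))
    dsv_o = np.abs(_hyp_sv(a_r, d_r, k_o) - _hyp_sv(a_l, d_l, k_o))
    r = spearmanr(dsv_s, dsv_o).statistic
    return {
        "spearman_r": float(r),
        "separation_self": _separation(dsv_s),
        "separation_other": _separation(dsv_o),
    }


def _make_it_trials(
    a1: np.ndarray,
    d1: np.ndarray,
    a2: np.ndarray,
    d2: np.ndarray,
    rng: np.random.Generator,
) -> list[ChoiceTrial]:
    n = a1.size
    order = rng.permutation(n)
    sooner_left = rng.random(n) < 0.5
    trials = []
    for tid, idx in enumerate(order):
        sooner = InterTemporalOption(float(a1[idx]), float(d1[idx]))
        later = InterTemporalOption(float(a2[idx]), float(d2[idx]))
        left, right = (sooner, later) if sooner_left[tid] else (later, sooner)
        trials.append(ChoiceTrial(trial_id=tid, agent="self", left=left, right=right))
    return trials


def generate_intertemporal_trialset(
    self_params: ParamSet | float,
    other_params: ParamSet | float,
    constraints: DesignConstraints | None = None,
    rng: RNGLike = None,
) -> list[ChoiceTrial]:
    """Engineer an intertemporal choice set decorrelating self and other value.

    Each trial is assigned to one of four target cells — (self-high |dSV|,
    other-high), (self-high, other-low), (self-low, other-high), (self-low,
    other-low) in equal proportion — and candidate smaller-sooner /
    larger-later pairs are rejection-sampled into the cell's |dSV| bands
    under both discount rates.  The returned set is verified post hoc
    against the decorrelation and separation constraints.
    """
    constraints = constraints or DesignConstraints()
    rng = as_rng(rng)
    k_s = _value_param(self_params, "self")
    k_o = _value_param(other_params, "other")
    scale = constraints.amount_range[1] / 40.0
    band_low = (0.2 * scale, 1.2 * scale)
    band_high = (6.0 * scale, 14.0 * scale)
    n = constraints.n_trials
    cells = [(True, True), (True, False), (False, True), (False, False)]
    quota = [n // 4] * 4
    for i in range(n % 4):
        quota[i] += 1

    tol_low = (band_low[1] - band_low[0]) / 8.0
    tol_high = (band_high[1] - band_high[0]) / 8.0

    best: dict = {}
    for attempt_rng in spawn(rng, 3):
        # per-trial independent |dSV| targets: band membership follows the
        # 4-cell quota, the position within each band is uniform — so the
        # two agents' value differences are decorrelated both between and
        # within cells.
        targets = []
        for (s_high, o_high), q in zip(cells, quota):
            b_s = band_high if s_high else band_low
            b_o = band_high if o_high else band_low
            u_s = attempt_rng.uniform(b_s[0], b_s[1], size=q)
            u_o = attempt_rng.uniform(b_o[0], b_o[1], size=q)
            t_s = tol_high if s_high else tol_low
            t_o = tol_high if o_high else tol_low
            targets.extend(zip(u_s, u_o, [t_s] * q, [t_o] * q, [b_s] * q, [b_o] * q))
        pending = list(range(n))
        found: dict[int, tuple] = {}
        drawn = 0
        while pending and drawn < constraints.max_candidates:
            a1, d1, a2, d2 = _draw_it_candidates(8192, constraints, attempt_rng)
            drawn += 8192
            dsv_s = np.abs(_hyp_sv(a2, d2, k_s) - _hyp_sv(a1, d1, k_s))
            dsv_o = np.abs(_hyp_sv(a2, d2, k_o) - _hyp_sv(a1, d1, k_o))
            used = np.zeros(dsv_s.size, dtype=bool)
            # relax the target tolerance (never beyond the band) as the
            # budget is consumed, so rare corner targets still resolve
            grow = 1.0 + 8.0 * (drawn / constraints.max_candidates)
            still = []
            for t_idx in pending:
                u_s, u_o, t_s, t_o, b_s, b_o = targets[t_idx]
                ok = (
                    (np.abs(dsv_s - u_s) <= t_s * grow)
                    & (np.abs(dsv_o - u_o) <= t_o * grow)
                    & (dsv_s >= b_s[0]) & (dsv_s <= b_s[1])
                    & (dsv_o >= b_o[0]) & (dsv_o <= b_o[1])
                    & ~used
                )
                hit = np.argmax(ok) if ok.any() else -1
                if hit >= 0:
                    used[hit] = True
                    found[t_idx] = (a1[hit], d1[hit], a2[hit], d2[hit])
                else:
                    still.append(t_idx)
            pending = still
        best = {"n_matched": len(found), "candidates_drawn": drawn}
        if pending:
            continue
        cols = [
            np.array([found[i][j] for i in range(n)]) for j in range(4)
        ]
        trials = _make_it_trials(*cols, rng=attempt_rng)
        measured = measure_intertemporal_design(trials, k_s, k_o)
        best.update(measured)
        if (
            abs(measured["spearman_r"]) <= constraints.decorrelation_max_abs_r
            and measured["separation_self"] >= constraints.min_split_separation
            and measured["separation_other"] >= constraints.min_split_separation
        ):
            return trials
    raise InfeasibleDesignError(
        "could not satisfy decorrelation/separation constraints "
        f"(best achieved: {best})",
        best=best,
    )


# ---------------------------------------------------------------------------
# learning task


def generate_learning_trialset(
    self_params: ParamSet | float,
    other_params: ParamSet | float,
    n: int = 80,
    rng: RNGLike = None,
    constraints: DesignConstraints | None = None,
) -> list[ChoiceTrial]:
    """Trial set on which self and other deterministically disagree.

    At least ``disagreement_min`` of the n trials have opposite argmax-SV
    choices under the two discount rates; the remainder are unconstrained.
    """
    constraints = constraints or DesignConstraints()
    rng = as_rng(rng)
    k_s = _value_param(self_params, "self")
    k_o = _value_param(other_params, "other")
    n_dis = math.ceil(n * constraints.disagreement_min)
    dis: list[tuple] = []
    free: list[tuple] = []
    drawn = 0
    while drawn < constraints.max_candidates and (
        len(dis) < n_dis or len(free) < n - n_dis
    ):
        a1, d1, a2, d2 = _draw_it_candidates(4096, constraints, rng)
        drawn += 4096
        later_wins_s = _hyp_sv(a2, d2, k_s) > _hyp_sv(a1, d1, k_s)
        later_wins_o = _hyp_sv(a2, d2, k_o) > _hyp_sv(a1, d1, k_o)
        disagree = later_wins_s != later_wins_o
        for i in range(a1.size):
            bucket = dis if disagree[i] else free
            cap = n_dis if disagree[i] else n - n_dis
            if len(bucket) < cap:
                bucket.append((a1[i], d1[i], a2[i], d2[i]))
    if len(dis) < n_dis:
        raise InfeasibleDesignError(
            f"only {len(dis)}/{n_dis} disagreement trials found "
            f"(k_self={k_s}, k_other={k_o})",
            best={"n_disagreement": len(dis), "candidates_drawn": drawn},
        )
    rows = dis + free
    cols = [np.array([r[j] for r in rows]) for j in range(4)]
    return _make_it_trials(*cols, rng=rng)


def measure_disagreement(
    trials: Sequence[ChoiceTrial],
    self_params: ParamSet | float,
    other_params: ParamSet | float,
) -> float:
    """Fraction of trials where self and other argmax-SV choices differ."""
    k_s = _value_param(self_params, "self")
    k_o = _value_param(other_params, "other")
    n_dis = 0
    scored = [t for t in trials if not t.is_dummy]
    for t in scored:
        sv = lambda o, k: o.amount / (1.0 + k * o.delay)
        n_dis += (sv(t.right, k_s) > sv(t.left, k_s)) != (
            sv(t.right, k_o) > sv(t.left, k_o)
        )
    return n_dis / len(scored)


# ---------------------------------------------------------------------------
# risky sets


def generate_risky_trialset(
    params: ParamSet | float,
    n: int = 240,
    rng: RNGLike = None,
    constraints: DesignConstraints | None = None,
) -> list[ChoiceTrial]:
    """Risky choice set where the riskier option wins about half the time.

    Each trial pits a safer option (higher probability, lower amount)
    against a riskier one (lower probability, higher amount); trials are
    selected so that the deterministic (argmax prospect-theory SV) choice
    frequency of the riskier option hits ``risky_choice_target`` within
    tolerance.
    """
    constraints = constraints or DesignConstraints()
    rng = as_rng(rng)
    alpha = _value_param(params, "self")
    n_risky = int(round(n * constraints.risky_choice_target))
    risky_wins: list[tuple] = []
    safe_wins: list[tuple] = []
    c_lo = max(1, int(round(constraints.amount_range[0] * 100)))
    c_hi = int(round(constraints.amount_range[1] * 100))
    p_lo = int(round(constraints.probability_range[0] * 100))
    p_hi = int(round(constraints.probability_range[1] * 100))
    drawn = 0
    while drawn < constraints.max_candidates and (
        len(risky_wins) < n_risky or len(safe_wins) < n - n_risky
    ):
        a = np.sort(rng.integers(c_lo, c_hi + 1, size=(4096, 2)), axis=1) / 100.0
        p = np.sort(rng.integers(p_lo, p_hi + 1, size=(4096, 2)), axis=1) / 100.0
        drawn += 4096
        ok = (a[:, 0] < a[:, 1]) & (p[:, 0] < p[:, 1])
        # safer = (a_small, p_big); riskier = (a_big, p_small)
        a_s, a_r = a[ok, 0], a[ok, 1]
        p_s, p_r = p[ok, 1], p[ok, 0]
        sv_safe = p_s * a_s**alpha
        sv_risky = p_r * a_r**alpha
        riskier_chosen = sv_risky > sv_safe
        tie = sv_risky == sv_safe
        for i in range(a_s.size):
            if tie[i]:
                continue
            bucket = risky_wins if riskier_chosen[i] else safe_wins
            cap = n_risky if riskier_chosen[i] else n - n_risky
            if len(bucket) < cap:
                bucket.append((a_s[i], p_s[i], a_r[i], p_r[i]))
    if len(risky_wins) < n_risky or len(safe_wins) < n - n_risky:
        raise InfeasibleDesignError(
            f"could not balance riskier-option choices at alpha={alpha} "
            f"({len(risky_wins)} risky-win, {len(safe_wins)} safe-win trials found)",
            best={"n_risky_wins": len(risky_wins), "n_safe_wins": len(safe_wins)},
        )
    rows = risky_wins + safe_wins
    order = rng.permutation(len(rows))
    safer_left = rng.random(len(rows)) < 0.5
    trials = []
    for tid, idx in enumerate(order):
        a_s, p_s, a_r, p_r = rows[idx]
        safer = RiskyOption(float(a_s), float(p_s))
        riskier = RiskyOption(float(a_r), float(p_r))
        left, right = (safer, riskier) if safer_left[tid] else (riskier, safer)
        trials.append(ChoiceTrial(trial_id=tid, agent="self", left=left, right=right))
    return trials


def measure_risky_choice_rate(
    trials: Sequence[ChoiceTrial], params: ParamSet | float
) -> float:
    """Deterministic (argmax-SV) choice frequency of the riskier option."""
    alpha = _value_param(params, "self")
    hits = used = 0
    for t in trials:
        if t.is_dummy:
            continue
        riskier = t.left if t.left.probability < t.right.probability else t.right
        safer = t.right if riskier is t.left else t.left
        sv_r = riskier.probability * riskier.amount**alpha
        sv_s = safer.probability * safer.amount**alpha
        if sv_r == sv_s:
            continue
        used += 1
        hits += sv_r > sv_s
    return hits / used if used else float("nan")


# ---------------------------------------------------------------------------
# session assembly


def assemble_session(
    trials: Sequence[ChoiceTrial],
    config: SessionConfig | None = None,
    rng: RNGLike = None,
) -> tuple[SessionPlan, list[ChoiceTrial]]:
    """Arrange scored trials into alternating single-agent blocks.

    The default layout is 8 blocks of 30 scored trials, alternating
    self/other starting from ``config.first_agent`` (counterbalance the
    first condition across subjects by flipping it), each block opening
    with one dummy trial excluded from analysis.  Trial ids are reassigned
    in presentation order.
    """
    config = config or SessionConfig()
    rng = as_rng(rng)
    scored = [t for t in trials if not t.is_dummy]
    capacity = config.n_blocks * config.trials_per_block
    if len(scored) != capacity:
        raise InvalidRequestError(
            f"session holds {capacity} scored trials, got {len(scored)}"
        )
    other: Agent = "other" if config.first_agent == "self" else "self"
    block_agents = tuple(
        config.first_agent if i % 2 == 0 else other for i in range(config.n_blocks)
    )
    order = rng.permutation(len(scored))
    out: list[ChoiceTrial] = []
    tid = 0
    pos = 0
    for b, agent in enumerate(block_agents, start=1):
        for _ in range(config.n_dummy_per_block):
            src = scored[int(rng.integers(len(scored)))]
            out.append(
                replace(src, trial_id=tid, agent=agent, block=b, is_dummy=True)
            )
            tid += 1
        for _ in range(config.trials_per_block):
            src = scored[int(order[pos])]
            out.append(
                replace(src, trial_id=tid, agent=agent, block=b, is_dummy=False)
            )
            tid += 1
            pos += 1
    plan = SessionPlan(
        block_agents=block_agents,
        trials_per_block=config.trials_per_block,
        n_dummy_per_block=config.n_dummy_per_block,
    )
    return plan, out
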