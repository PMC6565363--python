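"""Synthetic study generator.

Produces choice data, trial-level feature patterns and questionnaire
scores with the statistical structure the analysis pipeline assumes, so
every stage can be exercised end to end without any recorded data:

* agents with hyperbolic-discounting or prospect-theory preferences and
  softmax choice noise (shared or distinct parameters for self/other);
* trial patterns carrying a linear high/low value code whose encoding
  vectors have a configurable cosine similarity ("code overlap") across
  agent conditions and tasks, plus isotropic Gaussian noise;
* questionnaire batteries generated from a one-factor antisocial-attitude
  model, with each subject's code overlap optionally tied to the same
  latent factor (a planted, sign-recoverable overlap-antisociality slope).

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._seeds import RNGLike, as_rng, spawn
from .errors import DegenerateInputError, InvalidParameterError
from .mvpa import PatternDataset
from .trial_design import (
    DesignConstraints,
    SessionConfig,
    _draw_it_candidates,
    assemble_session,
    generate_intertemporal_trialset,
    generate_risky_trialset,
)
from .types import (
    AGENTS,
    ChoiceTrial,
    Family,
    InterTemporalOption,
    ParamSet,
    SessionPlan,
)
from .value_metrics import compute_rsv, median_split


@dataclass(frozen=True)
class SyntheticAgent:
    """Generating parameters for one simulated subject."""

    subject_id: str
    family: Family = "hyperbolic"
    value_self: float = 0.05
    value_other: float = 0.005
    beta: float = 0.3

    def param_set(self) -> ParamSet:
        return ParamSet.distinct(
            self.family, self.value_self, self.value_other, self.beta
        )


def simulate_choices(
    params: ParamSet | SyntheticAgent,
    trials: Sequence[ChoiceTrial],
    rng: RNGLike = None,
    rt_intercept: float | None = None,
    rt_slope: float = 0.0,
    rt_noise_sd: float = 0.0,
) -> list[ChoiceTrial]:
    """Sample choices for every trial from the softmax rule.

    Each choice is Bernoulli with the right-option probability from the
    agent-condition-appropriate value and noise parameters.  If
    ``rt_intercept`` is given, response times are generated as
    ``max(0.1, rt_intercept - rt_slope * |dSV| + noise)`` so that
    higher-relative-value trials are answered faster.
    """
    if isinstance(params, SyntheticAgent):
        params = params.param_set()
    rng = as_rng(rng)
    out = []
    for t in trials:
        v = params.value_for(t.agent)
        beta = params.noise_for(t.agent)
        if t.family == "hyperbolic":
            sv_l = t.left.amount / (1.0 + v * t.left.delay)
            sv_r = t.right.amount / (1.0 + v * t.right.delay)
        else:
            sv_l = t.left.probability * t.left.amount**v
            sv_r = t.right.probability * t.right.amount**v
        p_right = 1.0 / (1.0 + math.exp(-np.clip(beta * (sv_r - sv_l), -700, 700)))
        side = "right" if rng.random() < p_right else "left"
        rt = None
        if rt_intercept is not None:
            rt = max(
                0.1,
                rt_intercept
                - rt_slope * abs(sv_r - sv_l)
                + rt_noise_sd * rng.standard_normal(),
            )
        out.append(t.with_choice(side, response_time=rt))
    return out


# ---------------------------------------------------------------------------
# pattern generation


@dataclass(frozen=True)
class PatternGenConfig:
    """Geometry and noise of the planted linear value code.

    ``effect_size`` is the signal amplitude in units of the noise SD;
    ``code_overlap`` is the cosine similarity between the encoding vectors
    of any two conditions (agent x task).
    """

    n_features: int = 500
    effect_size: float = 0.6
    noise_sd: float = 1.0
    code_overlap: float = 1.0
    n_trials_per_block: int = 30
    n_blocks: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.code_overlap <= 1.0:
            raise InvalidParameterError("code_overlap must be in [0, 1]")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise InvalidParameterError("effect_size and noise_sd must be >= 0")


def encoding_vectors(
    n_conditions: int,
    n_features: int,
    overlap: float,
    rng: RNGLike = None,
) -> np.ndarray:
    """Unit encoding vectors with exact pairwise cosine similarity.

    Builds a random orthonormal basis and mixes it through the Cholesky
    factor of the requested Gram matrix, so realized pairwise similarities
    match ``overlap`` to machine precision.
    """
    if n_conditions > n_features:
        raise DegenerateInputError(
            f"cannot embed {n_conditions} vectors in {n_features} dimensions"
        )
    rng = as_rng(rng)
    gram = np.full((n_conditions, n_conditions), float(overlap))
    np.fill_diagonal(gram, 1.0)
    # PSD square root handles the rank-deficient overlap = 1 case exactly
    eigval, eigvec = np.linalg.eigh(gram)
    if eigval.min() < -1e-10:
        raise DegenerateInputError(
            f"requested overlap geometry infeasible (min eigenvalue {eigval.min():.3g})"
        )
    L = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    basis, _ = np.linalg.qr(rng.standard_normal((n_features, n_conditions)))
    return L @ basis.T  # rows are unit vectors with Gram matrix `gram`


def simulate_patterns(
    meta: pd.DataFrame,
    config: PatternGenConfig,
    rng: RNGLike = None,
    subject_id: str = "sim",
) -> dict[tuple[str, str], PatternDataset]:
    """Trial patterns carrying the planted value code, one dataset per
    condition.

    ``meta`` needs columns ``label`` ("high"/"low"), ``block`` (1..4 within
    condition), ``agent`` and ``task``.  Pattern_t = amplitude * s_t * w_c
    + Gaussian noise, with s_t = +1 for high and -1 for low and w_c the
    condition's encoding vector.
    """
    required = {"label", "block", "agent", "task"}
    if not required.issubset(meta.columns):
        raise DegenerateInputError(f"meta needs columns {sorted(required)}")
    rng = as_rng(rng)
    conditions = sorted(set(zip(meta["agent"], meta["task"])))
    W = encoding_vectors(len(conditions), config.n_features, config.code_overlap, rng)
    amplitude = config.effect_size * config.noise_sd
    out = {}
    for (agent, task), w in zip(conditions, W):
        sub = meta[(meta["agent"] == agent) & (meta["task"] == task)]
        signs = np.where(sub["label"].to_numpy() == "high", 1.0, -1.0)
        noise = config.noise_sd * rng.standard_normal((len(sub), config.n_features))
        out[(agent, task)] = PatternDataset(
            patterns=amplitude * signs[:, None] * w[None, :] + noise,
            labels=sub["label"].to_numpy(),
            block=sub["block"].to_numpy(),
            agent=agent,
            task=task,
            subject_id=subject_id,
        )
    return out


# ---------------------------------------------------------------------------
# questionnaires

#: one-factor loadings mirroring an antisocial-attitude component:
#: psychopathy loads positively, altruism and empathy negatively, autism
#: quotient and social phobia near zero.
DEFAULT_LOADINGS = {
    "altruism": -0.7,
    "empathy_quotient": -0.6,
    "autism_quotient": 0.1,
    "psychopathy": 0.8,
    "social_phobia": 0.0,
}

#: plausible instrument centers and spreads (native units) used to place
#: the factor-model scores on each instrument's own scale.
_INSTRUMENT_SCALES = {
    "altruism": (56.0, 10.0),
    "empathy_quotient": (42.0, 12.0),
    "autism_quotient": (17.0, 6.0),
    "psychopathy": (40.0, 9.0),
    "social_phobia": (35.0, 15.0),
}


def simulate_questionnaires(
    latent: Sequence[float],
    loadings: dict[str, float] | None = None,
    noise_sd: float = 0.5,
    rng: RNGLike = None,
    subject_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Questionnaire totals from a one-factor antisocial-attitude model.

    ``score_ij = loading_j * latent_i + noise`` in factor units, then
    affinely mapped onto each instrument's native scale.
    """
    latent = np.asarray(latent, dtype=float)
    loadings = dict(DEFAULT_LOADINGS if loadings is None else loadings)
    rng = as_rng(rng)
    n = latent.size
    data = {}
    for name, (center, scale) in _INSTRUMENT_SCALES.items():
        raw = loadings[name] * latent + noise_sd * rng.standard_normal(n)
        data[name] = center + scale * raw
    idx = (
        list(subject_ids)
        if subject_ids is not None
        else [f"s{i:02d}" for i in range(n)]
    )
    return pd.DataFrame(data, index=pd.Index(idx, name="subject_id"))


# ---------------------------------------------------------------------------
# full cohort


@dataclass(frozen=True)
class CohortConfig:
    """Study-scale defaults for an end-to-end synthetic cohort.

    20 subjects, 240-trial sessions (8 alternating-agent blocks of 30
    scored trials plus a dummy each), 500-feature patterns.  Discount
    rates are drawn log-uniform (log10 k in [-2.5, -1]) with the partner's
    rate a fixed ratio away, emulating the pairing of high with low
    discounters; ``overlap_slope`` plants the monotone relationship
    between each subject's code overlap and the latent antisocial factor
    (positive by default, matching the observed direction).
    """

    n_subjects: int = 20
    family: Family = "hyperbolic"
    tasks: tuple[str, ...] = ("intertemporal",)
    n_trials: int = 240
    n_blocks: int = 8
    k_log10_range: tuple[float, float] = (-2.5, -1.0)
    k_other_ratio: float = 10.0
    alpha_range: tuple[float, float] = (0.5, 1.2)
    beta: float = 0.3
    design: Literal["engineered", "random"] = "engineered"
    pattern: PatternGenConfig = field(default_factory=PatternGenConfig)
    overlap_base: float = 0.5
    overlap_slope: float = 0.25
    questionnaire_noise_sd: float = 0.5
    rt_intercept: float | None = 1.2
    rt_slope: float = 0.02
    rt_noise_sd: float = 0.15


@dataclass
class SubjectData:
    """Everything generated for one synthetic subject."""

    agent: SyntheticAgent
    plan: SessionPlan
    trials: list[ChoiceTrial]
    records: list  # labeled TrialValueRecords (online perspective)
    patterns: dict[tuple[str, str], PatternDataset]
    latent: float
    code_overlap: float


@dataclass
class CohortData:
    config: CohortConfig
    subjects: list[SubjectData]
    questionnaires: pd.DataFrame


def _random_intertemporal_set(
    n: int, constraints: DesignConstraints, rng: np.random.Generator
) -> list[ChoiceTrial]:
    """Unconstrained smaller-sooner / larger-later pairs (fast path)."""
    cols = [[], [], [], []]
    while len(cols[0]) < n:
        batch = _draw_it_candidates(4 * n, constraints, rng)
        for store, col in zip(cols, batch):
            store.extend(col.tolist())
    trials = []
    for tid in range(n):
        sooner = InterTemporalOption(cols[0][tid], cols[1][tid])
        later = InterTemporalOption(cols[2][tid], cols[3][tid])
        left, right = (sooner, later) if rng.random() < 0.5 else (later, sooner)
        trials.append(ChoiceTrial(trial_id=tid, agent="self", left=left, right=right))
    return trials


def _labels_meta(records, trials, task: str) -> pd.DataFrame:
    """Per-trial label/block/agent metadata with 4 CV blocks per agent."""
    block_of = {t.trial_id: t.block for t in trials}
    rows = []
    for r in records:
        rows.append(
            {
                "trial_id": r.trial_id,
                "label": r.value_label,
                "scanner_block": block_of[r.trial_id],
                "agent": r.agent,
                "task": task,
            }
        )
    meta = pd.DataFrame(rows)
    # each agent sees 4 of the 8 scanner blocks; rank them into CV blocks 1..4
    meta["block"] = meta.groupby("agent")["scanner_block"].transform(
        lambda b: b.rank(method="dense").astype(int)
    )
    return meta


def simulate_subject(
    config: CohortConfig,
    subject_idx: int,
    agent: SyntheticAgent,
    latent: float,
    rng: RNGLike = None,
) -> SubjectData:
    """Generate one subject: trial set, choices, labels and patterns."""
    rng = as_rng(rng)
    design_rng, choice_rng, pattern_rng = spawn(rng, 3)
    constraints = DesignConstraints(n_trials=config.n_trials)
    session = SessionConfig(
        n_blocks=config.n_blocks,
        trials_per_block=config.n_trials // config.n_blocks,
        first_agent="self" if subject_idx % 2 == 0 else "other",
    )
    params = agent.param_set()
    task = config.tasks[0]
    if config.design == "engineered" and config.family == "hyperbolic":
        base = generate_intertemporal_trialset(params, params, constraints, design_rng)
    elif config.family == "hyperbolic":
        base = _random_intertemporal_set(config.n_trials, constraints, design_rng)
    else:
        base = generate_risky_trialset(params, config.n_trials, design_rng, constraints)
    plan, placed = assemble_session(base, session, design_rng)
    trials = simulate_choices(
        params,
        placed,
        choice_rng,
        rt_intercept=config.rt_intercept,
        rt_slope=config.rt_slope,
        rt_noise_sd=config.rt_noise_sd,
    )
    records = compute_rsv(trials, params, "online")
    block_of = {t.trial_id: t.block for t in trials}
    labeled = []
    for cond in AGENTS:  # median split within each agent condition
        labeled.extend(median_split([r for r in records if r.agent == cond]))
    # the decoder requires >= 2 trials per label in every CV block; a
    # session-wide split can starve a small block, in which case fall
    # back to splitting within each (agent, block) cell
    counts: dict[tuple, int] = {}
    for r in labeled:
        counts[(r.agent, block_of[r.trial_id], r.value_label)] = (
            counts.get((r.agent, block_of[r.trial_id], r.value_label), 0) + 1
        )
    blocks = sorted({block_of[r.trial_id] for r in labeled})
    if any(
        counts.get((a, b, lab), 0) < 2
        for a in AGENTS
        for b in blocks
        if any(block_of[r.trial_id] == b and r.agent == a for r in labeled)
        for lab in ("high", "low")
    ):
        labeled = []
        for cond in AGENTS:
            for b in blocks:
                group = [
                    r
                    for r in records
                    if r.agent == cond and block_of[r.trial_id] == b
                ]
                if group:
                    labeled.extend(median_split(group))
    overlap = float(np.clip(config.overlap_base + config.overlap_slope * latent, 0, 1))
    pattern_cfg = PatternGenConfig(
        n_features=config.pattern.n_features,
        effect_size=config.pattern.effect_size,
        noise_sd=config.pattern.noise_sd,
        code_overlap=overlap,
        n_trials_per_block=config.pattern.n_trials_per_block,
    )
    meta = _labels_meta(labeled, trials, task)
    patterns = simulate_patterns(
        meta, pattern_cfg, pattern_rng, subject_id=agent.subject_id
    )
    return SubjectData(
        agent=agent,
        plan=plan,
        trials=trials,
        records=labeled,
        patterns=patterns,
        latent=latent,
        code_overlap=overlap,
    )


def simulate_cohort(config: CohortConfig | None = None, rng: RNGLike = None) -> CohortData:
    """Generate a full synthetic study: choices, patterns, questionnaires."""
    config = config or CohortConfig()
    rng = as_rng(rng)
    master, q_rng = spawn(rng, 2)
    latents = master.standard_normal(config.n_subjects)
    subject_rngs = spawn(master, config.n_subjects)
    subjects = []
    for i, (latent, s_rng) in enumerate(zip(latents, subject_rngs)):
        sid = f"s{i:02d}"
        if config.family == "hyperbolic":
            lo, hi = config.k_log10_range
            k_self = 10 ** master.uniform(lo, hi)
            ratio = config.k_other_ratio if i % 2 == 0 else 1.0 / config.k_other_ratio
            agent = SyntheticAgent(sid, "hyperbolic", k_self, k_self * ratio, config.beta)
        else:
            a = master.uniform(*config.alpha_range)
            agent = SyntheticAgent(sid, "prospect", a, a, config.beta)
        subjects.append(simulate_subject(config, i, agent, float(latent), s_rng))
    questionnaires = simulate_questionnaires(
        latents,
        noise_sd=config.questionnaire_noise_sd,
        rng=q_rng,
        subject_ids=[s.agent.subject_id for s in subjects],
    )
    return CohortData(config=config, subjects=subjects, questionnaires=questionnaires)
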