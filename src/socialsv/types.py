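"""Domain types for social subjective-value analysis.

The task structure: an agent chooses between two monetary offers, either
for themselves ("self" trials) or on behalf of another person ("other"
trials).  Offers are either delayed amounts (intertemporal choice) or
probabilistic amounts (risky choice).  Behavioral models assign each offer
a subjective value (SV); a softmax over the SV difference generates
choices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Union

from .errors import InvalidParameterError

Agent = Literal["self", "other"]
Family = Literal["hyperbolic", "prospect"]
Side = Literal["left", "right", "none"]

AGENTS: tuple[Agent, Agent] = ("self", "other")


@dataclass(frozen=True)
class InterTemporalOption:
    """A delayed monetary offer: `amount` dollars after `delay` days."""

    amount: float
    delay: float

    def __post_init__(self) -> None:
        if not (self.amount > 0 and math.isfinite(self.amount)):
            raise InvalidParameterError(f"amount must be positive, got {self.amount}")
        if not (self.delay >= 0 and math.isfinite(self.delay)):
            raise InvalidParameterError(f"delay must be >= 0 days, got {self.delay}")


@dataclass(frozen=True)
class RiskyOption:
    """A probabilistic monetary offer: `amount` dollars with `probability`."""

    amount: float
    probability: float

    def __post_init__(self) -> None:
        if not (self.amount > 0 and math.isfinite(self.amount)):
            raise InvalidParameterError(f"amount must be positive, got {self.amount}")
        if not 0.0 <= self.probability <= 1.0:
            raise InvalidParameterError(
                f"probability must be in [0, 1], got {self.probability}"
            )


Option = Union[InterTemporalOption, RiskyOption]


@dataclass(frozen=True)
class ChoiceTrial:
    """One two-option trial with its agent condition and recorded choice.

    ``chosen_side == "none"`` is only legal on dummy/error trials or on
    trials not yet simulated/observed.  Dummy trials (first trial of each
    scanner block) and error trials are excluded from all analyses.
    """

    trial_id: int
    agent: Agent
    left: Option
    right: Option
    chosen_side: Side = "none"
    response_time: float | None = None
    is_dummy: bool = False
    is_error: bool = False
    block: int | None = None

    def __post_init__(self) -> None:
        if type(self.left) is not type(self.right):
            raise InvalidParameterError("left and right must be the same option kind")
        if self.response_time is not None and self.response_time < 0:
            raise InvalidParameterError("response_time must be >= 0 s")

    @property
    def usable(self) -> bool:
        return (not self.is_dummy) and (not self.is_error) and self.chosen_side != "none"

    @property
    def family(self) -> Family:
        return "hyperbolic" if isinstance(self.left, InterTemporalOption) else "prospect"

    @property
    def chosen(self) -> Option:
        if self.chosen_side == "none":
            raise InvalidParameterError(f"trial {self.trial_id} has no recorded choice")
        return self.left if self.chosen_side == "left" else self.right

    @property
    def unchosen(self) -> Option:
        if self.chosen_side == "none":
            raise InvalidParameterError(f"trial {self.trial_id} has no recorded choice")
        return self.right if self.chosen_side == "left" else self.left

    def with_choice(self, side: Side, response_time: float | None = None) -> "ChoiceTrial":
        return replace(self, chosen_side=side, response_time=response_time)


@dataclass(frozen=True)
class ModelVariant:
    """One cell of the 2x2 model lattice within a family.

    ``n_value_params``: 1 means a single discount rate k (or risk exponent
    alpha) shared across self and other; 2 means separate k_s/k_o (or
    alpha_s/alpha_o).  ``n_noise_params``: likewise for the softmax inverse
    temperature beta.
    """

    family: Family
    n_value_params: int
    n_noise_params: int

    def __post_init__(self) -> None:
        if self.family not in ("hyperbolic", "prospect"):
            raise InvalidParameterError(f"unknown family {self.family!r}")
        if self.n_value_params not in (1, 2) or self.n_noise_params not in (1, 2):
            raise InvalidParameterError("n_value_params and n_noise_params must be 1 or 2")

    @property
    def n_free_params(self) -> int:
        return self.n_value_params + self.n_noise_params

    @property
    def label(self) -> str:
        v = "k" if self.family == "hyperbolic" else "a"
        return f"{self.n_value_params}{v}{self.n_noise_params}b"


def variants(family: Family) -> list[ModelVariant]:
    """The four model variants of a family, ordered by free-parameter count."""
    return [
        ModelVariant(family, nv, nb)
        for nv, nb in ((1, 1), (1, 2), (2, 1), (2, 2))
    ]


@dataclass(frozen=True)
class ParamSet:
    """Concrete parameter values under a variant's sharing structure.

    ``value_self``/``value_other`` are the discount rate k (1/days) for the
    hyperbolic family or the risk exponent alpha (unitless) for prospect
    theory.  ``noise_self``/``noise_other`` are softmax inverse temperatures
    (inverse value units).  Under a shared variant the self/other members
    must be equal.
    """

    variant: ModelVariant
    value_self: float
    value_other: float
    noise_self: float
    noise_other: float

    def __post_init__(self) -> None:
        for name in ("value_self", "value_other"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise InvalidParameterError(f"{name} must be > 0, got {v}")
        for name in ("noise_self", "noise_other"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise InvalidParameterError(f"{name} must be >= 0, got {v}")
        if self.variant.n_value_params == 1 and self.value_self != self.value_other:
            raise InvalidParameterError("shared-value variant requires equal value params")
        if self.variant.n_noise_params == 1 and self.noise_self != self.noise_other:
            raise InvalidParameterError("shared-noise variant requires equal noise params")

    @classmethod
    def shared(cls, family: Family, value: float, noise: float) -> "ParamSet":
        return cls(ModelVariant(family, 1, 1), value, value, noise, noise)

    @classmethod
    def distinct(
        cls,
        family: Family,
        value_self: float,
        value_other: float,
        noise: float,
        noise_other: float | None = None,
    ) -> "ParamSet":
        n_noise = 1 if noise_other is None else 2
        return cls(
            ModelVariant(family, 2, n_noise),
            value_self,
            value_other,
            noise,
            noise if noise_other is None else noise_other,
        )

    def value_for(self, agent: Agent) -> float:
        return self.value_self if agent == "self" else self.value_other

    def noise_for(self, agent: Agent) -> float:
        return self.noise_self if agent == "self" else self.noise_other


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one variant to one subject's trials."""

    params: ParamSet
    neg_log_likelihood: float
    n_trials_used: int
    n_free_params: int
    bic: float
    converged: bool
    n_restarts: int

    def __post_init__(self) -> None:
        expected = self.n_free_params * math.log(self.n_trials_used) + 2 * self.neg_log_likelihood
        if not math.isclose(self.bic, expected, rel_tol=1e-9, abs_tol=1e-9):
            raise InvalidParameterError("bic inconsistent with negLL / q / n")


@dataclass
class TrialValueRecord:
    """Per-trial value quantities derived from a fitted model.

    ``rsv`` (relative subjective value) = SV(chosen) - SV(unchosen); the
    central per-trial regressor and, after a median split, the binary
    decoding label.
    """

    trial_id: int
    agent: Agent
    sv_chosen: float
    sv_unchosen: float
    rsv: float
    value_label: Literal["high", "low", "unassigned"] = "unassigned"
    perspective: Literal["online", "offline"] = "online"


@dataclass(frozen=True)
class SessionPlan:
    """Block layout of a scanning session.

    ``block_agents[i]`` is the agent condition of block i (single-condition
    blocks, announced at block start, alternating self/other).
    """

    block_agents: tuple[Agent, ...]
    trials_per_block: int
    n_dummy_per_block: int = 1

    @property
    def n_blocks(self) -> int:
        return len(self.block_agents)

    @property
    def n_scored(self) -> int:
        return self.n_blocks * self.trials_per_block
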