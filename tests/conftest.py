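"""Shared fixtures: toy trial tables and synthetic pattern datasets."""

import numpy as np
import pandas as pd
import pytest

from socialsv.mvpa import PatternDataset
from socialsv.synthetic import PatternGenConfig, simulate_patterns
from socialsv.types import ChoiceTrial, InterTemporalOption, ParamSet, RiskyOption


@pytest.fixture
def toy_it_trials() -> list[ChoiceTrial]:
    """Five hand-checkable intertemporal trials (self and other mixed)."""
    mk = InterTemporalOption
    return [
        ChoiceTrial(0, "self", mk(10, 0), mk(20, 30), "right"),
        ChoiceTrial(1, "self", mk(15, 5), mk(40, 180), "left"),
        ChoiceTrial(2, "other", mk(8, 2), mk(25, 60), "right"),
        ChoiceTrial(3, "other", mk(12, 10), mk(30, 90), "left"),
        ChoiceTrial(4, "self", mk(5, 1), mk(35, 120), "right"),
    ]


@pytest.fixture
def toy_risky_trials() -> list[ChoiceTrial]:
    mk = RiskyOption
    return [
        ChoiceTrial(0, "self", mk(10, 0.6), mk(30, 0.25), "left"),
        ChoiceTrial(1, "self", mk(8, 0.5), mk(40, 0.2), "right"),
        ChoiceTrial(2, "other", mk(12, 0.55), mk(25, 0.3), "right"),
        ChoiceTrial(3, "other", mk(6, 0.6), mk(35, 0.22), "left"),
        ChoiceTrial(4, "self", mk(15, 0.4), mk(20, 0.35), "right"),
    ]


def make_pattern_datasets(
    n_per_block: int = 6,
    n_features: int = 6,
    effect_size: float = 0.0,
    overlap: float = 1.0,
    seed: int = 0,
    tasks: tuple[str, ...] = ("intertemporal",),
) -> dict[tuple[str, str], PatternDataset]:
    """Balanced synthetic pattern datasets for each agent x task."""
    rng = np.random.default_rng(seed)
    rows = []
    for task in tasks:
        for agent in ("self", "other"):
            for b in range(1, 5):
                labs = ["high"] * (n_per_block // 2) + ["low"] * (
                    n_per_block - n_per_block // 2
                )
                rows.extend(
                    {"label": lab, "block": b, "agent": agent, "task": task}
                    for lab in labs
                )
    meta = pd.DataFrame(rows)
    cfg = PatternGenConfig(
        n_features=n_features,
        effect_size=effect_size,
        noise_sd=1.0,
        code_overlap=overlap,
        n_trials_per_block=n_per_block,
    )
    return simulate_patterns(meta, cfg, rng, subject_id=f"sim{seed}")


@pytest.fixture
def pattern_factory():
    return make_pattern_datasets


@pytest.fixture
def shared_hyp_params() -> ParamSet:
    return ParamSet.shared("hyperbolic", 0.02, 0.3)


@pytest.fixture
def distinct_hyp_params() -> ParamSet:
    return ParamSet.distinct("hyperbolic", 0.05, 0.005, 0.3)
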