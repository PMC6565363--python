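"""Delimited-text readers and writers for every pipeline artifact.

All formats are plain TSV/CSV with headers so they survive version
control and inspection; pattern matrices are written as one TSV per
subject/condition next to a metadata table.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidRequestError
from .mvpa import PatternDataset
from .types import (
    ChoiceTrial,
    Family,
    InterTemporalOption,
    RiskyOption,
    SessionPlan,
    TrialValueRecord,
)

CHOICE_COLUMNS = [
    "trial_id",
    "agent",
    "opt_left_amount",
    "opt_left_delay_or_prob",
    "opt_right_amount",
    "opt_right_delay_or_prob",
    "chosen_side",
    "rt_s",
    "is_dummy",
    "is_error",
    "block",
]


def trials_to_frame(trials: Sequence[ChoiceTrial]) -> pd.DataFrame:
    rows = []
    for t in trials:
        attr = (lambda o: o.delay) if t.family == "hyperbolic" else (
            lambda o: o.probability
        )
        rows.append(
            {
                "trial_id": t.trial_id,
                "agent": t.agent,
                "opt_left_amount": t.left.amount,
                "opt_left_delay_or_prob": attr(t.left),
                "opt_right_amount": t.right.amount,
                "opt_right_delay_or_prob": attr(t.right),
                "chosen_side": t.chosen_side,
                "rt_s": t.response_time if t.response_time is not None else np.nan,
                "is_dummy": int(t.is_dummy),
                "is_error": int(t.is_error),
                "block": t.block if t.block is not None else -1,
            }
        )
    return pd.DataFrame(rows, columns=CHOICE_COLUMNS)


def write_choice_table(trials: Sequence[ChoiceTrial], path: str | Path) -> None:
    trials_to_frame(trials).to_csv(path, sep="\t", index=False)


def read_choice_table(path: str | Path, family: Family) -> list[ChoiceTrial]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CHOICE_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise InvalidRequestError(f"choice table missing columns: {missing}")
    option = InterTemporalOption if family == "hyperbolic" else RiskyOption
    out = []
    for row in df.itertuples(index=False):
        rt = None if pd.isna(row.rt_s) else float(row.rt_s)
        block = getattr(row, "block", -1)
        out.append(
            ChoiceTrial(
                trial_id=int(row.trial_id),
                agent=row.agent,
                left=option(float(row.opt_left_amount), float(row.opt_left_delay_or_prob)),
                right=option(float(row.opt_right_amount), float(row.opt_right_delay_or_prob)),
                chosen_side=row.chosen_side,
                response_time=rt,
                is_dummy=bool(row.is_dummy),
                is_error=bool(row.is_error),
                block=None if block == -1 else int(block),
            )
        )
    return out


def records_to_frame(records: Sequence[TrialValueRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trial_id": r.trial_id,
                "agent": r.agent,
                "sv_chosen": r.sv_chosen,
                "sv_unchosen": r.sv_unchosen,
                "rsv": r.rsv,
                "value_label": r.value_label,
                "perspective": r.perspective,
            }
            for r in records
        ]
    )


def write_value_records(records: Sequence[TrialValueRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def write_session_plan(plan: SessionPlan, path: str | Path) -> None:
    lines = ["block\tagent\tn_scored\tn_dummy"]
    for i, agent in enumerate(plan.block_agents, start=1):
        lines.append(f"{i}\t{agent}\t{plan.trials_per_block}\t{plan.n_dummy_per_block}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pattern_dataset(dataset: PatternDataset, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{dataset.subject_id}_{dataset.task}_{dataset.agent}"
    np.savetxt(directory / f"{stem}_patterns.tsv", dataset.patterns, delimiter="\t")
    pd.DataFrame(
        {"label": dataset.labels, "block": dataset.block}
    ).to_csv(directory / f"{stem}_meta.tsv", sep="\t", index=False)


def read_pattern_dataset(
    directory: str | Path, subject_id: str, task: str, agent: str
) -> PatternDataset:
    directory = Path(directory)
    stem = f"{subject_id}_{task}_{agent}"
    patterns = np.loadtxt(directory / f"{stem}_patterns.tsv", delimiter="\t", ndmin=2)
    meta = pd.read_csv(directory / f"{stem}_meta.tsv", sep="\t")
    return PatternDataset(
        patterns=patterns,
        labels=meta["label"].to_numpy(),
        block=meta["block"].to_numpy(),
        agent=agent,
        task=task,
        subject_id=subject_id,
    )


def write_questionnaires(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")


def read_questionnaires(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subject_id")
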