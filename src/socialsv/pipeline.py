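"""End-to-end orchestration: simulate -> fit -> metrics -> decode -> attitudes.

A single config (nested dict, typically loaded from YAML) drives every
stage.  Per-stage seeds are derived from one master seed salted with the
stage name, so any stage can be reproduced in isolation; the JSON report
embeds the config hash and all derived seeds.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np

from . import io as ssv_io
from ._seeds import derive_seed
from .choice_models import FitConfig, fit_all_variants, select_model
from .errors import ConfigError
from .mvpa import DecoderConfig, build_null, decode_group, empirical_p
from .social_attitudes import aggregate_cross_decoding, first_pc, spearman_perm
from .synthetic import CohortConfig, PatternGenConfig, simulate_cohort
from .value_metrics import choice_consistency, paired_signed_rank, rt_by_split

_STAGES = ("simulate", "fit", "metrics", "decode", "null", "attitudes")

#: defaults match the study-scale analysis settings: 100 label
#: permutations per subject, 10,000 bootstrap samples, a penalty grid of
#: 100 values, ridge penalty.
_SCHEMA: dict[str, dict[str, Any]] = {
    "seed": 0,
    "cohort": {
        "n_subjects": 20,
        "n_trials": 240,
        "design": "engineered",
        "k_other_ratio": 10.0,
        "beta": 0.3,
        "n_features": 500,
        "effect_size": 0.6,
        "noise_sd": 1.0,
        "overlap_base": 0.5,
        "overlap_slope": 0.25,
        "questionnaire_noise_sd": 0.5,
    },
    "fit": {"n_restarts": 10, "maxiter": 2000},
    "mvpa": {
        "n_perm": 100,
        "n_boot": 10000,
        "grid_size": 100,
        "inner_cv": 5,
        "penalty": "ridge",
        "centering": "pattern",
    },
    "attitudes": {"n_shuffles": 10000, "standardize": True},
}

_CHOICES = {
    ("cohort", "design"): {"engineered", "random"},
    ("mvpa", "penalty"): {"ridge", "lasso"},
    ("mvpa", "centering"): {"pattern", "feature"},
}


def validate_config(config: dict | None) -> dict:
    """Merge a user config over the defaults, rejecting unknown fields."""
    config = config or {}
    if not isinstance(config, dict):
        raise ConfigError("<root>", "config must be a mapping")
    merged: dict[str, Any] = {}
    for key, default in _SCHEMA.items():
        if isinstance(default, dict):
            sub = config.get(key, {})
            if not isinstance(sub, dict):
                raise ConfigError(key, "must be a mapping")
            unknown = set(sub) - set(default)
            if unknown:
                raise ConfigError(f"{key}.{sorted(unknown)[0]}", "unknown field")
            merged[key] = {**default, **sub}
            for sub_key, value in merged[key].items():
                allowed = _CHOICES.get((key, sub_key))
                if allowed and value not in allowed:
                    raise ConfigError(f"{key}.{sub_key}", f"must be one of {sorted(allowed)}")
                default_value = default[sub_key]
                if isinstance(default_value, (int, float)) and not isinstance(
                    value, (int, float)
                ):
                    raise ConfigError(f"{key}.{sub_key}", "must be numeric")
        else:
            merged[key] = config.get(key, default)
    unknown = set(config) - set(_SCHEMA)
    if unknown:
        raise ConfigError(sorted(unknown)[0], "unknown field")
    if not isinstance(merged["seed"], int):
        raise ConfigError("seed", "must be an integer")
    return merged


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict | None = None, out_dir: str | Path | None = None) -> dict:
    """Execute every stage on a synthetic cohort and return the report.

    Stages: cohort simulation, behavioral model fitting and BIC selection,
    value metrics and RT checks, within-agent and cross-agent decoding
    with the permutation+bootstrap null, and the attitude correlation.
    If ``out_dir`` is given, the JSON report and per-stage tables are
    written there (partial outputs are retained on stage failure).
    """
    cfg = validate_config(config)
    seeds = {stage: derive_seed(cfg["seed"], stage) for stage in _STAGES}
    report: dict[str, Any] = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seeds": seeds,
    }
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def _dump() -> None:
        if out is not None:
            (out / "report.json").write_text(json.dumps(report, indent=2, default=str))

    try:
        c = cfg["cohort"]
        cohort_cfg = CohortConfig(
            n_subjects=c["n_subjects"],
            n_trials=c["n_trials"],
            design=c["design"],
            k_other_ratio=c["k_other_ratio"],
            beta=c["beta"],
            overlap_base=c["overlap_base"],
            overlap_slope=c["overlap_slope"],
            questionnaire_noise_sd=c["questionnaire_noise_sd"],
            pattern=PatternGenConfig(
                n_features=c["n_features"],
                effect_size=c["effect_size"],
                noise_sd=c["noise_sd"],
                n_trials_per_block=c["n_trials"] // 8,
            ),
        )
        cohort = simulate_cohort(cohort_cfg, seeds["simulate"])
        report["simulate"] = {
            "n_subjects": len(cohort.subjects),
            "n_trials": c["n_trials"],
        }

        fit_cfg = FitConfig(
            n_restarts=cfg["fit"]["n_restarts"],
            maxiter=cfg["fit"]["maxiter"],
            seed=seeds["fit"],
        )
        fits = {
            s.agent.subject_id: fit_all_variants(s.trials, "hyperbolic", fit_cfg)
            for s in cohort.subjects
        }
        selection = select_model(fits)
        report["fit"] = {
            "winner": selection.winner.label,
            "summed_bic": selection.table.set_index("variant")["summed_bic"].to_dict(),
        }
        if out is not None:
            selection.table.to_csv(out / "model_selection.tsv", sep="\t", index=False)

        rt_rows = []
        for s in cohort.subjects:
            params = s.agent.param_set()
            cons = choice_consistency(s.trials, params)
            rts = rt_by_split(s.trials, s.records)
            rt_rows.append(
                {
                    "subject_id": s.agent.subject_id,
                    "chose_higher_sv": cons.loc["overall", "chose_higher_sv"],
                    **rts,
                }
            )
        rt_high = [r["rt_high"] for r in rt_rows]
        rt_low = [r["rt_low"] for r in rt_rows]
        z_rt, p_rt = paired_signed_rank(rt_low, rt_high)
        report["metrics"] = {
            "mean_chose_higher_sv": float(
                np.mean([r["chose_higher_sv"] for r in rt_rows])
            ),
            "rt_low_vs_high_z": z_rt,
            "rt_low_vs_high_p": p_rt,
        }

        task = cohort.config.tasks[0]
        m = cfg["mvpa"]
        dec_cfg = DecoderConfig(
            grid_size=m["grid_size"],
            inner_cv=m["inner_cv"],
            penalty=m["penalty"],
            centering=m["centering"],
        )
        analyses = {
            "within_self": [("self", "self")],
            "within_other": [("other", "other")],
            "cross_agent": [("self", "other"), ("other", "self")],
        }
        decode_report = {}
        cross_by_subject: dict[str, dict[str, dict[str, float]]] = {}
        for tag, directions in analyses.items():
            accs = []
            nulls = []
            for d_idx, (tr_agent, te_agent) in enumerate(directions):
                pairs = [
                    (s.patterns[(tr_agent, task)], s.patterns[(te_agent, task)])
                    for s in cohort.subjects
                ]
                res = decode_group(
                    pairs, dec_cfg, derive_seed(seeds["decode"], f"{tag}{d_idx}"),
                    analysis_tag=tag,
                )
                accs.append(res.per_subject_accuracy)
                null = build_null(
                    pairs,
                    dec_cfg,
                    n_perm=m["n_perm"],
                    n_boot=m["n_boot"],
                    rng=derive_seed(seeds["null"], f"{tag}{d_idx}"),
                )
                nulls.append(null)
                if tag == "cross_agent":
                    key = f"{tr_agent}_to_{te_agent}"
                    for s, acc in zip(cohort.subjects, res.per_subject_accuracy):
                        cross_by_subject.setdefault(
                            s.agent.subject_id, {}
                        ).setdefault(task, {})[key] = float(acc)
            per_subject = np.mean(accs, axis=0)
            group_null = np.mean([n.group_null for n in nulls], axis=0)
            observed = float(per_subject.mean())
            p = (int(np.sum(group_null >= observed)) + 1) / (group_null.size + 1)
            decode_report[tag] = {
                "group_mean_accuracy": observed,
                "p_value": p,
                "null_mean": float(group_null.mean()),
            }
        report["decode"] = decode_report

        pc = first_pc(
            cohort.questionnaires, standardize=cfg["attitudes"]["standardize"]
        )
        agg = aggregate_cross_decoding(cross_by_subject)
        aligned = agg.loc[pc.scores.index]
        r, p = spearman_perm(
            pc.scores.to_numpy(),
            aligned["cross_decoding_accuracy"].to_numpy(),
            n_shuffles=cfg["attitudes"]["n_shuffles"],
            rng=seeds["attitudes"],
        )
        report["attitudes"] = {
            "pc1_variance_explained": pc.variance_explained,
            "loadings": pc.loadings.to_dict(),
            "spearman_r": r,
            "permutation_p": p,
        }
        if out is not None:
            ssv_io.write_questionnaires(cohort.questionnaires, out / "questionnaires.tsv")
    except Exception as exc:
        report["error"] = {"stage": _failed_stage(report), "message": str(exc)}
        _dump()
        raise
    _dump()
    return report


def _failed_stage(report: dict) -> str:
    order = ["simulate", "fit", "metrics", "decode", "attitudes"]
    for stage in order:
        if stage not in report:
            return stage
    return "finalize"
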