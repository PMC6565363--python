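"""Per-trial value quantities, labels, and behavioral sanity checks.

From a fitted parameter set this module derives, per usable trial, the
subjective value of the chosen and unchosen options and their difference
("relative subjective value", RSV), splits trials into high/low RSV
classes at the median, and provides the behavioral checks used to
validate the fits: choice-consistency proportions and response-time
differences between conditions (compared with a paired Wilcoxon
signed-rank test).

Two valuation perspectives exist.  *Online*: each trial is valued with
the parameters of the agent the chooser is currently deciding for.
*Offline*: the trial is valued with the other agent's parameters and the
"chosen" option is redefined as whichever option is higher-valued under
those parameters (so offline RSV is non-negative by construction);
undefined when value parameters are shared across agents.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .choice_models import sv_hyperbolic, sv_prospect
from .errors import (
    DegenerateSplitError,
    InsufficientDataError,
    InvalidRequestError,
)
from .types import ChoiceTrial, InterTemporalOption, Option, ParamSet, TrialValueRecord

Perspective = Literal["online", "offline"]


def _sv(option: Option, value_param: float) -> float:
    if isinstance(option, InterTemporalOption):
        return sv_hyperbolic(option, value_param)
    return sv_prospect(option, value_param)


def _sooner_or_likelier(a: Option, b: Option) -> Option:
    """Tie-break option: the sooner (intertemporal) or likelier (risky) one."""
    if isinstance(a, InterTemporalOption):
        return a if a.delay <= b.delay else b
    return a if a.probability >= b.probability else b


def compute_rsv(
    trials: Sequence[ChoiceTrial],
    params: ParamSet,
    perspective: Perspective = "online",
) -> list[TrialValueRecord]:
    """Per-trial chosen/unchosen subjective values and their difference.

    Online RSV can be negative (the agent may pick the lower-valued
    option); offline RSV is always >= 0 because the "chosen" option is the
    argmax under the opposite agent's parameters.  Ties in the offline
    perspective designate the sooner/likelier option as chosen.
    """
    if perspective == "offline" and params.variant.n_value_params == 1:
        raise InvalidRequestError(
            "offline values are undefined when value parameters are shared"
        )
    usable = [t for t in trials if t.usable]
    if not usable:
        raise InsufficientDataError("no usable trials")
    records = []
    for t in usable:
        if perspective == "online":
            v = params.value_for(t.agent)
            chosen, unchosen = t.chosen, t.unchosen
        else:
            other_agent = "other" if t.agent == "self" else "self"
            v = params.value_for(other_agent)
            sv_l, sv_r = _sv(t.left, v), _sv(t.right, v)
            if sv_l > sv_r:
                chosen, unchosen = t.left, t.right
            elif sv_r > sv_l:
                chosen, unchosen = t.right, t.left
            else:
                chosen = _sooner_or_likelier(t.left, t.right)
                unchosen = t.right if chosen is t.left else t.left
        sv_c, sv_u = _sv(chosen, v), _sv(unchosen, v)
        records.append(
            TrialValueRecord(
                trial_id=t.trial_id,
                agent=t.agent,
                sv_chosen=sv_c,
                sv_unchosen=sv_u,
                rsv=sv_c - sv_u,
                perspective=perspective,
            )
        )
    return records


def median_split(records: Sequence[TrialValueRecord]) -> list[TrialValueRecord]:
    """Assign high/low labels by a median split on RSV.

    Records strictly above the median are "high", strictly below "low";
    records at the median are assigned alternately in trial_id order,
    starting with the currently smaller class, which keeps the class sizes
    within one of each other.
    """
    vals = np.array([r.rsv for r in records], dtype=float)
    if vals.size < 2 or not np.all(np.isfinite(vals)):
        raise InsufficientDataError("median split needs >= 2 finite RSV values")
    if np.all(vals == vals[0]):
        raise DegenerateSplitError("all RSV values identical; split undefined")
    med = float(np.median(vals))
    out = []
    ties = []
    n_low = n_high = 0
    for r in records:
        label = "high" if r.rsv > med else ("low" if r.rsv < med else None)
        rec = TrialValueRecord(**{**r.__dict__})
        if label is None:
            ties.append(rec)
        else:
            rec.value_label = label
            n_low += label == "low"
            n_high += label == "high"
        out.append(rec)
    ties.sort(key=lambda r: r.trial_id)
    nxt = "low"  # alternation state for the balanced case
    for rec in ties:
        if n_low < n_high:
            label = "low"
        elif n_high < n_low:
            label = "high"
        else:
            label = nxt
            nxt = "high" if nxt == "low" else "low"
        rec.value_label = label
        n_low += label == "low"
        n_high += label == "high"
    return out


def choice_consistency(
    trials: Sequence[ChoiceTrial], params: ParamSet
) -> pd.DataFrame:
    """Proportions of trials choosing the higher-SV, higher-amount, and
    sooner/likelier option, per agent condition and overall.

    Trials where the two options have exactly equal SV are excluded from
    the higher-SV proportion's denominator.
    """
    usable = [t for t in trials if t.usable]
    if not usable:
        raise InsufficientDataError("no usable trials")
    rows = {}
    groups = {"self": [], "other": [], "overall": usable}
    for t in usable:
        groups[t.agent].append(t)
    for name, group in groups.items():
        if not group:
            rows[name] = dict.fromkeys(
                ["chose_higher_sv", "chose_higher_amount", "chose_sooner_or_likelier"],
                np.nan,
            )
            continue
        sv_hits = sv_n = amt_hits = soon_hits = 0
        for t in group:
            v = params.value_for(t.agent)
            sv_c, sv_u = _sv(t.chosen, v), _sv(t.unchosen, v)
            if sv_c != sv_u:
                sv_n += 1
                sv_hits += sv_c > sv_u
            amt_hits += t.chosen.amount > t.unchosen.amount
            soon_hits += _sooner_or_likelier(t.left, t.right) is t.chosen
        rows[name] = {
            "chose_higher_sv": sv_hits / sv_n if sv_n else np.nan,
            "chose_higher_amount": amt_hits / len(group),
            "chose_sooner_or_likelier": soon_hits / len(group),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def rt_by_split(
    trials: Sequence[ChoiceTrial], records: Sequence[TrialValueRecord]
) -> dict[str, float]:
    """Per-subject mean response time by value class and by agent.

    Returns means for high-RSV, low-RSV, self, and other trials; a
    condition with no recorded RTs yields NaN.  Group comparison of the
    resulting per-subject vectors is done with :func:`paired_signed_rank`.
    """
    label_by_id = {r.trial_id: r.value_label for r in records}
    bins: dict[str, list[float]] = {"high": [], "low": [], "self": [], "other": []}
    for t in trials:
        if not t.usable or t.response_time is None:
            continue
        bins[t.agent].append(t.response_time)
        lab = label_by_id.get(t.trial_id)
        if lab in ("high", "low"):
            bins[lab].append(t.response_time)
    return {
        f"rt_{k}": (float(np.mean(v)) if v else float("nan")) for k, v in bins.items()
    }


def paired_signed_rank(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test (normal approximation).

    Zero differences are dropped and ties mid-ranked.  Returns (z, p);
    all-zero differences give (0, 1) by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("x and y must be equal-length 1-D vectors")
    if x.size < 5:
        raise InsufficientDataError("signed-rank test needs n >= 5 pairs")
    if np.all(x == y):
        return 0.0, 1.0
    res = stats.wilcoxon(
        x, y, zero_method="wilcox", correction=False, alternative="two-sided",
        method="approx",
    )
    # scipy reports the z of the smaller rank sum (always <= 0 two-sided);
    # orient it so z > 0 means x tends to exceed y
    d = x - y
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    sign = np.sign(ranks[d > 0].sum() - ranks.sum() / 2)
    return float(abs(res.zstatistic) * sign), float(res.pvalue)
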