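"""Questionnaire PCA scoring and its correlation with cross-decoding.

Five self-report instruments — altruism, empathy quotient, autism
quotient, psychopathy, and social phobia — are collapsed into a single
"antisocial attitude" score: the first principal component of the
(by default z-scored) score matrix, sign-anchored so that the psychopathy
loading is positive.  The score is correlated with each subject's agent
cross-decoding accuracy by Spearman rank correlation, with significance
from a label-shuffle permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import RNGLike, as_rng
from .errors import DegenerateInputError, InsufficientDataError

INSTRUMENTS = (
    "altruism",
    "empathy_quotient",
    "autism_quotient",
    "psychopathy",
    "social_phobia",
)


@dataclass
class PCScore:
    """First-principal-component summary of the questionnaire battery."""

    scores: pd.Series  # per-subject PC1 projection
    loadings: pd.Series  # unit-norm coefficients, one per instrument
    variance_explained: float


def first_pc(table: pd.DataFrame, standardize: bool = True) -> PCScore:
    """First principal component of the five questionnaire totals.

    Columns are z-scored by default (the instruments have incommensurate
    scales, so correlation-matrix PCA is the sensible default; set
    ``standardize=False`` for covariance-matrix PCA).  The loading vector
    is unit-norm and sign-oriented so the psychopathy loading is positive,
    making higher scores more antisocial.
    """
    missing = [c for c in INSTRUMENTS if c not in table.columns]
    if missing:
        raise InsufficientDataError(f"missing questionnaire columns: {missing}")
    X = table[list(INSTRUMENTS)].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise InsufficientDataError("PCA needs at least 3 subjects")
    if not np.all(np.isfinite(X)):
        raise DegenerateInputError("questionnaire table contains missing values")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = [c for c, s in zip(INSTRUMENTS, sd) if s == 0]
        raise DegenerateInputError(f"constant questionnaire column(s): {const}")
    Xc = X - X.mean(axis=0)
    if standardize:
        Xc = Xc / sd
    # PCA via SVD of the centered (scaled) matrix
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = vt[0]
    if loadings[INSTRUMENTS.index("psychopathy")] < 0:
        loadings = -loadings
    scores = Xc @ loadings
    var = s**2
    return PCScore(
        scores=pd.Series(scores, index=table.index, name="pc1"),
        loadings=pd.Series(loadings, index=INSTRUMENTS, name="loading"),
        variance_explained=float(var[0] / var.sum()),
    )


def aggregate_cross_decoding(
    results: Mapping[object, Mapping[str, Mapping[str, float]]],
) -> pd.DataFrame:
    """Collapse per-direction, per-session cross-decoding accuracies.

    ``results[subject][session][direction]`` holds accuracies, e.g.
    ``results["s01"]["intertemporal"]["self_to_other"]``.  Directions are
    averaged within session, then sessions averaged; subjects with partial
    data keep the mean of what is available and are flagged.
    """
    rows = []
    for subject, sessions in results.items():
        session_means = []
        n_dirs = 0
        for session, directions in sessions.items():
            vals = [v for v in directions.values() if v is not None and np.isfinite(v)]
            if vals:
                session_means.append(float(np.mean(vals)))
                n_dirs += len(vals)
        if not session_means:
            raise InsufficientDataError(f"subject {subject!r} has no accuracies")
        complete = len(sessions) * 2 == n_dirs
        rows.append(
            {
                "subject_id": subject,
                "cross_decoding_accuracy": float(np.mean(session_means)),
                "n_sessions": len(session_means),
                "complete": complete,
            }
        )
    return pd.DataFrame(rows).set_index("subject_id")


def spearman_perm(
    x: Sequence[float],
    y: Sequence[float],
    n_shuffles: int = 10_000,
    rng: RNGLike = None,
) -> tuple[float, float]:
    """Spearman correlation with a two-sided label-shuffle permutation p.

    Mid-ranks are used for ties.  The null is built by shuffling one
    vector ``n_shuffles`` times; p = (#{|r_null| >= |r_obs|} + 1) /
    (n_shuffles + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 5:
        raise InsufficientDataError("need at least 5 subjects")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("correlation undefined for a constant vector")
    rng = as_rng(rng)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    r_obs = float(np.mean(rx * ry))
    perms = np.tile(ry, (n_shuffles, 1))
    perms = rng.permuted(perms, axis=1)
    r_null = perms @ rx / n
    p = (int(np.sum(np.abs(r_null) >= abs(r_obs))) + 1) / (n_shuffles + 1)
    return r_obs, p
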