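"""Penalized linear decoding of high vs low value with an empirical null.

Trial-level feature patterns (one row per trial, e.g. voxel betas) are
classified into high vs low relative-subjective-value classes with a
ridge-penalized logistic model whose penalty strength is selected on a
log-spaced grid by internal cross-validation.  Patterns are mean-centered
and unbalanced labels are randomly downsampled before every training.

Out-of-sample accuracy is estimated by leave-one-block-out
cross-validation over the four blocks of a session (a classifier is never
trained and tested on trials from the same block), and generalization is
probed by cross-decoding: training on one agent condition (or task) and
testing on the other.

Significance is assessed against a group-level empirical null rather than
a nominal 50% chance level: training labels are permuted within block
``n_perm`` times per subject to produce per-subject null accuracies, and
a group null is built by repeatedly (``n_boot`` times) sampling one null
accuracy per subject and averaging across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from ._seeds import RNGLike, as_rng, spawn
from .errors import InsufficientDataError, UntrainableError

N_BLOCKS = 4


@dataclass
class PatternDataset:
    """Trial patterns with decoding labels and CV block structure.

    ``patterns`` is trials x features; ``labels`` holds "high"/"low";
    ``block`` maps each trial to one of exactly four cross-validation
    blocks (scanner runs merged pairwise when a session has eight runs).
    """

    patterns: np.ndarray
    labels: np.ndarray
    block: np.ndarray
    agent: str
    task: str
    subject_id: str

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        self.labels = np.asarray(self.labels)
        self.block = np.asarray(self.block, dtype=int)
        if self.patterns.ndim != 2:
            raise InsufficientDataError("patterns must be a 2-D trials x features array")
        n = self.patterns.shape[0]
        if self.labels.shape != (n,) or self.block.shape != (n,):
            raise InsufficientDataError("labels/block must have one entry per trial")
        if not np.all(np.isfinite(self.patterns)):
            raise InsufficientDataError("patterns contain missing/non-finite values")
        bad = set(np.unique(self.labels)) - {"high", "low"}
        if bad:
            raise InsufficientDataError(f"labels must be high/low, found {bad}")

    def validate(self) -> "PatternDataset":
        """Check the analysis-input invariants: exactly four CV blocks,
        each holding at least two trials of each label.  (Intermediate
        datasets, e.g. downsampled training folds, need not satisfy this.)
        """
        blocks = np.unique(self.block)
        if blocks.size != N_BLOCKS:
            raise InsufficientDataError(
                f"expected exactly {N_BLOCKS} blocks, found {blocks.size}"
            )
        for b in blocks:
            for lab in ("high", "low"):
                if np.sum((self.block == b) & (self.labels == lab)) < 2:
                    raise InsufficientDataError(
                        f"block {b} has fewer than 2 '{lab}' trials"
                    )
        return self

    @property
    def n_trials(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_features(self) -> int:
        return self.patterns.shape[1]

    @property
    def blocks(self) -> np.ndarray:
        return np.unique(self.block)


@dataclass(frozen=True)
class DecoderConfig:
    """Classifier settings.

    ``grid_size`` log-spaced penalty strengths spanning 1e-4..1e4 are
    searched by ``inner_cv``-fold stratified CV on the training data.
    ``penalty`` "ridge" is the primary analysis; "lasso" is the robustness
    variant.  ``centering`` "pattern" subtracts each trial's own mean
    across features; "feature" subtracts training-fold feature means.
    """

    grid_size: int = 100
    inner_cv: int = 5
    penalty: Literal["ridge", "lasso"] = "ridge"
    centering: Literal["pattern", "feature"] = "pattern"


def mean_center(patterns: np.ndarray) -> np.ndarray:
    """Per-pattern centering: subtract each row's mean across features."""
    patterns = np.asarray(patterns, dtype=float)
    return patterns - patterns.mean(axis=1, keepdims=True)


def balance_downsample(dataset: PatternDataset, rng: RNGLike = None) -> PatternDataset:
    """Randomly subsample the majority class to the minority count."""
    idx = _balanced_indices(dataset.labels, as_rng(rng))
    return replace(
        dataset,
        patterns=dataset.patterns[idx],
        labels=dataset.labels[idx],
        block=dataset.block[idx],
    )


def _balanced_indices(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    hi = np.flatnonzero(labels == "high")
    lo = np.flatnonzero(labels == "low")
    if hi.size == 0 or lo.size == 0:
        raise UntrainableError("both labels must be present to balance")
    m = min(hi.size, lo.size)
    keep = np.concatenate(
        [
            rng.choice(hi, size=m, replace=False) if hi.size > m else hi,
            rng.choice(lo, size=m, replace=False) if lo.size > m else lo,
        ]
    )
    return np.sort(keep)


class _RidgeLogisticGridCV:
    """Ridge-penalized logistic classifier with penalty-grid selection.

    Fits the logistic loss with a pure quadratic penalty (lambda/2)|w|^2 in
    the dual (representer) parametrization w = X'a, which keeps the Newton
    systems n x n and lets all grid penalties be solved in one batched
    call.  The penalty is chosen by stratified inner CV on training
    accuracy (ties favor the stronger penalty), then the model is refit on
    the full training set.  Matches sklearn's liblinear l2 logistic
    solution (C = 1/lambda, no intercept) to solver tolerance.
    """

    def __init__(self, lambdas: np.ndarray, inner_cv: int, seed: int):
        self.lambdas = np.asarray(lambdas, dtype=float)
        self.inner_cv = inner_cv
        self.seed = seed

    @staticmethod
    def _solve(
        K: np.ndarray, y: np.ndarray, lambdas: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Batched Newton for dual coefficients plus an unpenalized
        intercept, one row per penalty."""
        n = y.size
        L = lambdas.size
        alpha = np.zeros((L, n))
        intercept = np.zeros(L)
        eye = np.eye(n)
        A = np.empty((L, n + 1, n + 1))
        rhs = np.empty((L, n + 1))
        for _ in range(50):
            scores = alpha @ K + intercept[:, None]
            sig = 1.0 / (1.0 + np.exp(np.clip(y * scores, -700, 700)))
            g = -y * sig
            weights = sig * (1.0 - sig) + 1e-12
            A[:, :n, :n] = (
                weights[:, :, None] * K[None, :, :]
                + lambdas[:, None, None] * eye
            )
            A[:, :n, n] = weights
            A[:, n, :n] = weights @ K
            A[:, n, n] = weights.sum(axis=1) + 1e-10
            rhs[:, :n] = g + lambdas[:, None] * alpha
            rhs[:, n] = g.sum(axis=1)
            delta = np.linalg.solve(A, rhs[..., None])[..., 0]
            alpha -= delta[:, :n]
            intercept -= delta[:, n]
            if np.abs(delta).max() < 1e-7:
                break
        return alpha, intercept

    def fit(self, X: np.ndarray, y_labels: np.ndarray):
        y = np.where(y_labels == "high", 1.0, -1.0)
        counts = np.bincount((y > 0).astype(int), minlength=2)
        n_splits = min(self.inner_cv, int(counts.min()))
        if self.lambdas.size == 1:  # degenerate grid: nothing to select
            self.lambda_ = float(self.lambdas[0])
        elif n_splits >= 2:
            folds = StratifiedKFold(
                n_splits=n_splits, shuffle=True, random_state=self.seed
            ).split(X, y)
            hits = np.zeros(self.lambdas.size)
            total = 0
            for tr, va in folds:
                K_tr = X[tr] @ X[tr].T
                alpha, intercept = self._solve(K_tr, y[tr], self.lambdas)
                scores = alpha @ (X[tr] @ X[va].T) + intercept[:, None]
                hits += np.sum(np.sign(scores) == y[va], axis=1)
                total += va.size
            # ties toward the strongest penalty
            best = np.flatnonzero(hits == hits.max())
            self.lambda_ = float(self.lambdas[best[np.argmax(self.lambdas[best])]])
        else:  # too few per class for an inner CV: fixed mid-grid penalty
            self.lambda_ = 1.0
        K = X @ X.T
        alpha, intercept = self._solve(K, y, np.array([self.lambda_]))
        self.alpha_ = alpha[0]
        self.intercept_ = float(intercept[0])
        self.X_train_ = X
        return self

    @property
    def coef_(self) -> np.ndarray:
        return (self.alpha_ @ self.X_train_)[None, :]

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.alpha_ @ (self.X_train_ @ X.T) + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) > 0, "high", "low")


def _fit(
    X: np.ndarray, y: np.ndarray, config: DecoderConfig, rng: np.random.Generator
):
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise UntrainableError("training set has a single label")
    seed = int(rng.integers(0, 2**31))
    if config.penalty == "ridge":
        lambdas = 1.0 / np.logspace(-4, 4, config.grid_size)
        return _RidgeLogisticGridCV(lambdas, config.inner_cv, seed).fit(X, y)
    n_splits = min(config.inner_cv, int(counts.min()))
    if n_splits >= 2:
        model = LogisticRegressionCV(
            Cs=np.logspace(-4, 4, config.grid_size),
            cv=StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed),
            penalty="l1",
            solver="liblinear",
            refit=True,
        )
    else:  # too few per class for an inner CV: fall back to a fixed penalty
        model = LogisticRegression(C=1.0, penalty="l1", solver="liblinear")
    return model.fit(X, y)


def train_classifier(
    train: PatternDataset, config: DecoderConfig | None = None, rng: RNGLike = None
):
    """Fit the penalized logistic decision rule on one training set.

    Applies the configured centering, balances labels by random
    downsampling, then fits a logistic model with the ridge (or lasso)
    penalty chosen over the log-spaced grid by internal stratified CV.
    """
    config = config or DecoderConfig()
    rng = as_rng(rng)
    X = train.patterns
    if config.centering == "pattern":
        X = mean_center(X)
    else:
        X = X - X.mean(axis=0, keepdims=True)
    idx = _balanced_indices(train.labels, rng)
    return _fit(X[idx], train.labels[idx], config, rng)


def _fold_accuracy(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    y_te: np.ndarray,
    config: DecoderConfig,
    rng: np.random.Generator,
) -> float:
    if config.centering == "pattern":
        X_tr, X_te = mean_center(X_tr), mean_center(X_te)
    else:
        mu = X_tr.mean(axis=0, keepdims=True)
        X_tr, X_te = X_tr - mu, X_te - mu
    idx = _balanced_indices(y_tr, rng)
    model = _fit(X_tr[idx], y_tr[idx], config, rng)
    return float(np.mean(model.predict(X_te) == y_te))


def cross_decode(
    train_set: PatternDataset,
    test_set: PatternDataset,
    config: DecoderConfig | None = None,
    rng: RNGLike = None,
    mode: Literal["block_paired", "full", "auto"] = "auto",
) -> float:
    """Accuracy of decoders trained on one dataset and tested on another.

    ``block_paired`` (used whenever the two sets share a session/task):
    train on three blocks of ``train_set``, test on the held-out block
    position of ``test_set``, and average over the four fold positions —
    preserving the never-train-and-test-on-the-same-run guarantee.
    ``full`` (different sessions, e.g. cross-task): train on all of
    ``train_set``, test on all of ``test_set``.  With
    ``test_set is train_set`` this is ordinary leave-one-block-out CV.
    """
    config = config or DecoderConfig()
    rng = as_rng(rng)
    if train_set.n_features != test_set.n_features:
        raise InsufficientDataError("train and test feature dimensions differ")
    if mode == "auto":
        mode = "block_paired" if train_set.task == test_set.task else "full"
    if mode == "block_paired":
        train_set.validate()
        test_set.validate()
    if mode == "full":
        return _fold_accuracy(
            train_set.patterns,
            train_set.labels,
            test_set.patterns,
            test_set.labels,
            config,
            rng,
        )
    accs = []
    fold_rngs = spawn(rng, len(train_set.blocks))
    for held_out, fold_rng in zip(train_set.blocks, fold_rngs):
        tr = train_set.block != held_out
        te = test_set.block == held_out
        if not te.any():
            continue
        try:
            accs.append(
                _fold_accuracy(
                    train_set.patterns[tr],
                    train_set.labels[tr],
                    test_set.patterns[te],
                    test_set.labels[te],
                    config,
                    fold_rng,
                )
            )
        except UntrainableError:
            warnings.warn(f"fold {held_out} untrainable; skipped", stacklevel=2)
    if not accs:
        raise UntrainableError("no trainable cross-validation fold")
    return float(np.mean(accs))


def cv_accuracy(
    dataset: PatternDataset,
    config: DecoderConfig | None = None,
    rng: RNGLike = None,
) -> float:
    """Leave-one-block-out cross-validated decoding accuracy."""
    return cross_decode(dataset, dataset, config, rng, mode="block_paired")


# ---------------------------------------------------------------------------
# permutation + bootstrap empirical null


@dataclass
class NullDistribution:
    """Per-subject permutation accuracies and the group bootstrap null."""

    per_subject_null: np.ndarray  # subjects x n_perm
    group_null: np.ndarray  # n_boot
    rng_seed: int | None = None

    @property
    def n_perm(self) -> int:
        return self.per_subject_null.shape[1]

    @property
    def n_boot(self) -> int:
        return self.group_null.size

    def summary(self) -> dict[str, float]:
        return {
            "null_mean": float(self.group_null.mean()),
            "null_p2.5": float(np.percentile(self.group_null, 2.5)),
            "null_p97.5": float(np.percentile(self.group_null, 97.5)),
        }


@dataclass
class DecodingResult:
    """Group decoding outcome for one analysis direction."""

    analysis_tag: str
    per_subject_accuracy: np.ndarray
    p_value: float | None = None
    null: NullDistribution | None = None

    @property
    def group_mean_accuracy(self) -> float:
        return float(np.mean(self.per_subject_accuracy))


def permute_labels_within_block(
    dataset: PatternDataset, rng: RNGLike = None
) -> PatternDataset:
    """Shuffle labels within each block (block label counts preserved)."""
    rng = as_rng(rng)
    labels = dataset.labels.copy()
    for b in dataset.blocks:
        idx = np.flatnonzero(dataset.block == b)
        labels[idx] = labels[rng.permutation(idx)]
    return replace(dataset, labels=labels)


SubjectPair = tuple[PatternDataset, PatternDataset]


def decode_group(
    pairs: Sequence[SubjectPair],
    config: DecoderConfig | None = None,
    rng: RNGLike = None,
    mode: Literal["block_paired", "full", "auto"] = "auto",
    analysis_tag: str = "within",
) -> DecodingResult:
    """Observed per-subject accuracies for one (train, test) analysis.

    ``pairs`` holds one (train_set, test_set) per subject; pass the same
    dataset twice for a within-condition analysis.
    """
    rngs = spawn(as_rng(rng), len(pairs))
    accs = np.array(
        [
            cross_decode(tr, te, config, r, mode=mode)
            for (tr, te), r in zip(pairs, rngs)
        ]
    )
    return DecodingResult(analysis_tag=analysis_tag, per_subject_accuracy=accs)


def build_null(
    pairs: Sequence[SubjectPair],
    config: DecoderConfig | None = None,
    n_perm: int = 100,
    n_boot: int = 10_000,
    rng: RNGLike = None,
    mode: Literal["block_paired", "full", "auto"] = "auto",
) -> NullDistribution:
    """Permutation + bootstrap empirical null for a group analysis.

    For each subject the full decoding analysis is repeated ``n_perm``
    times with training labels permuted within block (the penalty grid is
    re-selected on each permuted dataset).  The group null is built by
    sampling one null accuracy per subject uniformly and averaging across
    subjects, ``n_boot`` times.
    """
    if n_perm < 1 or n_boot < 1:
        raise InsufficientDataError("n_perm and n_boot must be >= 1")
    rng = as_rng(rng)
    subj_rngs = spawn(rng, len(pairs) + 1)
    boot_rng = subj_rngs[-1]
    per_subject = np.empty((len(pairs), n_perm))
    for s, ((train_set, test_set), s_rng) in enumerate(zip(pairs, subj_rngs)):
        perm_rngs = spawn(s_rng, 2 * n_perm)
        got = 0
        for j in range(n_perm):
            permuted = permute_labels_within_block(train_set, perm_rngs[2 * j])
            # within-condition analysis: the permuted session IS both the
            # training and testing set, so the relabeling applies to both
            # (the standard exact permutation of the full analysis);
            # cross-decoding: only the training session is relabeled
            permuted_test = permuted if test_set is train_set else test_set
            try:
                per_subject[s, got] = cross_decode(
                    permuted, permuted_test, config, perm_rngs[2 * j + 1], mode=mode
                )
                got += 1
            except UntrainableError:
                warnings.warn(
                    f"subject {train_set.subject_id}: permutation {j} untrainable",
                    stacklevel=2,
                )
        if got == 0:
            raise UntrainableError(
                f"subject {train_set.subject_id}: no successful permutation"
            )
        if got < n_perm:  # pad by resampling successful permutations
            fill = boot_rng.integers(0, got, size=n_perm - got)
            per_subject[s, got:] = per_subject[s, fill]
    draws = boot_rng.integers(0, n_perm, size=(n_boot, len(pairs)))
    group_null = per_subject[np.arange(len(pairs))[None, :], draws].mean(axis=1)
    return NullDistribution(per_subject_null=per_subject, group_null=group_null)


def empirical_p(observed_group_mean: float, null: NullDistribution) -> float:
    """One-sided empirical p with the add-one convention (never zero)."""
    if null.group_null.size == 0:
        raise InsufficientDataError("empty null distribution")
    exceed = int(np.sum(null.group_null >= observed_group_mean))
    return (exceed + 1) / (null.n_boot + 1)
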