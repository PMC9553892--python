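"""One-vs-all L2 logistic identification with grouped CV tuning and
sliding-window majority voting.

Identification is framed as one binary L2-regularized logistic regression
per subject; a sample's predicted identity is the subject whose classifier
scores highest. The regularization strength C is tuned by grid search under
grouped ten-fold cross-validation, where a group is one task recording (its
~64 segments stay together so that fold splits never leak temporally
adjacent segments). At test time, 15 consecutive raw predictions are
combined into one final prediction by majority vote, which turns 64 raw
predictions per 65-s task into 50 final ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier

from .features import FeatureSet

DEFAULT_C_GRID = (1e-2, 1e-1, 1.0, 10.0, 100.0)


def _make_estimator(C: float) -> OneVsRestClassifier:
    # scikit-learn defaults for tolerance/class weights; lbfgs is
    # deterministic for fixed data.
    return OneVsRestClassifier(
        LogisticRegression(C=C, solver="lbfgs", max_iter=1000),
        n_jobs=None,
    )


@dataclass
class IdentityModel:
    """Per-subject linear discriminators over one feature space."""

    labels: np.ndarray  # sorted subject ids, one row of coef per label
    coef: np.ndarray  # (n_subjects, n_features)
    intercept: np.ndarray
    C: float
    mode: str
    feature_channels: np.ndarray | None
    feature_freqs: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.coef.shape[1]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef.T + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        if X.shape[0] == 0:
            return np.empty(0, dtype=self.labels.dtype)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"model expects {self.n_features} features, got {X.shape[1]}"
            )
        return self.labels[np.argmax(self.decision_scores(X), axis=1)]

    def save(self, path: str | Path) -> None:
        payload = {
            "labels": self.labels.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "C": self.C,
            "mode": self.mode,
            "feature_channels": None
            if self.feature_channels is None
            else list(map(str, self.feature_channels)),
            "feature_freqs": self.feature_freqs.tolist(),
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "IdentityModel":
        d = json.loads(Path(path).read_text())
        return cls(
            labels=np.array(d["labels"]),
            coef=np.array(d["coef"]),
            intercept=np.array(d["intercept"]),
            C=d["C"],
            mode=d["mode"],
            feature_channels=None
            if d["feature_channels"] is None
            else np.array(d["feature_channels"]),
            feature_freqs=np.array(d["feature_freqs"]),
            metadata=d["metadata"],
        )


@dataclass(frozen=True)
class VotingScheme:
    """Majority voting over a sliding window of raw predictions."""

    window: int = 15
    stride: int = 1
    tie_break: str = "lowest"  # modal ties go to the lowest subject label

    def __post_init__(self) -> None:
        if self.window < 1 or self.stride < 1:
            raise ValueError("window and stride must be >= 1")


@dataclass
class PredictionSet:
    """Raw (per segment) or final (per voting window) predictions."""

    frame: pd.DataFrame  # metadata columns + 'true' + 'predicted'
    level: str  # "raw" | "final"
    group_cols: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.frame)


def _group_table(features: FeatureSet) -> np.ndarray:
    cols = list(features.group_cols)
    return features.meta.groupby(cols, sort=True).ngroup().to_numpy()


def assign_group_folds(groups: np.ndarray, n_folds: int, seed: int = 0) -> np.ndarray:
    """Shuffle groups and assign each one whole to a fold.

    Returns a per-sample fold index; every sample of a group lands in the
    same fold.
    """
    uniq = np.unique(groups)
    if uniq.size < n_folds:
        raise ValueError(f"{uniq.size} groups < {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq)
    fold_of_group = np.empty(uniq.size, dtype=int)
    for fold, chunk in enumerate(np.array_split(order, n_folds)):
        fold_of_group[chunk] = fold
    return fold_of_group[np.searchsorted(uniq, groups)]


def tune_C(
    train: FeatureSet,
    grid=DEFAULT_C_GRID,
    n_folds: int = 10,
    seed: int = 0,
    return_scores: bool = False,
):
    """Grid-search C by grouped n-fold CV on raw segment accuracy.

    Groups (whole task recordings) are shuffled and assigned whole to
    folds; the returned C maximizes the mean fold accuracy, with ties going
    to the smallest C.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty C grid")
    groups = _group_table(train)
    fold = assign_group_folds(groups, n_folds, seed)

    y = train.meta["subject"].to_numpy()
    scores = {}
    for C in sorted(grid):
        accs = []
        for k in range(n_folds):
            est = _make_estimator(C)
            est.fit(train.X[fold != k], y[fold != k])
            accs.append(float(np.mean(est.predict(train.X[fold == k]) == y[fold == k])))
        scores[C] = float(np.mean(accs))
    best = max(sorted(scores), key=lambda c: scores[c])  # ties -> smallest C
    best = min(c for c in scores if scores[c] == scores[best])
    return (best, scores) if return_scores else best


def fit(train: FeatureSet, C: float = 1.0, metadata: dict | None = None) -> IdentityModel:
    """Fit one-vs-all L2 logistic discriminators on a training FeatureSet."""
    y = train.meta["subject"].to_numpy()
    labels = np.unique(y)
    if labels.size < 2:
        raise ValueError("need at least two subjects to fit an identity model")
    est = _make_estimator(C)
    est.fit(train.X, y)
    if len(est.estimators_) == 1:
        # two subjects: one binary discriminator, mirrored for the negative class
        e = est.estimators_[0]
        coef = np.vstack([-e.coef_[0], e.coef_[0]])
        intercept = np.array([-e.intercept_[0], e.intercept_[0]])
    else:
        coef = np.vstack([e.coef_[0] for e in est.estimators_])
        intercept = np.array([e.intercept_[0] for e in est.estimators_])
    meta = {
        "weeks": sorted(map(int, train.meta["week"].unique())),
        "tasks": sorted(train.meta["task"].unique()),
        "n_train": int(train.n_samples),
    }
    meta.update(metadata or {})
    return IdentityModel(
        labels=est.classes_,
        coef=coef,
        intercept=intercept,
        C=C,
        mode=train.mode,
        feature_channels=train.feature_channels,
        feature_freqs=train.feature_freqs,
        metadata=meta,
    )


def predict_raw(model: IdentityModel, test: FeatureSet) -> PredictionSet:
    """Raw per-segment identity predictions (argmax over subject scores)."""
    frame = test.meta.copy()
    frame["true"] = test.meta["subject"]
    frame["predicted"] = model.predict(test.X)
    return PredictionSet(frame=frame, level="raw", group_cols=test.group_cols)


def _vote_group(labels_idx: np.ndarray, n_labels: int, scheme: VotingScheme) -> np.ndarray:
    n = labels_idx.size
    if n < scheme.window:
        raise ValueError(f"group of {n} raw predictions is shorter than the "
                         f"{scheme.window}-sample voting window")
    onehot = np.zeros((n + 1, n_labels), dtype=np.int32)
    onehot[np.arange(1, n + 1), labels_idx] = 1
    cum = np.cumsum(onehot, axis=0)
    counts = cum[scheme.window:] - cum[:-scheme.window]
    counts = counts[:: scheme.stride]
    # argmax returns the first maximum: modal ties resolve to the lowest label
    return np.argmax(counts, axis=1)


def vote(raw: PredictionSet, scheme: VotingScheme | None = None) -> PredictionSet:
    """Aggregate raw predictions into final ones by sliding majority vote.

    Voting runs inside each (subject, week, task, block[, channel]) group in
    segment order and never crosses group boundaries; a group of n raw
    predictions yields n - window + 1 finals at stride 1.
    """
    if raw.level != "raw":
        raise ValueError("vote() expects raw predictions")
    scheme = scheme or VotingScheme()
    label_space = np.unique(
        np.concatenate([raw.frame["predicted"].to_numpy(), raw.frame["true"].to_numpy()])
    )
    lookup = {lab: i for i, lab in enumerate(label_space)}
    out_rows = []
    for key, grp in raw.frame.groupby(list(raw.group_cols), sort=True):
        grp = grp.sort_values("segment")
        idx = np.array([lookup[v] for v in grp["predicted"]])
        finals = _vote_group(idx, label_space.size, scheme)
        base = dict(zip(raw.group_cols, key if isinstance(key, tuple) else (key,)))
        base["true"] = grp["true"].iloc[0]
        base["pair"] = grp["pair"].iloc[0] if "pair" in grp.columns else None
        for wi, f in enumerate(finals):
            out_rows.append({**base, "segment": wi, "predicted": label_space[f]})
    return PredictionSet(
        frame=pd.DataFrame(out_rows), level="final", group_cols=raw.group_cols
    )


def accuracy(pred: PredictionSet) -> float:
    """Percentage of correct predictions at this PredictionSet's level."""
    if len(pred) == 0:
        raise ValueError("no predictions to score")
    return 100.0 * float(
        np.mean(pred.frame["predicted"].to_numpy() == pred.frame["true"].to_numpy())
    )


def confusion(pred: PredictionSet, labels=None, normalize: bool = True) -> pd.DataFrame:
    """Confusion matrix (rows: true subject, columns: predicted).

    With ``normalize`` each row is divided by its total count, so rows sum
    to one.
    """
    if len(pred) == 0:
        raise ValueError("no predictions to tabulate")
    if labels is None:
        labels = np.unique(pred.frame["true"])
    mat = pd.crosstab(pred.frame["true"], pred.frame["predicted"])
    mat = mat.reindex(index=labels, columns=labels, fill_value=0).astype(float)
    if normalize:
        mat = mat.div(mat.sum(axis=1), axis=0)
    return mat
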