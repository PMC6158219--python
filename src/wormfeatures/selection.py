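"""Feature selection by recursive elimination with loss-delta importance.

The pipeline mirrors the strain-classification workflow: drop features that
are NaN in more than 2.5% of worms, impute remaining NaNs with the
population mean, z-normalize, split 80/20 within each strain, fit a
multinomial logistic regression by stochastic gradient descent on the
categorical cross-entropy, rank each feature by the loss increase when its
contribution is ablated from the fitted model (no refit), and drop the
least important features down to the next power of two, repeating until one
feature remains.  The whole procedure is repeated over independent random
splits and the test accuracy recorded at every feature-set size.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .io import FeatureTable, ValidationError


# ---------------------------------------------------------------------------
# preprocessing


def clean_features(
    table: FeatureTable, nan_fraction_threshold: float = 0.025
) -> FeatureTable:
    """Drop features NaN in more than the threshold fraction of worms and
    impute the rest with the feature's population mean.  Idempotent."""
    values = table.values
    nan_frac = np.isnan(values).mean(axis=0)
    keep = nan_frac <= nan_fraction_threshold
    if not keep.any():
        raise ValidationError("cleaning removed every feature")
    values = values[:, keep].copy()
    names = [n for n, k in zip(table.feature_names, keep) if k]
    col_mean = np.nanmean(values, axis=0)
    nan_idx = np.where(np.isnan(values))
    values[nan_idx] = np.take(col_mean, nan_idx[1])
    return replace(table, values=values, feature_names=names)


def znormalize(table: FeatureTable) -> tuple[FeatureTable, np.ndarray, np.ndarray]:
    """Subtract the feature mean and divide by its (population) standard
    deviation.  Constant features become all zeros (sd recorded as 0)."""
    mean = table.values.mean(axis=0)
    sd = table.values.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) z-normalized to zeros",
            stacklevel=2,
        )
    safe_sd = np.where(constant, 1.0, sd)
    values = (table.values - mean) / safe_sd
    return replace(table, values=values), mean, np.where(constant, 0.0, sd)


def split_per_strain(
    table: FeatureTable, train_fraction: float = 0.8, seed: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Random train/test split within each strain (reproducible by seed)."""
    rng = np.random.default_rng(seed)
    strains = np.asarray(table.strain_labels)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for strain in sorted(set(strains)):
        idx = np.flatnonzero(strains == strain)
        if idx.size < 2:
            raise ValidationError(
                f"strain {strain!r} has {idx.size} worm(s); need at least 2 to split"
            )
        perm = rng.permutation(idx)
        n_train = int(np.clip(round(train_fraction * idx.size), 1, idx.size - 1))
        train_idx += perm[:n_train].tolist()
        test_idx += perm[n_train:].tolist()
    train_idx.sort()
    test_idx.sort()

    def _take(idx: list[int]) -> FeatureTable:
        return replace(
            table,
            values=table.values[idx],
            worm_ids=[table.worm_ids[i] for i in idx],
            strain_labels=[table.strain_labels[i] for i in idx],
        )

    return _take(train_idx), _take(test_idx)


# ---------------------------------------------------------------------------
# softmax classifier


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class SoftmaxClassifier:
    """Multinomial logistic regression trained by minibatch SGD on the
    categorical cross-entropy loss (optionally L2-regularized)."""

    learning_rate: float = 0.05
    n_epochs: int = 60
    batch_size: int = 32
    l2: float = 1e-4
    lr_decay: float = 0.01  # lr_t = lr / (1 + decay * epoch)
    seed: int = 0
    classes_: np.ndarray = field(default=None, init=False)  # type: ignore[assignment]
    weights_: np.ndarray = field(default=None, init=False)  # type: ignore[assignment]
    intercept_: np.ndarray = field(default=None, init=False)  # type: ignore[assignment]

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SoftmaxClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValidationError("need at least 2 classes to fit a classifier")
        n, f = X.shape
        c = self.classes_.size
        y_idx = np.searchsorted(self.classes_, y)
        onehot = np.eye(c)[y_idx]
        rng = np.random.default_rng(self.seed)
        W = np.zeros((f, c))
        b = np.zeros(c)
        for epoch in range(self.n_epochs):
            lr = self.learning_rate / (1.0 + self.lr_decay * epoch)
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                Xb, Tb = X[batch], onehot[batch]
                P = _softmax(Xb @ W + b)
                G = (P - Tb) / len(batch)
                W -= lr * (Xb.T @ G + self.l2 * W)
                b -= lr * G.sum(axis=0)
        self.weights_ = W
        self.intercept_ = b
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights_ + self.intercept_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _softmax(self.decision_function(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        """Mean categorical cross-entropy (data term only)."""
        y_idx = np.searchsorted(self.classes_, np.asarray(y))
        logp = np.log(np.clip(self.predict_proba(X), 1e-300, None))
        return float(-np.mean(logp[np.arange(len(y_idx)), y_idx]))

    def config(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "n_epochs": self.n_epochs,
            "batch_size": self.batch_size,
            "l2": self.l2,
            "lr_decay": self.lr_decay,
            "seed": self.seed,
        }


def fit_classifier(
    train: FeatureTable, seed: int = 0, **kwargs
) -> SoftmaxClassifier:
    """Fit the softmax classifier on a (cleaned, normalized) feature table."""
    model = SoftmaxClassifier(seed=seed, **kwargs)
    return model.fit(train.values, np.asarray(train.strain_labels))


# ---------------------------------------------------------------------------
# importance and elimination


def rank_importance(
    model: SoftmaxClassifier, X: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Per-feature loss delta when the feature's contribution is ablated.

    Ablation zeroes the (normalized) column in the fitted model without
    refitting; larger delta means more important.  Vectorized over features
    by subtracting each column's contribution from the decision scores.
    """
    X = np.asarray(X, dtype=float)
    y_idx = np.searchsorted(model.classes_, np.asarray(y))
    Z = model.decision_function(X)
    base = _loss_from_scores(Z, y_idx)
    deltas = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        Zj = Z - np.outer(X[:, j], model.weights_[j])
        deltas[j] = _loss_from_scores(Zj, y_idx) - base
    return deltas


def _loss_from_scores(Z: np.ndarray, y_idx: np.ndarray) -> float:
    logp = np.log(np.clip(_softmax(Z), 1e-300, None))
    return float(-np.mean(logp[np.arange(len(y_idx)), y_idx]))


def next_power_of_two_schedule(n_features: int) -> list[int]:
    """Feature-set sizes for recursive elimination: the starting size, then
    the largest power of two strictly below it, then halving down to 1."""
    if n_features < 1:
        raise ValidationError("n_features must be at least 1")
    schedule = [n_features]
    if n_features == 1:
        return schedule
    size = 2 ** int(np.ceil(np.log2(n_features)) - 1)
    if size == n_features:  # exact power of two: first drop is a halving
        size //= 2
    while size >= 1:
        schedule.append(size)
        size //= 2
    return schedule


@dataclass
class SelectionResult:
    """Outcome of repeated recursive feature elimination."""

    schedule: list[int]
    retained: dict[int, list[str]]  # per size, from the first repeat
    retained_by_repeat: list[dict[int, list[str]]]
    accuracy: np.ndarray  # (repeats, len(schedule))
    repeats: int
    seeds: list[int]
    classifier_config: dict

    def mean_accuracy(self) -> np.ndarray:
        return self.accuracy.mean(axis=0)

    def to_json(self) -> dict:
        return {
            "schedule": self.schedule,
            "retained": {str(k): v for k, v in self.retained.items()},
            "accuracy": self.accuracy.tolist(),
            "repeats": self.repeats,
            "seeds": self.seeds,
            "classifier_config": self.classifier_config,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1)


def recursive_elimination(
    table: FeatureTable,
    repeats: int = 10,
    seed: int = 0,
    train_fraction: float = 0.8,
    classifier_kwargs: dict | None = None,
) -> SelectionResult:
    """Repeated RFE over fresh per-strain splits.

    ``table`` must already be cleaned and normalized.  Within a repeat the
    retained sets are nested: fit, rank by ablation loss delta, drop the
    least important features to the next power of two, refit.  Ties in the
    deltas break by feature-name order for determinism.
    """
    classifier_kwargs = classifier_kwargs or {}
    schedule = next_power_of_two_schedule(table.n_features)
    seeds = [seed + r for r in range(repeats)]
    accuracy = np.zeros((repeats, len(schedule)))
    retained_by_repeat: list[dict[int, list[str]]] = []
    cfg: dict = {}
    for r, rseed in enumerate(seeds):
        train, test = split_per_strain(table, train_fraction, seed=rseed)
        current_train, current_test = train, test
        retained: dict[int, list[str]] = {}
        for k, size in enumerate(schedule):
            try:
                model = fit_classifier(current_train, seed=rseed, **classifier_kwargs)
            except ValidationError as exc:
                raise ValidationError(
                    f"repeat {r}, size {size}: {exc}"
                ) from exc
            cfg = model.config()
            accuracy[r, k] = model.accuracy(
                current_test.values, np.asarray(current_test.strain_labels)
            )
            retained[size] = list(current_train.feature_names)
            if k + 1 == len(schedule):
                break
            next_size = schedule[k + 1]
            deltas = rank_importance(
                model, current_train.values, np.asarray(current_train.strain_labels)
            )
            order = sorted(
                range(len(deltas)),
                key=lambda j: (-deltas[j], current_train.feature_names[j]),
            )
            keep = sorted(order[:next_size])
            keep_names = [current_train.feature_names[j] for j in keep]
            current_train = current_train.select(keep_names)
            current_test = current_test.select(keep_names)
        retained_by_repeat.append(retained)
    return SelectionResult(
        schedule=schedule,
        retained=retained_by_repeat[0],
        retained_by_repeat=retained_by_repeat,
        accuracy=accuracy,
        repeats=repeats,
        seeds=seeds,
        classifier_config=cfg,
    )
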