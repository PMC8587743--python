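"""The 1D CNN rhythm classifier, its training protocol, and evaluation.

Architecture (fixed by :class:`ModelSpec`): four Conv1D blocks of 256, 128,
64 and 32 filters (kernel 3, stride 1, ReLU, each followed by batch
normalization), dropout 0.2, max-pooling of size 2, then dense layers of 8
(ReLU) and 1 (sigmoid). The input is the 12-feature HRV vector treated as a
length-12 single-channel sequence; with 'same' padding the lengths run
12 -> 12 -> 12 -> 12 -> 12 -> 6 -> flatten 192 -> 8 -> 1.

Training: Adam, binary cross-entropy, mini-batches of 16, 50 epochs, an 80/20
stratified outer split with stratified 5-fold cross-validation inside the 80%,
and a final refit on the full 80%. Cross-modality adaptation finetunes all
weights at a reduced learning rate under a stratified 4-fold 75/25 scheme.

The classifier follows the scikit-learn estimator protocol (``fit`` /
``predict`` / ``predict_proba``, ``get_params``/``set_params``, fitted
attributes with trailing underscores) and composes with sklearn model
selection utilities.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from ._nn import Adam, build_layers, sigmoid
from .errors import ParameterError, StratificationError
from .preprocess import ZScoreScaler
from .dataset import stratified_split

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "ConfusionCounts",
    "MetricsReport",
    "ConvNetAFClassifier",
    "build_model",
    "train_cv",
    "finetune",
    "evaluate",
    "compute_metrics",
    "compute_auc",
    "save_model",
    "load_model",
]


# --------------------------------------------------------------------------
# Specs and configs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Layer hyperparameters of the convolutional classifier."""

    n_features: int = 12
    n_filters: tuple[int, ...] = (256, 128, 64, 32)
    kernel_size: int = 3
    dropout_rate: float = 0.2
    pool_size: int = 2
    dense_units: int = 8

    def __post_init__(self) -> None:
        if self.n_features < self.kernel_size:
            raise ParameterError("input length shorter than the kernel")


@dataclass
class TrainConfig:
    """Training protocol parameters."""

    batch_size: int = 16
    epochs: int = 50
    learning_rate: float = 1e-3
    cv_folds: int = 5
    train_frac: float = 0.8
    seed: int = 0
    finetune_folds: int = 4
    finetune_epochs: int = 20
    finetune_lr_mult: float = 0.1

    def __post_init__(self) -> None:
        if self.cv_folds < 2 or self.finetune_folds < 2:
            raise ParameterError("folds must be >= 2")
        if not 0 < self.train_frac < 1:
            raise ParameterError("train_frac must be in (0, 1)")


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with AF as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ParameterError("counts must be non-negative")
        if self.total == 0:
            raise ParameterError("empty confusion table")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        )


@dataclass
class MetricsReport:
    """Evaluation metrics on the percent scale (0-100); nan where undefined."""

    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    auc: float
    counts: ConfusionCounts | None = None
    undefined: list[str] = field(default_factory=list)

    def to_dict(self, ndigits: int = 2) -> dict:
        return {
            k: (round(getattr(self, k), ndigits) if np.isfinite(getattr(self, k)) else None)
            for k in ("accuracy", "sensitivity", "specificity", "f1", "auc")
        }


def compute_metrics(
    counts: ConfusionCounts, scores=None, labels=None
) -> MetricsReport:
    """Accuracy, sensitivity, specificity, F1 (and AUC if scores are given).

    All on the percent scale. A zero denominator flags the metric as
    undefined (nan) instead of raising.
    """
    undefined: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return 100.0 * num / den

    acc = ratio(counts.tp + counts.tn, counts.total, "accuracy")
    sens = ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    spec = ratio(counts.tn, counts.tn + counts.fp, "specificity")
    f1 = ratio(counts.tp, counts.tp + 0.5 * (counts.fp + counts.fn), "f1")
    if scores is not None and labels is not None:
        try:
            auc = 100.0 * compute_auc(scores, labels)
        except StratificationError:
            undefined.append("auc")
            auc = float("nan")
    else:
        auc = float("nan")
    return MetricsReport(acc, sens, spec, f1, auc, counts=counts, undefined=undefined)


def compute_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with half credit for ties, as a fraction."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise StratificationError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks give 0.5 credit to ties
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# --------------------------------------------------------------------------
# Estimator
# --------------------------------------------------------------------------

class ConvNetAFClassifier(ClassifierMixin, BaseEstimator):
    """1D CNN for NSR-vs-AF classification of 12 HRV features.

    Parameters mirror :class:`ModelSpec` and :class:`TrainConfig`; all
    randomness (weight init, shuffling, dropout) derives from
    ``random_state``. ``warm_start=True`` makes ``fit`` continue training the
    existing weights (used for cross-modality finetuning) instead of
    re-initializing.
    """

    def __init__(
        self,
        n_filters=(256, 128, 64, 32),
        kernel_size=3,
        dense_units=8,
        dropout_rate=0.2,
        pool_size=2,
        epochs=50,
        batch_size=16,
        learning_rate=1e-3,
        beta_1=0.9,
        beta_2=0.999,
        epsilon=1e-7,
        shuffle=True,
        warm_start=False,
        random_state=None,
    ):
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.dense_units = dense_units
        self.dropout_rate = dropout_rate
        self.pool_size = pool_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.beta_1 = beta_1
        self.beta_2 = beta_2
        self.epsilon = epsilon
        self.shuffle = shuffle
        self.warm_start = warm_start
        self.random_state = random_state

    # -- construction ------------------------------------------------------

    def initialize(self, n_features: int) -> "ConvNetAFClassifier":
        """Build the (untrained) network deterministically from random_state."""
        if n_features < self.kernel_size:
            raise ParameterError("input length shorter than the kernel")
        init_rng = np.random.default_rng(self.random_state)
        self._train_rng = np.random.default_rng(
            None if self.random_state is None else int(self.random_state) + 0x5EED
        )
        self.network_ = build_layers(
            n_features,
            n_filters=tuple(self.n_filters),
            kernel_size=self.kernel_size,
            dropout_rate=self.dropout_rate,
            pool_size=self.pool_size,
            dense_units=self.dense_units,
            rng=init_rng,
            dropout_rng=self._train_rng,
        )
        self.n_features_in_ = n_features
        return self

    # -- training ----------------------------------------------------------

    def _run_epochs(self, X, y, epochs, learning_rate):
        n = X.shape[0]
        opt = Adam(
            self.network_.params, lr=learning_rate,
            beta_1=self.beta_1, beta_2=self.beta_2, epsilon=self.epsilon,
        )
        X3 = X[:, :, None]
        losses = []
        for _ in range(epochs):
            order = self._train_rng.permutation(n) if self.shuffle else np.arange(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X3[idx], y[idx]
                logits = self.network_.forward(xb, training=True)[:, 0]
                p = sigmoid(logits)
                eps = 1e-12
                epoch_loss += float(
                    -np.sum(yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps))
                )
                dlogit = ((p - yb) / len(idx))[:, None]
                self.network_.backward(dlogit)
                opt.step(self.network_.grads)
            losses.append(epoch_loss / n)
        return losses

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if not np.all(np.isin(classes, [0, 1])):
            raise ParameterError("labels must be 0 (NSR) / 1 (AF)")
        y = y.astype(float)
        continuing = self.warm_start and hasattr(self, "network_")
        if not continuing:
            self.initialize(X.shape[1])
        elif X.shape[1] != self.n_features_in_:
            raise ParameterError("feature count changed since initialization")
        self.classes_ = np.array([0, 1])
        self.loss_curve_ = self._run_epochs(
            X, y, self.epochs, self.learning_rate
        )
        return self

    def finetune(self, X, y, epochs=None, learning_rate=None) -> "ConvNetAFClassifier":
        """Continue training the fitted network (all layers trainable)."""
        check_is_fitted(self, "network_")
        X, y = check_X_y(X, y)
        self.loss_curve_ = self._run_epochs(
            X,
            y.astype(float),
            self.epochs if epochs is None else epochs,
            (self.learning_rate if learning_rate is None else learning_rate),
        )
        return self

    # -- inference ---------------------------------------------------------

    def decision_function(self, X):
        check_is_fitted(self, "network_")
        X = check_array(X)
        return self.network_.forward(X[:, :, None], training=False)[:, 0]

    def predict_proba(self, X):
        p = sigmoid(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def clone_fitted(self) -> "ConvNetAFClassifier":
        """Deep copy carrying the trained weights (for finetuning variants)."""
        return copy.deepcopy(self)


def build_model(spec: ModelSpec | None = None, seed: int | None = 0) -> ConvNetAFClassifier:
    """Instantiate the classifier from a spec with deterministic init."""
    spec = spec or ModelSpec()
    clf = ConvNetAFClassifier(
        n_filters=spec.n_filters,
        kernel_size=spec.kernel_size,
        dense_units=spec.dense_units,
        dropout_rate=spec.dropout_rate,
        pool_size=spec.pool_size,
        random_state=seed,
    )
    return clf.initialize(spec.n_features)


# --------------------------------------------------------------------------
# Protocols: CV training, finetuning, evaluation
# --------------------------------------------------------------------------

@dataclass
class TrainCVResult:
    model: ConvNetAFClassifier
    scaler: ZScoreScaler | None
    fold_reports: list[MetricsReport]
    cv_mean: dict
    cv_sd: dict
    holdout_report: MetricsReport


def _aggregate(reports: list[MetricsReport]):
    keys = ("accuracy", "sensitivity", "specificity", "f1", "auc")
    arr = {k: np.array([getattr(r, k) for r in reports]) for k in keys}
    mean = {k: float(np.nanmean(v)) for k, v in arr.items()}
    sd = {k: float(np.nanstd(v, ddof=1)) if len(reports) > 1 else 0.0 for k, v in arr.items()}
    return mean, sd


def evaluate(model: ConvNetAFClassifier, X, y, scaler=None) -> MetricsReport:
    """Confusion-count metrics + AUC of a fitted model on (X, y)."""
    if scaler is not None:
        X = scaler.transform(X)
    scores = model.predict_proba(X)[:, 1]
    pred = (scores >= 0.5).astype(int)
    counts = ConfusionCounts.from_predictions(y, pred)
    return compute_metrics(counts, scores=scores, labels=y)


def train_cv(
    X,
    y,
    config: TrainConfig | None = None,
    scaling: str = "train",
) -> TrainCVResult:
    """Stratified 80/20 split, 5-fold CV inside the 80%, refit, holdout eval.

    ``scaling``: ``"train"`` fits z-score stats on the 80% partition only
    (leakage-free default), ``"global"`` fits on everything (reproducing the
    source protocol), ``"none"`` assumes pre-scaled input.
    """
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    train_idx, test_idx = stratified_split(y, config.train_frac, config.seed)

    scaler: ZScoreScaler | None = None
    if scaling == "train":
        scaler = ZScoreScaler().fit(X[train_idx])
    elif scaling == "global":
        scaler = ZScoreScaler().fit(X)
    elif scaling != "none":
        raise ParameterError("scaling must be 'train', 'global' or 'none'")
    Xs = scaler.transform(X) if scaler is not None else X

    Xtr, ytr = Xs[train_idx], y[train_idx]
    skf = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.seed
    )
    fold_reports = []
    for k, (fit_idx, val_idx) in enumerate(skf.split(Xtr, ytr)):
        if len(np.unique(ytr[fit_idx])) < 2 or len(np.unique(ytr[val_idx])) < 2:
            raise StratificationError(f"fold {k} lost a class")
        fold_clf = ConvNetAFClassifier(
            epochs=config.epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            random_state=config.seed * 1000 + k,
        )
        fold_clf.fit(Xtr[fit_idx], ytr[fit_idx])
        fold_reports.append(evaluate(fold_clf, Xtr[val_idx], ytr[val_idx]))

    final = ConvNetAFClassifier(
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        random_state=config.seed,
    )
    final.fit(Xtr, ytr)
    holdout = evaluate(final, Xs[test_idx], y[test_idx])
    cv_mean, cv_sd = _aggregate(fold_reports)
    return TrainCVResult(final, scaler, fold_reports, cv_mean, cv_sd, holdout)


def save_model(directory, model: ConvNetAFClassifier, scaler: ZScoreScaler | None = None) -> None:
    """Persist weights (.npz) plus a JSON echo of the architecture/params."""
    import json
    from pathlib import Path

    check_is_fitted(model, "network_")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    weights = model.network_.get_weights()
    np.savez(directory / "weights.npz", **{f"w{i}": w for i, w in enumerate(weights)})
    spec = {
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in model.get_params().items()
        },
        "n_features_in": int(model.n_features_in_),
        "scaler": None
        if scaler is None
        else {"mean": scaler.mean_.tolist(), "sd": scaler.sd_.tolist()},
    }
    (directory / "model.json").write_text(json.dumps(spec, indent=1, sort_keys=True))


def load_model(directory):
    """Load a persisted model; returns ``(model, scaler_or_None)``."""
    import json
    from pathlib import Path

    directory = Path(directory)
    spec = json.loads((directory / "model.json").read_text())
    params = dict(spec["params"])
    if isinstance(params.get("n_filters"), list):
        params["n_filters"] = tuple(params["n_filters"])
    clf = ConvNetAFClassifier(**params)
    clf.initialize(spec["n_features_in"])
    with np.load(directory / "weights.npz") as npz:
        weights = [npz[f"w{i}"] for i in range(len(npz.files))]
    clf.network_.set_weights(weights)
    clf.classes_ = np.array([0, 1])
    clf.loss_curve_ = []
    scaler = None
    if spec["scaler"] is not None:
        scaler = ZScoreScaler()
        scaler.mean_ = np.asarray(spec["scaler"]["mean"])
        scaler.sd_ = np.asarray(spec["scaler"]["sd"])
        scaler.n_features_in_ = scaler.mean_.size
    return clf, scaler


@dataclass
class FinetuneResult:
    fold_reports: list[MetricsReport]
    mean: dict
    sd: dict
    pooled_report: MetricsReport


def finetune(
    model: ConvNetAFClassifier,
    X,
    y,
    config: TrainConfig | None = None,
    scaler_policy: str = "refit",
    base_scaler: ZScoreScaler | None = None,
) -> FinetuneResult:
    """Adapt a trained model to a new modality by k-fold finetuning.

    Stratified ``finetune_folds``-fold scheme (default 4, i.e. 75/25 splits):
    in each fold a copy of the model continues training on the training
    portion at ``learning_rate * finetune_lr_mult`` for ``finetune_epochs``
    epochs, then predicts the held-out portion, so every instance is tested
    exactly once. ``scaler_policy='refit'`` standardizes with stats from the
    fold's training portion; ``'reuse'`` applies ``base_scaler`` (the source
    modality's stats); ``'none'`` assumes pre-scaled input.
    """
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if scaler_policy not in ("refit", "reuse", "none"):
        raise ParameterError("scaler_policy must be 'refit', 'reuse' or 'none'")
    if scaler_policy == "reuse" and base_scaler is None:
        raise ParameterError("scaler_policy='reuse' requires base_scaler")
    counts = np.bincount(y, minlength=2)
    if counts.min() < config.finetune_folds:
        raise StratificationError(
            f"minority class has {counts.min()} samples; cannot form "
            f"{config.finetune_folds} stratified folds"
        )
    skf = StratifiedKFold(
        n_splits=config.finetune_folds, shuffle=True, random_state=config.seed
    )
    fold_reports = []
    pooled_true = np.empty_like(y)
    pooled_scores = np.empty(len(y), dtype=float)
    for k, (tr_idx, te_idx) in enumerate(skf.split(X, y)):
        if scaler_policy == "refit":
            fold_scaler = ZScoreScaler().fit(X[tr_idx])
        elif scaler_policy == "reuse":
            fold_scaler = base_scaler
        else:
            fold_scaler = None
        Xtr = fold_scaler.transform(X[tr_idx]) if fold_scaler else X[tr_idx]
        Xte = fold_scaler.transform(X[te_idx]) if fold_scaler else X[te_idx]
        clf = model.clone_fitted()
        clf.random_state = config.seed * 1000 + k
        clf._train_rng = np.random.default_rng(clf.random_state + 0x5EED)
        for layer in clf.network_.layers:  # re-seed dropout for this fold
            if hasattr(layer, "rng"):
                layer.rng = clf._train_rng
        if config.finetune_epochs > 0:
            clf.finetune(
                Xtr, y[tr_idx],
                epochs=config.finetune_epochs,
                learning_rate=config.learning_rate * config.finetune_lr_mult,
            )
        scores = clf.predict_proba(Xte)[:, 1]
        pooled_true[te_idx] = y[te_idx]
        pooled_scores[te_idx] = scores
        rep = compute_metrics(
            ConfusionCounts.from_predictions(y[te_idx], (scores >= 0.5).astype(int)),
            scores=scores,
            labels=y[te_idx],
        )
        fold_reports.append(rep)
    mean, sd = _aggregate(fold_reports)
    pooled = compute_metrics(
        ConfusionCounts.from_predictions(pooled_true, (pooled_scores >= 0.5).astype(int)),
        scores=pooled_scores,
        labels=pooled_true,
    )
    return FinetuneResult(fold_reports, mean, sd, pooled)
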