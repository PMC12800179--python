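"""Base classifiers: RBF-SVM on fused features and the image CNN.

Both produce a probability of "manipulated" per input. The SVM pipeline is
z-score standardization (statistics frozen from the training split), an RBF
kernel with (C, gamma) selected by validation AUC over a grid (ties broken
toward smaller C, then smaller gamma), and Platt sigmoid calibration fitted
on validation decision values. The CNN (see :mod:`affetds.nn`) is trained
with Adam and early stopping on validation loss, returning the weights of
the best-validation-loss epoch.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from ._exceptions import NotFittedError, NumericalError, ParameterError, ShapeError
from .nn import Adam, CnnConfig, SmallCnn

DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
#: The string "reciprocal_dim" stands for gamma = 1 / n_features.
DEFAULT_GAMMA_GRID = (1e-4, 1e-3, 1e-2, 1e-1, "reciprocal_dim")


@dataclass
class TrainReport:
    """What a training run chose and how it went."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    hyperparameters: dict = field(default_factory=dict)
    val_auc: float = float("nan")
    stopping_epoch: int = 0
    best_epoch: int = 0
    seed: int = 0


class SvmModel:
    """Standardize -> RBF-SVM -> Platt sigmoid, frozen after fit."""

    def __init__(self) -> None:
        self.mean_: Optional[np.ndarray] = None
        self.std_: Optional[np.ndarray] = None
        self.svc_: Optional[SVC] = None
        self.calibrator_: Optional[LogisticRegression] = None
        self.C_: Optional[float] = None
        self.gamma_: Optional[float] = None

    def _require_fit(self) -> None:
        if self.svc_ is None or self.mean_ is None:
            raise NotFittedError("SVM has not been trained")

    def _standardize(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=np.float64)
        if features.ndim == 1:
            features = features[None]
        if features.shape[1] != self.mean_.shape[0]:
            raise ShapeError(
                f"expected {self.mean_.shape[0]} features, got {features.shape[1]}"
            )
        return (features - self.mean_) / self.std_

    def decision_function(self, features: np.ndarray) -> np.ndarray:
        self._require_fit()
        return self.svc_.decision_function(self._standardize(features))

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Calibrated probability of "manipulated" per row."""
        self._require_fit()
        single = np.asarray(features).ndim == 1
        scores = self.decision_function(features)
        if self.calibrator_ is not None:
            p = self.calibrator_.predict_proba(scores[:, None])[:, 1]
        else:  # fall back to an uncalibrated logistic link
            p = 1.0 / (1.0 + np.exp(-scores))
        return float(p[0]) if single else p


def train_svm(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    val_features: np.ndarray,
    val_labels: np.ndarray,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence = DEFAULT_GAMMA_GRID,
    seed: int = 0,
) -> tuple[SvmModel, TrainReport]:
    """Grid-search an RBF-SVM on fused features by validation AUC.

    Features are z-scored with training-split statistics only (zero-variance
    dimensions get unit scale). Grid ties resolve to the smaller C, then the
    smaller gamma. Probabilities come from a Platt sigmoid fitted on the
    validation decision values.
    """
    X = np.asarray(train_features, dtype=np.float64)
    y = np.asarray(train_labels, dtype=np.int64)
    Xv = np.asarray(val_features, dtype=np.float64)
    yv = np.asarray(val_labels, dtype=np.int64)
    if X.ndim != 2 or len(X) != len(y):
        raise ShapeError("train features/labels mismatch")
    if len(np.unique(y)) < 2:
        raise ParameterError("SVM training needs both classes present")

    model = SvmModel()
    model.mean_ = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    model.std_ = std
    Xs = (X - model.mean_) / model.std_
    Xvs = (Xv - model.mean_) / model.std_

    n_features = X.shape[1]
    gammas = [1.0 / n_features if g == "reciprocal_dim" else float(g) for g in gamma_grid]

    best = None  # (auc, C, gamma, svc)
    for C in sorted(set(float(c) for c in c_grid)):
        for gamma in sorted(set(gammas)):
            svc = SVC(C=C, gamma=gamma, kernel="rbf", random_state=seed)
            svc.fit(Xs, y)
            scores = svc.decision_function(Xvs)
            auc = roc_auc_score(yv, scores) if len(np.unique(yv)) > 1 else 0.5
            if best is None or auc > best[0] + 1e-12:  # strict: ties keep smaller C, gamma
                best = (auc, C, gamma, svc)

    auc, C, gamma, svc = best
    model.C_, model.gamma_, model.svc_ = C, gamma, svc
    val_scores = svc.decision_function(Xvs)
    if len(np.unique(yv)) > 1:
        calibrator = LogisticRegression(C=100.0, random_state=seed)  # near-ML Platt fit
        calibrator.fit(val_scores[:, None], yv)
        if calibrator.coef_[0, 0] > 0:  # keep the link monotone increasing
            model.calibrator_ = calibrator
    report = TrainReport(
        hyperparameters={"C": C, "gamma": gamma, "kernel": "rbf"},
        val_auc=float(auc),
        seed=seed,
    )
    return model, report


def train_cnn(
    train_images: np.ndarray,
    train_labels: np.ndarray,
    val_images: np.ndarray,
    val_labels: np.ndarray,
    config: Optional[CnnConfig] = None,
    seed: Optional[int] = None,
    initial_model: Optional[SmallCnn] = None,
) -> tuple[SmallCnn, TrainReport]:
    """Train the image CNN with Adam and validation-loss early stopping.

    Runs at most ``config.max_epochs`` epochs and stops once validation loss
    has not improved for ``config.patience`` consecutive epochs; the returned
    model carries the weights of the best-validation-loss epoch. Fully
    deterministic for a fixed seed. ``initial_model`` allows continued
    training (e.g. after adversarial augmentation of the training set).
    """
    config = config or CnnConfig()
    if seed is not None:
        config = CnnConfig(**{**asdict(config), "seed": seed})
    X = np.asarray(train_images, dtype=np.float32)
    y = np.asarray(train_labels, dtype=np.int64)
    Xv = np.asarray(val_images, dtype=np.float32)
    yv = np.asarray(val_labels, dtype=np.int64)
    if len(X) == 0 or len(Xv) == 0:
        raise ParameterError("train and validation splits must be nonempty")
    if len(X) != len(y) or len(Xv) != len(yv):
        raise ShapeError("images/labels length mismatch")

    model = initial_model if initial_model is not None else SmallCnn(config)
    optimizer = Adam(lr=config.learning_rate, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)

    report = TrainReport(
        hyperparameters={
            "learning_rate": config.learning_rate,
            "batch_size": config.batch_size,
            "patience": config.patience,
            "max_epochs": config.max_epochs,
            "conv_widths": list(config.conv_widths),
            "fc_width": config.fc_width,
            "head_pool": config.head_pool,
            "head_downsample": config.head_downsample,
            "weight_decay": config.weight_decay,
        },
        seed=config.seed,
    )
    best_state = model.state_copy()
    if initial_model is not None:
        # Continued training must never end worse than it started: the
        # incoming weights are the baseline candidate.
        best_val = model.mean_loss(Xv, yv)
    else:
        best_val = np.inf
    since_best = 0
    # Drop a trailing partial minibatch when at least one full batch exists:
    # keeps workspace buffer shapes constant within an epoch.
    n_train = len(X)
    usable = (n_train // config.batch_size) * config.batch_size if n_train >= config.batch_size else n_train
    for epoch in range(config.max_epochs):
        # Cosine learning-rate decay (floor 10% of base) steadies the
        # late epochs, where a fixed step size caused validation spikes.
        optimizer.lr = config.learning_rate * (
            0.1 + 0.9 * 0.5 * (1 + np.cos(np.pi * epoch / max(1, config.max_epochs - 1)))
        )
        order = rng.permutation(n_train)[:usable]
        epoch_losses = []
        for start in range(0, usable, config.batch_size):
            batch = order[start : start + config.batch_size]
            loss, grads = model.loss_and_param_grads(X[batch], y[batch])
            if not np.isfinite(loss):
                raise NumericalError(f"non-finite training loss at epoch {epoch + 1}")
            optimizer.step(model.params, grads)
            epoch_losses.append(loss)
        val_loss = model.mean_loss(Xv, yv)
        if not np.isfinite(val_loss):
            raise NumericalError(f"non-finite validation loss at epoch {epoch + 1}")
        report.train_loss.append(float(np.mean(epoch_losses)))
        report.val_loss.append(float(val_loss))
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = model.state_copy()
            report.best_epoch = epoch + 1
            since_best = 0
        else:
            since_best += 1
        report.stopping_epoch = epoch + 1
        if since_best >= config.patience:
            break

    model.load_state(best_state)
    if len(np.unique(yv)) > 1:
        _fit_cnn_calibration(model, Xv, yv, seed=config.seed)
        report.val_auc = float(roc_auc_score(yv, model.predict_proba(Xv)))
    return model, report


def _fit_cnn_calibration(model: SmallCnn, val_images: np.ndarray, val_labels: np.ndarray, seed: int = 0) -> None:
    """Platt-recalibrate the CNN's "manipulated" probability on validation.

    Softmax outputs of a small network trained on few images are routinely
    over- or under-shifted relative to the 0.5 decision threshold; the same
    sigmoid recalibration the SVM gets makes the two members' probabilities
    commensurable inside the ensemble. Monotone (slope > 0) fits only; AUC
    is unchanged.
    """
    model.calibration = None
    p = model.predict_proba(val_images)
    z = np.log(np.clip(p, 1e-12, 1 - 1e-12) / np.clip(1 - p, 1e-12, 1))
    calibrator = LogisticRegression(C=100.0, random_state=seed)  # near-ML Platt fit
    calibrator.fit(z[:, None], np.asarray(val_labels, dtype=np.int64))
    slope = float(calibrator.coef_[0, 0])
    if slope > 0:
        model.calibration = (slope, float(calibrator.intercept_[0]))


def predict_proba(model, inputs: np.ndarray) -> np.ndarray:
    """Probability of "manipulated" per input, for either base model."""
    if not hasattr(model, "predict_proba"):
        raise ParameterError(f"{type(model).__name__} cannot produce probabilities")
    p = model.predict_proba(inputs)
    arr = np.atleast_1d(np.asarray(p, dtype=np.float64))
    if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
        raise NumericalError("model produced probabilities outside [0, 1]")
    return p


def save_model(model, path: str | Path, metadata: Optional[dict] = None) -> None:
    """Persist a model with a JSON metadata sidecar (``<path>.json``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(model, SmallCnn):
        np.savez(path.with_suffix(".npz"), **model.params)
        meta = {
            "kind": "cnn",
            "config": asdict(model.config),
            "calibration": list(model.calibration) if model.calibration else None,
        }
    elif isinstance(model, SvmModel):
        joblib.dump(model, path.with_suffix(".joblib"))
        meta = {"kind": "svm", "C": model.C_, "gamma": model.gamma_}
    else:
        raise ParameterError(f"cannot serialize {type(model).__name__}")
    meta.update(metadata or {})
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path):
    """Load a model saved by :func:`save_model`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta["kind"] == "cnn":
        cfg = meta["config"]
        cfg["conv_widths"] = tuple(cfg["conv_widths"])
        model = SmallCnn(CnnConfig(**cfg))
        with np.load(path.with_suffix(".npz")) as data:
            model.load_state({k: data[k] for k in data.files})
        if meta.get("calibration"):
            model.calibration = tuple(meta["calibration"])
        return model
    if meta["kind"] == "svm":
        return joblib.load(path.with_suffix(".joblib"))
    raise ParameterError(f"unknown model kind {meta['kind']!r}")
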