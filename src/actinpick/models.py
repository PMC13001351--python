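"""Denoiser and segmenter estimators, plus training-harness wrappers.

Both models are scikit-learn-style estimators around the numpy U-Net in
:mod:`actinpick._net`:

* :class:`DenoisingAutoencoder` regresses noiseless projections from
  noisy ones (MSE loss; validation metric is the mean per-image Pearson
  cross-correlation between prediction and target).
* :class:`SemanticSegmenter` is a 3-class per-pixel classifier
  (categorical cross-entropy; class-balanced weighting during training,
  unweighted CE reported).

Inputs are standardized per image (zero mean, unit variance) inside the
estimators; the same normalization is applied at inference, so tiles
cut from a micrograph can be segmented directly.  Training is
reproducible from the ``seed`` parameter (pure numpy; any run-to-run
residue from threaded BLAS summation order is far below the metric
tolerances used in the tests).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._net import UNet, cross_entropy_grad, mse_grad, softmax_channels
from .exceptions import DataError, ParameterError

__all__ = [
    "TrainConfig",
    "TrainReport",
    "DenoisingAutoencoder",
    "SemanticSegmenter",
    "train_denoiser",
    "train_segmenter",
    "evaluate",
    "pearson_cc",
    "categorical_ce",
]

_EPS = 1e-8


def standardize(images: np.ndarray) -> np.ndarray:
    """Per-image zero-mean unit-variance normalization."""
    x = np.asarray(images, dtype=np.float32)
    axes = tuple(range(1, x.ndim))
    mu = x.mean(axis=axes, keepdims=True)
    sd = x.std(axis=axes, keepdims=True)
    return (x - mu) / (sd + _EPS)


def pearson_cc(pred: np.ndarray, target: np.ndarray) -> float:
    """Pearson correlation between two images (nan for constant input)."""
    a = np.asarray(pred, dtype=np.float64).ravel()
    b = np.asarray(target, dtype=np.float64).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return float("nan")
    return float((a * b).sum() / denom)


def categorical_ce(proba: np.ndarray, target_onehot: np.ndarray) -> float:
    """Unweighted categorical cross-entropy, mean over pixels."""
    p = np.clip(np.asarray(proba, dtype=np.float64), 1e-12, None)
    t = np.asarray(target_onehot, dtype=np.float64)
    return float(-(t * np.log(p)).sum(axis=-3).mean())


@dataclass
class TrainConfig:
    """Training-harness configuration (full-scale counts in the docs)."""

    n_train_pairs: Optional[int] = None
    val_fraction: float = 0.1
    epochs: int = 6
    batch_size: int = 8
    learning_rate: float = 2e-3
    seed: int = 0
    arch: dict = field(default_factory=lambda: {"depth": 3, "width": 8})

    def validate(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ParameterError("val_fraction must lie in (0, 1)")
        if self.epochs < 0 or self.batch_size < 1:
            raise ParameterError("epochs must be >= 0 and batch_size >= 1")


@dataclass
class TrainReport:
    """Outcome of one training run."""

    final_val_cc: Optional[float] = None
    final_val_ce: Optional[float] = None
    initial_val_cc: Optional[float] = None
    initial_val_ce: Optional[float] = None
    loss_curve: List[float] = field(default_factory=list)
    weights_path: Optional[str] = None


class _NetEstimator(BaseEstimator):
    """Shared fit loop for both networks."""

    _out_channels = 1

    def __init__(
        self,
        depth: int = 3,
        width: int = 8,
        epochs: int = 6,
        batch_size: int = 8,
        learning_rate: float = 2e-3,
        val_fraction: float = 0.1,
        seed: int = 0,
        ema_decay: Optional[float] = None,
    ):
        self.depth = depth
        self.width = width
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.val_fraction = val_fraction
        self.seed = seed
        self.ema_decay = ema_decay

    # subclasses: target prep, loss, validation metric
    def _prepare_targets(self, Y):
        raise NotImplementedError

    def _loss_grad(self, logits, yb):
        raise NotImplementedError

    def _val_metric(self, X_val, Y_val) -> float:
        raise NotImplementedError

    def fit(self, X, Y):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[0] == 0:
            raise DataError("X must be a non-empty (n, H, W) image stack")
        if len(Y) != len(X):
            raise DataError("X and Y must be aligned")
        Xs = standardize(X)
        Ys = self._prepare_targets(np.asarray(Y))

        rng = np.random.default_rng(self.seed)
        n = len(Xs)
        perm = rng.permutation(n)
        n_val = max(1, int(round(self.val_fraction * n))) if n > 1 else 0
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        if len(train_idx) == 0:
            train_idx = perm
        self.net_ = UNet(
            in_channels=1,
            out_channels=self._out_channels,
            depth=self.depth,
            width=self.width,
            seed=int(rng.integers(2**31)),
        )
        self.loss_curve_ = []
        self.initial_val_metric_ = (
            self._val_metric(Xs[val_idx], Ys[val_idx]) if n_val else float("nan")
        )

        # EMA of the weights smooths the SGD trajectory; the averaged
        # weights become the fitted model
        ema = (
            {k: v.copy() for k, v in self.net_.state_dict().items()}
            if self.ema_decay is not None
            else None
        )
        for _ in range(self.epochs):
            order = rng.permutation(train_idx)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, len(order), self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = self.net_.forward(Xs[idx], train=True)
                loss, dlogits = self._loss_grad(logits, Ys[idx])
                self.net_.backward(dlogits)
                self.net_.adam_step(self.learning_rate)
                if ema is not None:
                    for k, v in self.net_.state_dict().items():
                        ema[k] *= self.ema_decay
                        ema[k] += (1.0 - self.ema_decay) * v
                epoch_loss += loss
                n_batches += 1
            self.loss_curve_.append(epoch_loss / max(n_batches, 1))
        if ema is not None and self.epochs > 0:
            self.net_.load_state_dict(ema)
        self.val_metric_ = (
            self._val_metric(Xs[val_idx], Ys[val_idx]) if n_val else float("nan")
        )
        self.val_indices_ = val_idx
        return self

    def _forward_batched(self, Xs: np.ndarray, batch: int = 8) -> np.ndarray:
        outs = [
            self.net_.forward(Xs[i : i + batch]) for i in range(0, len(Xs), batch)
        ]
        return np.concatenate(outs, axis=0)

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        """Save weights (.npz) plus a JSON metadata sidecar."""
        path = Path(path)
        np.savez(path, **self.net_.state_dict())
        meta = {
            "estimator": type(self).__name__,
            "params": self.get_params(),
            "out_channels": self._out_channels,
            "normalization": "per-image zero mean, unit variance",
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path):
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        est = cls(**meta["params"])
        est.net_ = UNet(
            in_channels=1,
            out_channels=cls._out_channels,
            depth=est.depth,
            width=est.width,
        )
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as f:
            est.net_.load_state_dict(dict(f))
        return est


class DenoisingAutoencoder(_NetEstimator):
    """Noisy -> noiseless image regressor (DAE).

    ``fit(X, Y)`` takes noisy and noiseless ``(n, H, W)`` stacks;
    ``predict`` returns denoised images in the standardized intensity
    scale (the Pearson validation metric is scale-invariant).
    """

    _out_channels = 1

    def _prepare_targets(self, Y):
        return standardize(Y)[:, None]

    def _loss_grad(self, logits, yb):
        return mse_grad(logits, yb)

    def _val_metric(self, X_val, Y_val) -> float:
        if len(X_val) == 0:
            return float("nan")
        pred = self._forward_batched(X_val)
        ccs = [pearson_cc(p[0], t[0]) for p, t in zip(pred, Y_val)]
        ccs = [c for c in ccs if np.isfinite(c)]
        return float(np.mean(ccs)) if ccs else float("nan")

    def predict(self, X) -> np.ndarray:
        pred = self._forward_batched(standardize(np.asarray(X, dtype=np.float32)))
        return pred[:, 0]


class SemanticSegmenter(_NetEstimator):
    """3-class per-pixel classifier (background / bare / decorated).

    Trained with class-balanced categorical cross-entropy (inverse
    class frequency, capped) so that the rare decorated class is not
    swamped by background; the reported validation CE is unweighted.
    ``predict_proba`` returns a ``(n, 3, H, W)`` probability simplex.
    """

    _out_channels = 3

    def __init__(
        self,
        depth: int = 3,
        width: int = 8,
        epochs: int = 6,
        batch_size: int = 8,
        learning_rate: float = 2e-3,
        val_fraction: float = 0.1,
        seed: int = 0,
        ema_decay: Optional[float] = None,
        class_weight="balanced",
        max_class_weight: float = 20.0,
    ):
        super().__init__(
            depth, width, epochs, batch_size, learning_rate, val_fraction, seed, ema_decay
        )
        self.class_weight = class_weight
        self.max_class_weight = max_class_weight

    def _prepare_targets(self, Y):
        Y = np.asarray(Y, dtype=np.float32)
        if Y.ndim != 4 or Y.shape[1] != self._out_channels:
            raise DataError("targets must have shape (n, 3, H, W)")
        if isinstance(self.class_weight, str) and self.class_weight == "balanced":
            freq = Y.mean(axis=(0, 2, 3))
            w = 1.0 / np.clip(freq, 1e-6, None)
            w = np.minimum(w / w.min(), self.max_class_weight)
            self.class_weights_ = w.astype(np.float32)
        elif self.class_weight is None:
            self.class_weights_ = None
        else:
            self.class_weights_ = np.asarray(self.class_weight, dtype=np.float32)
        return Y

    def _loss_grad(self, logits, yb):
        return cross_entropy_grad(logits, yb, self.class_weights_)

    def _val_metric(self, X_val, Y_val) -> float:
        if len(X_val) == 0:
            return float("nan")
        proba = softmax_channels(self._forward_batched(X_val))
        return categorical_ce(proba, Y_val)

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        single = X.ndim == 2
        if single:
            X = X[None]
        proba = softmax_channels(self._forward_batched(standardize(X)))
        return proba[0] if single else proba

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=-3)


# ---------------------------------------------------------------------------
# training-harness wrappers

def _subset(dataset, config: TrainConfig):
    n = len(dataset)
    if config.n_train_pairs is not None and config.n_train_pairs < n:
        return slice(0, config.n_train_pairs)
    return slice(0, n)


def train_denoiser(dataset, config: TrainConfig = TrainConfig(), weights_path=None) -> TrainReport:
    """Train the DAE on a simulator dataset; report validation cc."""
    config.validate()
    if len(dataset) == 0:
        raise DataError("dataset is empty")
    sel = _subset(dataset, config)
    est = DenoisingAutoencoder(
        depth=config.arch.get("depth", 3),
        width=config.arch.get("width", 8),
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        val_fraction=config.val_fraction,
        seed=config.seed,
    )
    est.fit(dataset.noisy[sel], dataset.noiseless[sel])
    report = TrainReport(
        final_val_cc=est.val_metric_,
        initial_val_cc=est.initial_val_metric_,
        loss_curve=list(est.loss_curve_),
    )
    if weights_path is not None:
        est.save(weights_path)
        report.weights_path = str(weights_path)
    report.estimator = est  # type: ignore[attr-defined]
    return report


def train_segmenter(dataset, config: TrainConfig = TrainConfig(), weights_path=None) -> TrainReport:
    """Train the 3-class segmenter; report unweighted validation CE."""
    config.validate()
    if len(dataset) == 0:
        raise DataError("dataset is empty")
    sel = _subset(dataset, config)
    est = SemanticSegmenter(
        depth=config.arch.get("depth", 3),
        width=config.arch.get("width", 8),
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        val_fraction=config.val_fraction,
        seed=config.seed,
    )
    est.fit(dataset.noisy[sel], dataset.targets[sel])
    report = TrainReport(
        final_val_ce=est.val_metric_,
        initial_val_ce=est.initial_val_metric_,
        loss_curve=list(est.loss_curve_),
    )
    if weights_path is not None:
        est.save(weights_path)
        report.weights_path = str(weights_path)
    report.estimator = est  # type: ignore[attr-defined]
    return report


def evaluate(model, dataset) -> pd.DataFrame:
    """Per-sample metrics table for a fitted model on a dataset.

    DAE rows carry ``cc``; segmenter rows carry ``ce`` plus per-class
    pixel accuracy.
    """
    rows = []
    if isinstance(model, DenoisingAutoencoder):
        pred = model.predict(dataset.noisy)
        for i in range(len(dataset)):
            rows.append({"sample": i, "cc": pearson_cc(pred[i], dataset.noiseless[i])})
    elif isinstance(model, SemanticSegmenter):
        proba = model.predict_proba(dataset.noisy)
        labels = np.argmax(proba, axis=1)
        truth = np.argmax(dataset.targets, axis=1)
        for i in range(len(dataset)):
            row = {"sample": i, "ce": categorical_ce(proba[i], dataset.targets[i])}
            for c, name in enumerate(("background", "bare", "decorated")):
                mask = truth[i] == c
                row[f"acc_{name}"] = (
                    float((labels[i][mask] == c).mean()) if mask.any() else float("nan")
                )
            rows.append(row)
    else:
        raise DataError(f"cannot evaluate model of type {type(model).__name__}")
    df = pd.DataFrame(rows)
    df.attrs["mean"] = {
        k: float(np.nanmean(df[k])) for k in df.columns if k != "sample"
    }
    return df
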