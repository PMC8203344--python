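"""Scikit-learn-style classifiers for spectrogram images.

Three estimators share one training loop:

* :class:`CNNLSTMClassifier` — the 14-layer hybrid: sequence folding,
  two conv/batch-norm/max-pool blocks, sequence unfolding, flatten, a
  200-unit LSTM, a 2-way fully connected layer and softmax;
* :class:`CNNClassifier` — the convolutional stack with no recurrence;
* :class:`LSTMClassifier` — flatten → LSTM (ReLU) → fully connected,
  with no convolution.

All accept ``X`` of shape ``(n, H, W, 3)`` with values in [0, 1] and a
binary string label array.  Training minimizes softmax cross-entropy
with Adam; per-epoch mean squared error between the softmax output and
the one-hot labels is logged additionally, along with validation MSE and
accuracy on a stratified holdout.  With a fixed ``random_state`` runs
are bit-reproducible.
"""
from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from . import _layers as L
from .architecture import ModelArchitecture, cnn_lstm_architecture, same_padding


def _onehot(y_idx: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((y_idx.size, k))
    out[np.arange(y_idx.size), y_idx] = 1.0
    return out


class _ImageNNClassifier(ClassifierMixin, BaseEstimator):
    """Shared fit/predict machinery; subclasses define the layer stack."""

    def __init__(
        self,
        image_size: int = 124,
        hidden_size: int = 200,
        epochs: int = 20,
        batch_size: int = 64,
        learning_rate: float = 1e-3,
        validation_fraction: float = 0.3,
        early_stopping: bool = False,
        random_state: int | None = None,
    ):
        self.image_size = image_size
        self.hidden_size = hidden_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.early_stopping = early_stopping
        self.random_state = random_state

    # subclasses override ------------------------------------------------
    def _build_layers(self, n_classes: int, rng: np.random.Generator) -> list[L.Layer]:
        raise NotImplementedError

    # ---------------------------------------------------------------
    def _validate_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        expected = (self.image_size, self.image_size, 3)
        if X.ndim != 4 or X.shape[1:] != expected:
            raise ValueError(f"X must have shape (n, {expected[0]}, {expected[1]}, 3), got {X.shape}")
        return X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_ImageNNClassifier":
        X = self._validate_X(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(f"need exactly 2 classes, got {self.classes_.tolist()}")
        y_idx = np.searchsorted(self.classes_, y)

        rng = np.random.default_rng(self.random_state)
        if self.validation_fraction > 0:
            split_seed = int(rng.integers(2**31))
            X_tr, X_val, yi_tr, yi_val = train_test_split(
                X, y_idx, test_size=self.validation_fraction,
                stratify=y_idx, random_state=split_seed,
            )
        else:
            X_tr, yi_tr = X, y_idx
            X_val = yi_val = None
        if np.bincount(yi_tr, minlength=2).min() < 2:
            raise ValueError("need at least 2 training samples per class")

        self._layers = self._build_layers(2, rng)
        opt = L.Adam(lr=self.learning_rate)
        history = []
        for epoch in range(1, self.epochs + 1):
            perm = rng.permutation(X_tr.shape[0])
            losses = []
            for start in range(0, perm.size, self.batch_size):
                idx = perm[start : start + self.batch_size]
                probs = self._forward(X_tr[idx], train=True)
                onehot = _onehot(yi_tr[idx], 2)
                losses.append(L.cross_entropy(probs, onehot))
                self._backward((probs - onehot) / idx.size)
                params = [p for layer in self._layers for p in layer.params()]
                opt.step(params)
            row = dict(epoch=epoch, loss=float(np.mean(losses)))
            p_tr = self._forward(X_tr, train=False)
            row["mse"] = float(np.mean((p_tr - _onehot(yi_tr, 2)) ** 2))
            if X_val is not None:
                p_val = self._forward(X_val, train=False)
                row["val_mse"] = float(np.mean((p_val - _onehot(yi_val, 2)) ** 2))
                row["val_accuracy"] = float(np.mean(p_val.argmax(axis=1) == yi_val))
            history.append(row)
        # recalibrate batch-norm inference statistics under the final
        # weights with one pass over the full training set
        for layer in self._layers:
            if isinstance(layer, L.BatchNorm):
                layer.reset_running()
        self._forward(X_tr, train=True)
        self.history_ = pd.DataFrame(history)
        if X_val is not None:
            self.best_epoch_ = int(self.history_["val_mse"].idxmin()) + 1
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def _forward(self, X: np.ndarray, train: bool) -> np.ndarray:
        out = X
        for layer in self._layers:
            out = layer.forward(out, train)
        return L.softmax(out)

    def _backward(self, dlogits: np.ndarray) -> None:
        # softmax+CE gradient enters at the logits
        d = dlogits
        for layer in reversed(self._layers):
            d = layer.backward(d)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "history_")
        X = self._validate_X(X)
        return self._forward(X, train=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        # argmax ties resolve to the first class in sorted order
        # ("under_stress" precedes "without_stress")
        probs = self.predict_proba(X)
        return self.classes_[probs.argmax(axis=1)]

    # persistence -----------------------------------------------------
    def save(self, path: str) -> None:
        """Serialize weights + config to one ``.npz`` with an architecture fingerprint."""
        check_is_fitted(self, "history_")
        arrays = {}
        for li, layer in enumerate(self._layers):
            for pi, (p, _) in enumerate(layer.params()):
                arrays[f"layer{li}_param{pi}"] = p
            if isinstance(layer, L.BatchNorm):
                arrays[f"layer{li}_running_mean"] = layer.running_mean
                arrays[f"layer{li}_running_var"] = layer.running_var
        meta = dict(
            estimator=type(self).__name__,
            params=self.get_params(),
            classes=self.classes_.tolist(),
            fingerprint=[type(l).__name__ for l in self._layers],
        )
        np.savez(path, _meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "_ImageNNClassifier":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["_meta"]))
            est_cls = {c.__name__: c for c in (CNNLSTMClassifier, CNNClassifier, LSTMClassifier)}[
                meta["estimator"]
            ]
            est = est_cls(**meta["params"])
            est.classes_ = np.array(meta["classes"])
            est._layers = est._build_layers(2, np.random.default_rng(0))
            fingerprint = [type(l).__name__ for l in est._layers]
            if fingerprint != meta["fingerprint"]:
                raise ValueError(
                    f"architecture fingerprint mismatch: file has {meta['fingerprint']}, "
                    f"rebuilt {fingerprint}"
                )
            for li, layer in enumerate(est._layers):
                for pi, (p, _) in enumerate(layer.params()):
                    p[...] = data[f"layer{li}_param{pi}"]
                if isinstance(layer, L.BatchNorm):
                    layer.running_mean = data[f"layer{li}_running_mean"]
                    layer.running_var = data[f"layer{li}_running_var"]
        est.history_ = pd.DataFrame({"epoch": []})
        return est


class CNNLSTMClassifier(_ImageNNClassifier):
    """The hybrid convolutional–recurrent classifier.

    ``architecture()`` returns the 14-row table with the computed shape
    trace (flatten width 31·31·12 = 11532 and stacked LSTM gate blocks
    800 × 11532 / 800 × 200 at the full 124-pixel default).
    """

    conv1 = (5, 6)  # filter size, filter count
    conv2 = (3, 12)

    def architecture(self) -> ModelArchitecture:
        return cnn_lstm_architecture(
            image_size=self.image_size,
            conv1=self.conv1,
            conv2=self.conv2,
            hidden_size=self.hidden_size,
        )

    def _build_layers(self, n_classes, rng):
        arch = self.architecture()  # validates shapes; raises naming the layer
        flat_width = next(l.activation for l in arch.layers if l.name == "flatten")
        (f1, k1), (f2, k2) = self.conv1, self.conv2
        return [
            L.SequenceFolding(),
            L.Conv2D(f1, f1, 3, k1, same_padding(f1), rng),
            L.BatchNorm(k1),
            L.ReLU(),
            L.MaxPool(2),
            L.Conv2D(f2, f2, k1, k2, same_padding(f2), rng),
            L.BatchNorm(k2),
            L.ReLU(),
            L.MaxPool(2),
            L.SequenceUnfolding(),
            L.Flatten(),
            L.LSTMLayer(flat_width, self.hidden_size, rng),
            L.Dense(self.hidden_size, n_classes, rng),
        ]


class CNNClassifier(_ImageNNClassifier):
    """Convolution-only baseline: conv/BN/pool stack → fully connected → softmax."""

    conv1 = (5, 6)
    conv2 = (3, 12)

    def _build_layers(self, n_classes, rng):
        (f1, k1), (f2, k2) = self.conv1, self.conv2
        flat_width = (self.image_size // 4) ** 2 * k2
        return [
            L.Conv2D(f1, f1, 3, k1, same_padding(f1), rng),
            L.BatchNorm(k1),
            L.ReLU(),
            L.MaxPool(2),
            L.Conv2D(f2, f2, k1, k2, same_padding(f2), rng),
            L.BatchNorm(k2),
            L.ReLU(),
            L.MaxPool(2),
            L.Flatten(),
            L.Dense(flat_width, n_classes, rng),
        ]


class LSTMClassifier(_ImageNNClassifier):
    """Recurrence-only baseline: flatten → LSTM with ReLU → fully connected."""

    def _build_layers(self, n_classes, rng):
        flat_width = self.image_size**2 * 3
        return [
            L.Flatten(),
            L.LSTMLayer(flat_width, self.hidden_size, rng),
            L.ReLU(),
            L.Dense(self.hidden_size, n_classes, rng),
        ]


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def build_cnn_lstm(**params) -> tuple[ModelArchitecture, CNNLSTMClassifier]:
    """Architecture table plus an unfitted estimator."""
    est = CNNLSTMClassifier(**params)
    return est.architecture(), est


def build_cnn_baseline(**params) -> CNNClassifier:
    return CNNClassifier(**params)


def build_lstm_baseline(**params) -> LSTMClassifier:
    return LSTMClassifier(**params)


def train(model: _ImageNNClassifier, X: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Fit in place and return the per-epoch history frame."""
    model.fit(X, y)
    return model.history_


def predict_proba(model: _ImageNNClassifier, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)


def predict(model: _ImageNNClassifier, X: np.ndarray) -> np.ndarray:
    return model.predict(X)
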