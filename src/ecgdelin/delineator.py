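"""The CNN-Bi-LSTM waveform delineator.

The model labels every sample of a fixed 370-sample beat window with one of
five classes (P, QRS, T, no-wave, padding).  Four same-length convolutional
layers (8, 16, 32, 64 filters, kernel 3, stride 1, ReLU, no pooling) extract
per-timestep features; a bidirectional LSTM (512 units per direction in the
canonical configuration, output width 1024) integrates context in both
directions; a per-timestep affine map with softmax produces the class
probabilities.  Training minimizes categorical cross-entropy with Adam.

For a canonical (370, 1) input the per-layer output widths are
8 -> 16 -> 32 -> 64 -> 1024 -> 5 with the window length preserved throughout.

:class:`CnnBiLstmDelineator` wraps the model as a scikit-learn style
estimator (``fit``/``predict``/``predict_proba`` on stacked window arrays);
the module-level :func:`build_model`, :func:`train` and :func:`predict`
functions are thin procedural equivalents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import ValidationError
from .nn import Adam, BiLSTM, Conv1D, TimeDistributedDense, softmax, softmax_cross_entropy
from .records import CLASS_NAMES, N_CLASSES, LabelMask, WAVE_CLASSES
from .segment import WINDOW_LEN, BeatWindow

CANONICAL_CONV_FILTERS = (8, 16, 32, 64)
CANONICAL_UNITS = 512

#: predicted wave runs shorter than this are discarded as spurious
MIN_WAVE_DURATION_S = 0.02


@dataclass(frozen=True)
class ConvLayerSpec:
    filters: int
    kernel: int = 3
    stride: int = 1
    activation: str = "relu"
    padding: str = "same"


@dataclass(frozen=True)
class RecurrentLayerSpec:
    units_per_direction: int = CANONICAL_UNITS
    directions: int = 2

    @property
    def output_width(self) -> int:
        return self.units_per_direction * self.directions


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; canonical defaults are Adam at 1e-4 for 300
    epochs with categorical cross-entropy (reduce epochs for smoke runs)."""

    learning_rate: float = 1e-4
    epochs: int = 300
    batch_size: int = 32
    seed: int = 0
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if not 0 <= self.validation_fraction < 1:
            raise ValidationError("validation_fraction must be in [0, 1)")


class DelineatorModel:
    """Layer-structured network with explicit forward/backward passes."""

    CHECKPOINT_VERSION = 1

    def __init__(self, conv_filters, units_per_direction: int,
                 n_classes: int = N_CLASSES, *, kernel: int = 3,
                 bidirectional: bool = True, seed: int = 0):
        if n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        conv_filters = tuple(int(f) for f in conv_filters)
        if any(f < 1 for f in conv_filters):
            raise ValidationError("conv filter counts must be positive")
        if units_per_direction < 1:
            raise ValidationError("units_per_direction must be positive")
        self.conv_filters = conv_filters
        self.units_per_direction = int(units_per_direction)
        self.n_classes = int(n_classes)
        self.kernel = int(kernel)
        self.bidirectional = bool(bidirectional)
        self.seed = int(seed)
        self.fitted_fs = 250.0
        self.trained = False

        rng = np.random.default_rng(seed)
        self.layers = []
        width = 1
        for f in conv_filters:
            self.layers.append(Conv1D(width, f, kernel, rng=rng))
            width = f
        self.layers.append(
            BiLSTM(width, units_per_direction, rng=rng, bidirectional=bidirectional)
        )
        width = self.layers[-1].out_channels
        self.layers.append(TimeDistributedDense(width, n_classes, rng=rng))

    # -- structure ---------------------------------------------------------

    @property
    def conv_specs(self) -> list[ConvLayerSpec]:
        return [ConvLayerSpec(filters=f, kernel=self.kernel) for f in self.conv_filters]

    @property
    def recurrent_spec(self) -> RecurrentLayerSpec:
        return RecurrentLayerSpec(
            units_per_direction=self.units_per_direction,
            directions=2 if self.bidirectional else 1,
        )

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    # -- computation -------------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits for a batch; x is (B, L) or (B, L, 1)."""
        if x.ndim == 2:
            x = x[:, :, None]
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def forward_hidden(self, x: np.ndarray) -> list[np.ndarray]:
        """Per-layer outputs (post-activation), ending with the class
        probabilities; used to verify the architecture's printed shapes."""
        if x.ndim == 2:
            x = x[:, :, None]
        outputs = []
        for layer in self.layers:
            x = layer.forward(x)
            outputs.append(x)
        outputs[-1] = softmax(outputs[-1])
        return outputs

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        meta = dict(
            version=self.CHECKPOINT_VERSION,
            conv_filters=list(self.conv_filters),
            units_per_direction=self.units_per_direction,
            n_classes=self.n_classes,
            kernel=self.kernel,
            bidirectional=self.bidirectional,
            seed=self.seed,
            trained=self.trained,
        )
        arrays = {f"p{i}": p for i, p in enumerate(self.params())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "DelineatorModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            if meta["version"] != cls.CHECKPOINT_VERSION:
                raise ValidationError(f"unsupported checkpoint version {meta['version']}")
            model = cls(meta["conv_filters"], meta["units_per_direction"],
                        meta["n_classes"], kernel=meta["kernel"],
                        bidirectional=meta["bidirectional"], seed=meta["seed"])
            for i, p in enumerate(model.params()):
                p[...] = data[f"p{i}"]
        model.trained = meta["trained"]
        return model


def build_model(conv_filters=CANONICAL_CONV_FILTERS,
                units_per_direction: int = CANONICAL_UNITS,
                n_classes: int = N_CLASSES, *, bidirectional: bool = True,
                seed: int = 0) -> DelineatorModel:
    """Build an untrained delineator.

    An empty ``conv_filters`` list yields the recurrent-only baselines
    (Bi-LSTM or, with ``bidirectional=False``, unidirectional LSTM).
    """
    return DelineatorModel(conv_filters, units_per_direction, n_classes,
                           bidirectional=bidirectional, seed=seed)


def _as_xy(windows) -> tuple[np.ndarray, np.ndarray]:
    if len(windows) and isinstance(windows[0], BeatWindow):
        X = np.stack([w.samples for w in windows])
        Y = np.stack([w.onehot for w in windows])
    else:
        raise ValidationError("expected a list of BeatWindow")
    return X, Y


def train(model: DelineatorModel, windows, config: TrainConfig | None = None):
    """Train in place; returns ``(model, history)``.

    ``history`` maps "loss"/"accuracy" (and, when a validation split is
    taken, "val_loss"/"val_accuracy") to per-epoch lists.  PAD positions stay
    in the 5-class cross-entropy target; they are only excluded later, when
    waveform metrics are reported.
    """
    config = config or TrainConfig()
    if len(windows) < 2:
        raise ValidationError("need at least 2 windows to train")
    X, Y = _as_xy(windows)
    return _train_arrays(model, X, Y, config)


def _train_arrays(model: DelineatorModel, X: np.ndarray, Y: np.ndarray,
                  config: TrainConfig):
    if X.shape[1] != Y.shape[1] or Y.shape[2] != model.n_classes:
        raise ValidationError(
            f"window shapes {X.shape}/{Y.shape} do not match the model"
        )
    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    n_val = int(round(config.validation_fraction * n))
    order = rng.permutation(n)
    val_idx, train_idx = order[:n_val], order[n_val:]
    if train_idx.size < 1:
        raise ValidationError("validation split leaves no training windows")
    Xt, Yt = X[train_idx], Y[train_idx]
    opt = Adam(model.params(), lr=config.learning_rate)
    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    if n_val:
        history["val_loss"] = []
        history["val_accuracy"] = []
    bs = config.batch_size
    for _epoch in range(config.epochs):
        perm = rng.permutation(Xt.shape[0])
        losses, correct, total = [], 0, 0
        for b0 in range(0, Xt.shape[0], bs):
            idx = perm[b0:b0 + bs]
            logits = model.forward(Xt[idx])
            loss, dlogits = softmax_cross_entropy(logits, Yt[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {_epoch}; reduce the "
                    f"learning rate (currently {config.learning_rate})"
                )
            model.backward(dlogits)
            opt.step(model.grads())
            losses.append(loss)
            correct += int((logits.argmax(-1) == Yt[idx].argmax(-1)).sum())
            total += idx.size * X.shape[1]
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(correct / total)
        if n_val:
            vlogits = model.forward(X[val_idx])
            vloss, _ = softmax_cross_entropy(vlogits, Y[val_idx])
            history["val_loss"].append(vloss)
            history["val_accuracy"].append(
                float((vlogits.argmax(-1) == Y[val_idx].argmax(-1)).mean())
            )
    model.trained = True
    return model, history


def predict(model: DelineatorModel, window, *, allow_untrained: bool = False):
    """Class probabilities and argmax mask for one window.

    Rows of the probability matrix each sum to 1; ties resolve to the lowest
    class index (numpy argmax convention).
    """
    if not model.trained and not allow_untrained:
        raise ValidationError("model is untrained; pass allow_untrained=True to force")
    x = window.samples if isinstance(window, BeatWindow) else np.asarray(window, float)
    if x.ndim != 1:
        raise ValidationError("predict expects a single window")
    probs = softmax(model.forward(x[None, :]))[0]
    return probs, LabelMask(probs.argmax(axis=1))


@dataclass(frozen=True)
class Fiducial:
    wave: str          # "P", "QRS" or "T"
    onset: int         # first sample of the run
    offset: int        # one past the last sample
    duration_s: float
    peak_index: int    # argmax |amplitude| within the run (R-peak for QRS)


def fiducials_from_mask(mask: LabelMask, samples, fs: float) -> list[Fiducial]:
    """Wave onsets/offsets/durations/peaks from a (predicted) mask.

    One fiducial per maximal P/QRS/T run; runs shorter than
    ``MIN_WAVE_DURATION_S`` are discarded as spurious.
    """
    if fs <= 0:
        raise ValidationError("fs must be positive")
    samples = np.asarray(samples, float)
    out = []
    min_len = MIN_WAVE_DURATION_S * fs
    for cls, start, end in mask.runs():
        if cls not in WAVE_CLASSES or (end - start) < min_len:
            continue
        peak = start + int(np.argmax(np.abs(samples[start:end])))
        out.append(Fiducial(CLASS_NAMES[cls], start, end, (end - start) / fs, peak))
    return out


class CnnBiLstmDelineator(ClassifierMixin, BaseEstimator):
    """Scikit-learn style estimator for per-sample ECG waveform labeling.

    ``X`` is an (n_windows, window_len) array of voltages (mV) and ``y`` an
    integer class mask of the same shape.  ``predict`` returns per-sample
    class labels, ``predict_proba`` the (n, L, 5) probability tensor, and
    ``score`` the per-node accuracy.

    Parameters mirror the canonical architecture and training recipe: four
    convolutional layers of 8/16/32/64 filters, 512 LSTM units per direction,
    Adam at learning rate 1e-4, categorical cross-entropy, 300 epochs.
    Reduce ``units_per_direction`` and ``epochs`` for CPU-scale runs.
    """

    def __init__(self, conv_filters=CANONICAL_CONV_FILTERS,
                 units_per_direction: int = CANONICAL_UNITS,
                 n_classes: int = N_CLASSES, bidirectional: bool = True,
                 learning_rate: float = 1e-4, epochs: int = 300,
                 batch_size: int = 32, validation_fraction: float = 0.1,
                 random_state: int = 0):
        self.conv_filters = conv_filters
        self.units_per_direction = units_per_direction
        self.n_classes = n_classes
        self.bidirectional = bidirectional
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        if X.ndim == 3 and X.shape[2] == 1:
            X = X[:, :, 0]
        if X.ndim != 2 or y.shape != X.shape:
            raise ValidationError(
                f"X must be (n, window_len) with y the same shape; "
                f"got {X.shape} and {y.shape}"
            )
        if np.any((y < 0) | (y >= self.n_classes)):
            raise ValidationError("y contains labels outside the class range")
        Y = np.eye(self.n_classes)[y]
        self.model_ = DelineatorModel(
            self.conv_filters, self.units_per_direction, self.n_classes,
            bidirectional=self.bidirectional, seed=self.random_state,
        )
        config = TrainConfig(
            learning_rate=self.learning_rate, epochs=self.epochs,
            batch_size=self.batch_size, seed=self.random_state,
            validation_fraction=self.validation_fraction,
        )
        _, self.history_ = _train_arrays(self.model_, X, Y, config)
        self.classes_ = np.arange(self.n_classes)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[None, :]
        if not hasattr(self, "model_"):
            raise ValidationError("estimator is not fitted")
        # batch the forward pass to bound memory on large window sets
        chunks = [softmax(self.model_.forward(X[i:i + 64]))
                  for i in range(0, X.shape[0], 64)]
        return np.concatenate(chunks, axis=0)

    def predict(self, X):
        return self.predict_proba(X).argmax(axis=-1)

    def score(self, X, y):
        """Per-node accuracy over all windows and timesteps."""
        return float((self.predict(X) == np.asarray(y, int)).mean())
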