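"""5-class 1D CNN for per-pixel Raman spectrum classification.

The classifier consumes *raw* spectra -- no baseline correction, smoothing
or normalisation -- as (2, 512) arrays whose first row holds intensities and
second row the wavenumber values, and predicts one of five classes:
0 stroma/empty, 1 AVAC, 2 IPMC, 3 cPDAC, 4 benign.  The network has 18
one-dimensional convolution layers (six blocks of three, ReLU, max-pool 2
after each block) followed by 4 fully connected layers of 512/256/128/5
units with a terminal softmax, glorot-uniform initialisation, Adam, and
categorical cross-entropy.

The whole stack -- convolutions, pooling, dense layers, Adam -- is
implemented here on numpy arrays (float32, im2col + GEMM convolutions), so
training is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CLASS_NAMES, HyperMap, LabeledSpectraSet, SpectralAxis
from .prep import resample as resample_spectrum
from .core import Spectrum

__all__ = [
    "CNNConfig",
    "Dataset",
    "PredictionMap",
    "prepare_dataset",
    "spectra_to_tensors",
    "build_model",
    "train",
    "evaluate",
    "save_model",
    "load_model",
    "predict",
    "predict_map",
    "extract_dense_features",
    "Model1D",
]

N_CLASSES = len(CLASS_NAMES)


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training regime of the spectral CNN.

    ``conv_channels`` gives the filter count of each of the six
    three-convolution blocks; kernel 7, stride 1, 'same' padding, ReLU, and
    a max-pool of 2 after every block.  Defaults follow the published
    training regime (Adam, categorical cross-entropy, batch 105, 70/30
    split); ``epochs`` defaults to the scaled-down 30-epoch run used
    throughout this package.
    """

    conv_channels: tuple[int, ...] = (8, 8, 16, 16, 32, 32)
    convs_per_block: int = 3
    kernel_size: int = 7
    dense_sizes: tuple[int, ...] = (512, 256, 128, N_CLASSES)
    n_points: int = 512
    epochs: int = 30
    batch_size: int = 105
    train_fraction: float = 0.7
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0
    #: per-channel batch normalization after every convolution (before ReLU)
    batch_norm: bool = True
    #: fixed constant applied to the wavenumber input row so both rows are
    #: O(1); part of the model, not a data-dependent preprocessing step.
    wavenumber_scale: float = 1e-3

    def __post_init__(self) -> None:
        if self.dense_sizes[-1] != N_CLASSES:
            raise ValueError(f"last dense size must be {N_CLASSES}")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_points % 2 ** len(self.conv_channels) != 0:
            raise ValueError("n_points must be divisible by 2^n_blocks (max-pooling)")

    @property
    def n_conv_layers(self) -> int:
        return len(self.conv_channels) * self.convs_per_block

    @property
    def n_dense_layers(self) -> int:
        return len(self.dense_sizes)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Train/test tensors, one-hot labels, and the shared 512-point axis."""

    X_train: np.ndarray  # (n_train, 2, n_points) float32
    y_train: np.ndarray  # (n_train, 5) one-hot float32
    X_test: np.ndarray
    y_test: np.ndarray
    labels_train: np.ndarray
    labels_test: np.ndarray
    axis: SpectralAxis
    seed: int


def spectra_to_tensors(
    spectra: np.ndarray, axis: SpectralAxis, n_points: int = 512
) -> tuple[np.ndarray, SpectralAxis]:
    """Resample spectra to ``n_points`` and stack with the wavenumber row.

    Returns ``(tensors, axis512)`` with tensors of shape (n, 2, n_points):
    row 0 intensities, row 1 the (shared) wavenumber values.
    """
    spectra = np.asarray(spectra, dtype=float)
    wn = axis.wavenumbers
    if len(axis) == n_points:
        new_axis = axis
        resampled = spectra
    else:
        first = resample_spectrum(Spectrum(axis, spectra[0]), n_points)
        new_axis = first.axis
        ascending = wn[0] < wn[-1]
        src_x = wn if ascending else wn[::-1]
        tgt = new_axis.wavenumbers if ascending else new_axis.wavenumbers[::-1]
        cols = np.empty((spectra.shape[0], n_points))
        for i, row in enumerate(spectra):
            cols[i] = np.interp(tgt, src_x, row if ascending else row[::-1])
        resampled = cols if ascending else cols[:, ::-1]
    n = resampled.shape[0]
    tensors = np.empty((n, 2, n_points), dtype=np.float32)
    tensors[:, 0, :] = resampled
    tensors[:, 1, :] = new_axis.wavenumbers
    return tensors, new_axis


def _one_hot(labels: np.ndarray) -> np.ndarray:
    out = np.zeros((labels.size, N_CLASSES), dtype=np.float32)
    out[np.arange(labels.size), labels] = 1.0
    return out


def prepare_dataset(spectra: LabeledSpectraSet, config: CNNConfig | None = None) -> Dataset:
    """Shuffle, tensorise, one-hot encode and split a labeled spectra set.

    The split is stratified 70/30 (by ``config.train_fraction``): within each
    class the seeded shuffle order decides membership, so per-class
    proportions are preserved to within one sample.  Classes entirely absent
    from the input produce a warning; an empty input is an error.
    """
    cfg = config or CNNConfig()
    if len(spectra) == 0:
        raise ValueError("empty spectra set")
    import warnings

    present = set(int(c) for c in np.unique(spectra.labels))
    missing = [CLASS_NAMES[c] for c in range(N_CLASSES) if c not in present]
    if missing:
        warnings.warn(f"classes absent from dataset: {missing}")

    X, axis512 = spectra_to_tensors(spectra.spectra, spectra.axis, cfg.n_points)
    y = np.asarray(spectra.labels, dtype=int)
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(y))
    X, y = X[order], y[order]

    train_idx, test_idx = [], []
    for c in sorted(present):
        idx = np.flatnonzero(y == c)
        n_train = int(round(cfg.train_fraction * idx.size))
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    train_idx = rng.permutation(np.concatenate(train_idx))
    test_idx = rng.permutation(np.concatenate(test_idx))
    return Dataset(
        X_train=X[train_idx],
        y_train=_one_hot(y[train_idx]),
        X_test=X[test_idx],
        y_test=_one_hot(y[test_idx]),
        labels_train=y[train_idx],
        labels_test=y[test_idx],
        axis=axis512,
        seed=cfg.seed,
    )


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Layer:
    def params(self) -> list[dict]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class _InputScale(_Layer):
    """Fixed per-row scaling of the (2, L) input; not a learned layer."""

    def __init__(self, scales: np.ndarray) -> None:
        self.scales = scales.astype(np.float32).reshape(1, -1, 1)

    def forward(self, x, training):
        return x * self.scales

    def backward(self, grad):
        return grad * self.scales


class _Conv1D(_Layer):
    """'same'-padded 1-D convolution via im2col + GEMM."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator) -> None:
        limit = np.sqrt(6.0 / (cin * k + cout * k))  # glorot uniform
        self.W = rng.uniform(-limit, limit, (cin * k, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None

    def params(self):
        return [
            {"value": self.W, "grad": self.dW},
            {"value": self.b, "grad": self.db},
        ]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, L = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        # (n, c, L, k) -> (n*L, c*k)
        return np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(n * L, c * self.k)

    def forward(self, x, training):
        n, c, L = x.shape
        cols = self._im2col(x)
        y = cols @ self.W + self.b
        if training:
            self._cols = cols
            self._shape = (n, c, L)
        return y.reshape(n, L, self.cout).transpose(0, 2, 1)

    def backward(self, grad):
        n, c, L = self._shape
        g = np.ascontiguousarray(grad.transpose(0, 2, 1)).reshape(n * L, self.cout)
        self.db[...] = g.sum(axis=0)
        self.dW[...] = self._cols.T @ g
        dcols = (g @ self.W.T).reshape(n, L, c, self.k)
        dxp = np.zeros((n, c, L + 2 * self.pad), dtype=np.float32)
        for j in range(self.k):
            dxp[:, :, j : j + L] += dcols[:, :, :, j].transpose(0, 2, 1)
        self._cols = None
        return dxp[:, :, self.pad : self.pad + L]


class _BatchNorm1D(_Layer):
    """Per-channel batch normalization over (N, C, L) activations.

    Keeps the 18-layer stack trainable: without centering, the nonnegative
    ReLU activations of a plain net this deep collapse onto a single mean
    direction and learning stalls.  Running statistics (momentum 0.9) are
    used at inference.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(channels, dtype=np.float32)
        self.run_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._initialized = False

    def params(self):
        return [
            {"value": self.gamma, "grad": self.dgamma},
            {"value": self.beta, "grad": self.dbeta},
        ]

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            if not self._initialized:
                # seed running stats from the first batch so short runs
                # evaluate with sensible inference statistics
                self.run_mean = mean.astype(np.float32)
                self.run_var = var.astype(np.float32)
                self._initialized = True
            else:
                self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
                self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None]) * inv[None, :, None]
            self._xhat, self._inv = xhat, inv
        else:
            inv = 1.0 / np.sqrt(self.run_var + self.eps)
            xhat = (x - self.run_mean[None, :, None]) * inv[None, :, None]
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, grad):
        xhat, inv = self._xhat, self._inv
        m = grad.shape[0] * grad.shape[2]
        self.dgamma[...] = np.sum(grad * xhat, axis=(0, 2))
        self.dbeta[...] = grad.sum(axis=(0, 2))
        gxh = grad * self.gamma[None, :, None]
        dx = (
            gxh
            - gxh.mean(axis=(0, 2), keepdims=True)
            - xhat * np.mean(gxh * xhat, axis=(0, 2), keepdims=True)
        ) * inv[None, :, None]
        self._xhat = self._inv = None
        return dx.astype(np.float32)


class _ReLU(_Layer):
    def forward(self, x, training):
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class _MaxPool2(_Layer):
    def forward(self, x, training):
        n, c, L = x.shape
        xr = x.reshape(n, c, L // 2, 2)
        idx = xr.argmax(axis=3)
        if training:
            self._idx = idx
            self._L = L
        return np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]

    def backward(self, grad):
        n, c, Lh = grad.shape
        out = np.zeros((n, c, Lh, 2), dtype=np.float32)
        np.put_along_axis(out, self._idx[..., None], grad[..., None], axis=3)
        return out.reshape(n, c, self._L)


class _Flatten(_Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class _Dense(_Layer):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator) -> None:
        limit = np.sqrt(6.0 / (fin + fout))  # glorot uniform
        self.W = rng.uniform(-limit, limit, (fin, fout)).astype(np.float32)
        self.b = np.zeros(fout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [
            {"value": self.W, "grad": self.dW},
            {"value": self.b, "grad": self.db},
        ]

    def forward(self, x, training):
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        self._x = None
        return grad @ self.W.T


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class Model1D:
    """Sequential 1-D CNN: conv blocks then dense classifier head."""

    def __init__(self, config: CNNConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        layers: list[_Layer] = [
            _InputScale(np.array([1.0, config.wavenumber_scale]))
        ]
        cin = 2
        L = config.n_points
        for cout in config.conv_channels:
            for _ in range(config.convs_per_block):
                layers.append(_Conv1D(cin, cout, config.kernel_size, rng))
                if config.batch_norm:
                    layers.append(_BatchNorm1D(cout))
                layers.append(_ReLU())
                cin = cout
            layers.append(_MaxPool2())
            L //= 2
        layers.append(_Flatten())
        fin = cin * L
        self._dense_feature_indices: dict[str, int] = {}
        for di, fout in enumerate(config.dense_sizes):
            layers.append(_Dense(fin, fout, rng))
            if di < len(config.dense_sizes) - 1:
                layers.append(_ReLU())
                stage = {0: "begin", 1: "middle", 2: "end"}.get(di)
                if stage is not None:
                    # index of the post-ReLU activation of this dense layer
                    self._dense_feature_indices[stage] = len(layers) - 1
            fin = fout
        self.layers = layers

    # -- introspection -----------------------------------------------------
    @property
    def n_conv_layers(self) -> int:
        return sum(isinstance(l, _Conv1D) for l in self.layers)

    @property
    def n_dense_layers(self) -> int:
        return sum(isinstance(l, _Dense) for l in self.layers)

    @property
    def n_parameters(self) -> int:
        return sum(p["value"].size for l in self.layers for p in l.params())

    # -- compute -----------------------------------------------------------
    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3 or X.shape[1] != 2 or X.shape[2] != self.config.n_points:
            raise ValueError(
                f"expected input of shape (n, 2, {self.config.n_points}), got {X.shape}"
            )
        return X

    def forward_logits(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        h = self._check_input(X)
        for layer in self.layers:
            h = layer.forward(h, training)
        return h

    def predict_proba(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        X = self._check_input(X)
        out = np.empty((X.shape[0], N_CLASSES), dtype=np.float32)
        for start in range(0, X.shape[0], batch_size):
            sl = slice(start, start + batch_size)
            out[sl] = _softmax(self.forward_logits(X[sl], training=False))
        return out

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def parameters(self) -> list[dict]:
        return [p for l in self.layers for p in l.params()]


def build_model(config: CNNConfig | None = None) -> Model1D:
    """Construct the 18-conv / 4-dense spectral CNN with glorot-uniform init."""
    return Model1D(config or CNNConfig())


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: list[dict], lr: float, b1: float, b2: float) -> None:
        self.params = params
        self.lr, self.b1, self.b2 = lr, b1, b2
        self.m = [np.zeros_like(p["value"]) for p in params]
        self.v = [np.zeros_like(p["value"]) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p["grad"]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p["value"] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + 1e-8)


def _ce_loss(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.mean(np.sum(y * np.log(probs + 1e-12), axis=1)))


def evaluate(model: Model1D, X: np.ndarray, y_onehot: np.ndarray) -> tuple[float, float]:
    """(mean categorical cross-entropy, accuracy) on a labeled tensor set."""
    probs = model.predict_proba(X)
    loss = _ce_loss(probs, y_onehot)
    acc = float(np.mean(probs.argmax(axis=1) == y_onehot.argmax(axis=1)))
    return loss, acc


def train(
    model: Model1D,
    dataset: Dataset,
    config: CNNConfig | None = None,
    verbose: bool = False,
) -> dict[str, list[float]]:
    """Train with Adam on categorical cross-entropy.

    Returns a history dict with per-epoch ``loss`` / ``accuracy`` (training
    split, accumulated over the epoch's mini-batches) and ``val_loss`` /
    ``val_accuracy`` (held-out split).  A non-finite loss aborts with a
    diagnostic.  The seed fixes initialisation and shuffling, so repeated
    runs are bit-identical.
    """
    cfg = config or model.config
    opt = _Adam(model.parameters(), cfg.learning_rate, cfg.beta1, cfg.beta2)
    rng = np.random.default_rng(cfg.seed + 1)
    X, Y = dataset.X_train, dataset.y_train
    n = X.shape[0]
    history: dict[str, list[float]] = {
        "loss": [],
        "accuracy": [],
        "val_loss": [],
        "val_accuracy": [],
    }
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total_loss = 0.0
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], Y[idx]
            logits = model.forward_logits(xb, training=True)
            probs = _softmax(logits)
            loss = _ce_loss(probs, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch + 1}"
                )
            total_loss += loss * len(idx)
            correct += int(np.sum(probs.argmax(axis=1) == yb.argmax(axis=1)))
            model.backward((probs - yb) / len(idx))
            opt.step()
        val_loss, val_acc = evaluate(model, dataset.X_test, dataset.y_test)
        history["loss"].append(total_loss / n)
        history["accuracy"].append(correct / n)
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)
        if verbose:
            print(
                f"epoch {epoch + 1:3d}/{cfg.epochs}  "
                f"loss {history['loss'][-1]:.4f}  acc {history['accuracy'][-1]:.4f}  "
                f"val_loss {val_loss:.4f}  val_acc {val_acc:.4f}"
            )
    return history


# ---------------------------------------------------------------------------
# Prediction maps and feature extraction
# ---------------------------------------------------------------------------

def save_model(model: Model1D, directory) -> None:
    """Serialize weights (npz) plus a JSON config sidecar."""
    import json
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(model.layers):
        for j, p in enumerate(layer.params()):
            arrays[f"layer{i}_param{j}"] = p["value"]
        if isinstance(layer, _BatchNorm1D):
            arrays[f"layer{i}_run_mean"] = layer.run_mean
            arrays[f"layer{i}_run_var"] = layer.run_var
    np.savez(d / "weights.npz", **arrays)
    cfg = model.config
    (d / "config.json").write_text(
        json.dumps(
            {
                "conv_channels": list(cfg.conv_channels),
                "convs_per_block": cfg.convs_per_block,
                "kernel_size": cfg.kernel_size,
                "dense_sizes": list(cfg.dense_sizes),
                "n_points": cfg.n_points,
                "epochs": cfg.epochs,
                "batch_size": cfg.batch_size,
                "train_fraction": cfg.train_fraction,
                "learning_rate": cfg.learning_rate,
                "seed": cfg.seed,
                "batch_norm": cfg.batch_norm,
                "wavenumber_scale": cfg.wavenumber_scale,
            },
            indent=2,
        )
    )


def load_model(directory) -> Model1D:
    """Load a model serialized by :func:`save_model`."""
    import json
    from pathlib import Path

    d = Path(directory)
    raw = json.loads((d / "config.json").read_text())
    raw["conv_channels"] = tuple(raw["conv_channels"])
    raw["dense_sizes"] = tuple(raw["dense_sizes"])
    model = Model1D(CNNConfig(**raw))
    with np.load(d / "weights.npz") as data:
        for i, layer in enumerate(model.layers):
            for j, p in enumerate(layer.params()):
                p["value"][...] = data[f"layer{i}_param{j}"]
            if isinstance(layer, _BatchNorm1D):
                layer.run_mean = data[f"layer{i}_run_mean"]
                layer.run_var = data[f"layer{i}_run_var"]
    return model


@dataclass
class PredictionMap:
    """Per-pixel CNN classification of a hyperspectral map."""

    classes: np.ndarray  # (h, w) int codes 0-4
    probabilities: np.ndarray  # (h, w, 5)

    def __post_init__(self) -> None:
        if self.classes.shape != self.probabilities.shape[:2]:
            raise ValueError("classes and probabilities disagree on map shape")


def predict(model: Model1D, spectra: np.ndarray, axis: SpectralAxis) -> np.ndarray:
    """Class probabilities for raw spectra on an arbitrary axis."""
    tensors, _ = spectra_to_tensors(np.atleast_2d(spectra), axis, model.config.n_points)
    return model.predict_proba(tensors)


def predict_map(model: Model1D, raw_map: HyperMap) -> PredictionMap:
    """Classify every pixel of a raw (unpreprocessed) map."""
    probs = predict(model, raw_map.as_matrix(), raw_map.axis)
    h, w = raw_map.shape
    return PredictionMap(
        classes=probs.argmax(axis=1).reshape(h, w),
        probabilities=probs.reshape(h, w, N_CLASSES),
    )


def extract_dense_features(
    model: Model1D, spectrum: np.ndarray, stage: str, axis: SpectralAxis | None = None
) -> np.ndarray:
    """Activations of a named dense layer for one spectrum.

    ``stage`` is ``begin`` (512-unit layer), ``middle`` (256) or ``end``
    (128); the returned vector is the post-ReLU activation, so all entries
    are nonnegative.  ``spectrum`` may be a ready (2, n_points) tensor or a
    raw intensity vector accompanied by its axis.
    """
    if stage not in model._dense_feature_indices:
        raise ValueError(f"unknown stage {stage!r}; expected begin/middle/end")
    x = np.asarray(spectrum, dtype=np.float32)
    if x.ndim == 1:
        if axis is None:
            raise ValueError("a raw intensity vector needs its spectral axis")
        x, _ = spectra_to_tensors(x[None], axis, model.config.n_points)
    stop = model._dense_feature_indices[stage]
    h = model._check_input(x)
    for i, layer in enumerate(model.layers):
        h = layer.forward(h, False)
        if i == stop:
            break
    return h[0]
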