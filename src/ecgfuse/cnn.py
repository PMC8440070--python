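"""Time-domain stream: a small 1-D convolutional network over raw beats.

The default architecture maps a 250-sample beat to a 5-class softmax::

    input 250x1
    conv k=5, 4 filters, stride 1, ReLU   -> 246x4
    maxpool 2, stride 2                   -> 123x4
    conv k=4, 4 filters, ReLU             -> 120x4
    maxpool 2                             ->  60x4
    conv k=5, 4 filters, ReLU             ->  56x4
    maxpool 2                             ->  28x4
    conv k=5, 8 filters, ReLU             ->  24x8
    maxpool 2                             ->  12x8
    fully connected 10, ReLU
    output 5, softmax

Convolutions are "valid" (no padding); pooling floors odd lengths. Training
uses categorical cross-entropy and the Adam optimiser; weights are initialised
with seeded uniform fan-in scaling, so runs are reproducible from the config
seed alone. The network is small enough that plain vectorised numpy (im2col
via sliding windows) trains it in seconds on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .types import BEAT_LENGTH, CLASS_INDEX, CLASSES, BeatSegment


# --------------------------------------------------------------------------
# architecture description
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Conv:
    kernel: int
    filters: int
    stride: int = 1
    activation: str = "relu"


@dataclass(frozen=True)
class MaxPool:
    window: int = 2
    stride: int = 2


@dataclass(frozen=True)
class Dense:
    width: int
    activation: str = "relu"


@dataclass(frozen=True)
class Output:
    width: int = 5  # softmax


LayerSpec = Conv | MaxPool | Dense | Output


@dataclass(frozen=True)
class CnnArchitecture:
    layers: tuple[LayerSpec, ...]
    input_length: int = BEAT_LENGTH


def default_architecture() -> CnnArchitecture:
    """The standard 4-conv/4-pool/FC10/softmax5 architecture."""
    return CnnArchitecture(
        layers=(
            Conv(kernel=5, filters=4),
            MaxPool(),
            Conv(kernel=4, filters=4),
            MaxPool(),
            Conv(kernel=5, filters=4),
            MaxPool(),
            Conv(kernel=5, filters=8),
            MaxPool(),
            Dense(width=10),
            Output(width=5),
        ),
        input_length=BEAT_LENGTH,
    )


def layer_output_lengths(
    arch: CnnArchitecture, input_length: int | None = None
) -> list[tuple[int, ...]]:
    """Shape trace: (length, channels) after each layer, (width,) for dense.

    Pure arithmetic: valid conv with kernel k maps L -> L-k+1; pool window 2
    stride 2 maps L -> floor(L/2).
    """
    L = arch.input_length if input_length is None else input_length
    ch = 1
    out: list[tuple[int, ...]] = []
    for i, layer in enumerate(arch.layers):
        if isinstance(layer, Conv):
            L = (L - layer.kernel) // layer.stride + 1
            ch = layer.filters
            shape: tuple[int, ...] = (L, ch)
        elif isinstance(layer, MaxPool):
            L = L // layer.stride
            shape = (L, ch)
        elif isinstance(layer, (Dense, Output)):
            shape = (layer.width,)
            L, ch = layer.width, 1
        else:  # pragma: no cover
            raise TypeError(f"unknown layer spec {layer!r}")
        if L < 1:
            raise ValueError(f"layer {i} ({type(layer).__name__}) output length < 1")
        out.append(shape)
    return out


@dataclass
class TrainingConfig:
    """Optimisation settings. Defaults are the full-run settings (600 epochs,
    batch 64, Adam at 0.01); tests override epochs downward."""

    epochs: int = 600
    batch_size: int = 64
    learning_rate: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")


# --------------------------------------------------------------------------
# forward / backward primitives
# --------------------------------------------------------------------------

def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """x (B,L,Cin) * W (k,Cin,Cout) -> (B, L-k+1, Cout), valid, stride 1."""
    win = sliding_window_view(x, W.shape[0], axis=1)  # (B, Lout, Cin, k)
    return np.einsum("blkc,kco->blo", win.swapaxes(2, 3), W) + b


def _conv_backward(
    x: np.ndarray, W: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a valid stride-1 conv: returns (dx, dW, db)."""
    k = W.shape[0]
    win = sliding_window_view(x, k, axis=1).swapaxes(2, 3)  # (B, Lout, k, Cin)
    dW = np.einsum("blkc,blo->kco", win, dy)
    db = dy.sum(axis=(0, 1))
    # full correlation of dy with flipped kernel
    pad = k - 1
    dyp = np.pad(dy, ((0, 0), (pad, pad), (0, 0)))
    dwin = sliding_window_view(dyp, k, axis=1).swapaxes(2, 3)  # (B, L, k, Cout)
    Wflip = W[::-1]  # (k, Cin, Cout)
    dx = np.einsum("blko,kco->blc", dwin, Wflip)
    return dx, dW, db


def _pool_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Max pool window 2 stride 2, floor; returns (y, argmax mask)."""
    B, L, C = x.shape
    L2 = L // 2
    xr = x[:, : 2 * L2].reshape(B, L2, 2, C)
    idx = xr.argmax(axis=2)  # (B, L2, C)
    y = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]
    return y, idx


def _pool_backward(dy: np.ndarray, idx: np.ndarray, L: int) -> np.ndarray:
    B, L2, C = dy.shape
    dxr = np.zeros((B, L2, 2, C))
    np.put_along_axis(dxr, idx[:, :, None, :], dy[:, :, None, :], axis=2)
    dx = np.zeros((B, L, C))
    dx[:, : 2 * L2] = dxr.reshape(B, 2 * L2, C)
    return dx


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

@dataclass
class CnnModel:
    """A trained network: architecture, parameters and training history."""

    arch: CnnArchitecture
    params: dict[str, np.ndarray]
    config: TrainingConfig
    loss_history: list[float] = field(default_factory=list)
    trained: bool = False

    def forward(self, X: np.ndarray, return_cache: bool = False):
        """X: (B, 250) raw beats -> (B, 5) class probabilities."""
        a = X[:, :, None]  # (B, L, 1)
        cache: list[tuple] = []
        li = 0
        for layer in self.arch.layers:
            if isinstance(layer, Conv):
                W, b = self.params[f"W{li}"], self.params[f"b{li}"]
                z = _conv_forward(a, W, b)
                out = np.maximum(z, 0.0)
                cache.append(("conv", a, z))
                a = out
                li += 1
            elif isinstance(layer, MaxPool):
                out, idx = _pool_forward(a)
                cache.append(("pool", a.shape[1], idx))
                a = out
            elif isinstance(layer, Dense):
                W, b = self.params[f"W{li}"], self.params[f"b{li}"]
                flat = a.reshape(a.shape[0], -1)
                z = flat @ W + b
                out = np.maximum(z, 0.0)
                cache.append(("dense", a.shape, flat, z))
                a = out
                li += 1
            elif isinstance(layer, Output):
                W, b = self.params[f"W{li}"], self.params[f"b{li}"]
                flat = a.reshape(a.shape[0], -1)
                z = flat @ W + b
                probs = _softmax(z)
                cache.append(("output", a.shape, flat))
                a = probs
                li += 1
        return (a, cache) if return_cache else a

    def _backward(self, cache: list[tuple], probs: np.ndarray,
                  onehot: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        B = probs.shape[0]
        d = (probs - onehot) / B  # dL/dz at the softmax input
        li = sum(1 for l in self.arch.layers if not isinstance(l, MaxPool)) - 1
        for layer, c in zip(reversed(self.arch.layers), reversed(cache)):
            if isinstance(layer, Output):
                _, a_shape, flat = c
                W = self.params[f"W{li}"]
                grads[f"W{li}"] = flat.T @ d
                grads[f"b{li}"] = d.sum(axis=0)
                d = (d @ W.T).reshape(a_shape)
                li -= 1
            elif isinstance(layer, Dense):
                _, a_shape, flat, z = c
                d = d * (z > 0)
                W = self.params[f"W{li}"]
                grads[f"W{li}"] = flat.T @ d
                grads[f"b{li}"] = d.sum(axis=0)
                d = (d @ W.T).reshape(a_shape)
                li -= 1
            elif isinstance(layer, MaxPool):
                _, L, idx = c
                d = _pool_backward(d, idx, L)
            elif isinstance(layer, Conv):
                _, a_in, z = c
                d = d * (z > 0)
                W = self.params[f"W{li}"]
                d, grads[f"W{li}"], grads[f"b{li}"] = _conv_backward(a_in, W, d)
                li -= 1
        return grads


def _init_params(arch: CnnArchitecture, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Uniform fan-in initialisation for every parameterised layer."""
    params: dict[str, np.ndarray] = {}
    trace = layer_output_lengths(arch)
    ch = 1
    flat_in = arch.input_length
    li = 0
    for layer, shape in zip(arch.layers, trace):
        if isinstance(layer, Conv):
            fan_in = layer.kernel * ch
            a = np.sqrt(1.0 / fan_in)
            params[f"W{li}"] = rng.uniform(-a, a, size=(layer.kernel, ch, layer.filters))
            params[f"b{li}"] = np.zeros(layer.filters)
            ch = layer.filters
            flat_in = shape[0] * shape[1]
            li += 1
        elif isinstance(layer, MaxPool):
            flat_in = shape[0] * shape[1]
        else:
            a = np.sqrt(1.0 / flat_in)
            params[f"W{li}"] = rng.uniform(-a, a, size=(flat_in, layer.width))
            params[f"b{li}"] = np.zeros(layer.width)
            flat_in = layer.width
            li += 1
    return params


def _as_matrix(beats) -> np.ndarray:
    if isinstance(beats, np.ndarray):
        X = np.atleast_2d(np.asarray(beats, dtype=float))
    else:
        X = np.vstack([
            b.samples if isinstance(b, BeatSegment) else np.asarray(b, float)
            for b in beats
        ])
    if X.shape[1] != BEAT_LENGTH:
        raise ValueError(f"beats must have {BEAT_LENGTH} samples, got {X.shape[1]}")
    return X


def train_cnn(beats, labels, config: TrainingConfig | None = None,
              arch: CnnArchitecture | None = None) -> CnnModel:
    """Train the network with Adam on categorical cross-entropy.

    Deterministic given ``config.rng_seed``: initialisation and the per-epoch
    batch shuffle both draw from one seeded generator.
    """
    config = config or TrainingConfig()
    arch = arch or default_architecture()
    X = _as_matrix(beats)
    y = np.asarray([CLASS_INDEX[l] for l in labels])
    if X.shape[0] != y.size:
        raise ValueError("beats and labels must have equal length")
    if np.unique(y).size < 2:
        raise ValueError("training needs at least 2 distinct classes")

    rng = np.random.default_rng(config.rng_seed)
    model = CnnModel(arch=arch, params=_init_params(arch, rng), config=config)
    onehot = np.eye(len(CLASSES))[y]

    # Adam state
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(vv) for k, vv in model.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0

    n = X.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start: start + config.batch_size]
            probs, cache = model.forward(X[idx], return_cache=True)
            p = np.clip(probs[np.arange(idx.size), y[idx]], 1e-12, None)
            epoch_loss += float(-np.log(p).sum())
            grads = model._backward(cache, probs, onehot[idx])
            t += 1
            for k, g in grads.items():
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1**t)
                vhat = v[k] / (1 - b2**t)
                model.params[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        model.loss_history.append(epoch_loss / n)
    model.trained = True
    return model


def predict_mass_cnn(model: CnnModel, beats) -> np.ndarray:
    """Per-beat class probabilities (n, 5); each row is a valid mass function
    over the frame {N, L, R, V, A} (nonnegative, sums to 1)."""
    if not model.trained:
        raise ValueError("model has not been trained")
    return model.forward(_as_matrix(beats))


def save_model(model: CnnModel, path) -> None:
    """Serialise architecture + weights + config to one .npz file."""
    meta = {
        "layers": repr(model.arch.layers),
        "input_length": model.arch.input_length,
        "epochs": model.config.epochs,
        "batch_size": model.config.batch_size,
        "learning_rate": model.config.learning_rate,
        "rng_seed": model.config.rng_seed,
    }
    np.savez(path, _meta=np.asarray([repr(meta)]),
             _loss=np.asarray(model.loss_history), **model.params)


def load_model(path) -> CnnModel:
    import ast

    data = np.load(path, allow_pickle=False)
    meta = ast.literal_eval(str(data["_meta"][0]))
    arch = CnnArchitecture(layers=eval(meta["layers"]),  # specs are dataclass reprs
                           input_length=int(meta["input_length"]))
    config = TrainingConfig(
        epochs=int(meta["epochs"]), batch_size=int(meta["batch_size"]),
        learning_rate=float(meta["learning_rate"]), rng_seed=int(meta["rng_seed"]),
    )
    params = {k: data[k] for k in data.files if not k.startswith("_")}
    return CnnModel(arch=arch, params=params, config=config,
                    loss_history=list(data["_loss"]), trained=True)
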