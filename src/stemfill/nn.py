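"""Recurrent sequence models: architecture specs, analytic parameter
accounting, training and one-step prediction.

The models are stacked LSTM / simple-RNN layers with an optional dropout
layer and a final dense unit, trained by mean-squared-error
backpropagation-through-time with the Adam optimizer.  The implementation
is pure numpy and fully seeded, so training is reproducible bit-for-bit on
a fixed thread count.

An LSTM cell follows the standard gate equations

    f_t = σ(W_f·[h_{t−1}, x_t] + b_f)        (forget gate)
    i_t = σ(W_i·[h_{t−1}, x_t] + b_i)        (input gate)
    c_t = f_t ∘ c_{t−1} + i_t ∘ tanh(W_c·[h_{t−1}, x_t] + b_c)
    o_t = σ(W_o·[h_{t−1}, x_t] + b_o)        (output gate)
    h_t = o_t ∘ tanh(c_t)

with one bias vector per gate, so a layer with input width n and m units
carries 4·((n+m)·m + m) trainable parameters; a simple-RNN layer
(h_t = tanh(W·[h_{t−1}, x_t] + b)) carries (n+m)·m + m, exactly a quarter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .core_series import MinMaxTransform, Series

LAYER_KINDS = ("lstm", "rnn", "dense", "dropout")


# ---------------------------------------------------------------------------
# architecture specification and analytic parameter accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    kind: str
    units: int | None = None
    dropout_fraction: float | None = None
    return_sequences: bool = False

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "dropout":
            if self.dropout_fraction is None or not 0.0 <= self.dropout_fraction < 1.0:
                raise ValueError("dropout_fraction must lie in [0, 1)")
        else:
            if self.units is None or self.units < 1:
                raise ValueError(f"{self.kind} layer needs units >= 1")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer stack plus windowing and batching configuration."""

    layers: tuple[LayerSpec, ...]
    window_length: int = 200
    batch_size: int = 100
    input_features: int = 1

    def __post_init__(self) -> None:
        layers = tuple(self.layers)
        object.__setattr__(self, "layers", layers)
        if not layers:
            raise ValueError("architecture needs at least one layer")
        last = layers[-1]
        if last.kind != "dense" or last.units != 1:
            raise ValueError("last layer must be a dense layer with 1 unit")
        if self.window_length < 1 or self.batch_size < 1 or self.input_features < 1:
            raise ValueError("window_length, batch_size, input_features must be >= 1")

    def to_dict(self) -> dict:
        return {
            "layers": [asdict(l) for l in self.layers],
            "window_length": self.window_length,
            "batch_size": self.batch_size,
            "input_features": self.input_features,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(
            layers=tuple(LayerSpec(**l) for l in d["layers"]),
            window_length=d["window_length"],
            batch_size=d["batch_size"],
            input_features=d["input_features"],
        )


def stacked_architecture(
    kind: str,
    units: tuple[int, ...],
    *,
    dropout_fraction: float | None = 0.2,
    window_length: int = 200,
    batch_size: int = 100,
    input_features: int = 1,
) -> ArchitectureSpec:
    """Stack of recurrent layers (dropout after the first), ending in a
    single dense output unit."""
    layers: list[LayerSpec] = []
    for i, m in enumerate(units):
        layers.append(
            LayerSpec(kind=kind, units=m, return_sequences=i < len(units) - 1)
        )
        if i == 0 and dropout_fraction:
            layers.append(LayerSpec(kind="dropout", dropout_fraction=dropout_fraction))
    layers.append(LayerSpec(kind="dense", units=1))
    return ArchitectureSpec(
        layers=tuple(layers),
        window_length=window_length,
        batch_size=batch_size,
        input_features=input_features,
    )


def reference_lstm_architecture(**kwargs) -> ArchitectureSpec:
    """The 3-layer 256/128/64 LSTM stack with dropout after the first layer."""
    return stacked_architecture("lstm", (256, 128, 64), **kwargs)


def reference_rnn_architecture(**kwargs) -> ArchitectureSpec:
    """The simple-RNN twin of :func:`reference_lstm_architecture`."""
    return stacked_architecture("rnn", (256, 128, 64), **kwargs)


def count_layer_params(kind: str, input_width: int, units: int) -> int:
    """Analytic trainable-parameter count of one layer.

    lstm → 4·((n+m)·m + m); rnn → (n+m)·m + m; dense → n·m + m, where n is
    the input width and m the unit count.  One bias vector per gate.
    """
    n, m = int(input_width), int(units)
    if n < 0 or m < 0:
        raise ValueError("input width and units must be non-negative")
    if kind == "lstm":
        return 4 * ((n + m) * m + m)
    if kind == "rnn":
        return (n + m) * m + m
    if kind == "dense":
        return n * m + m
    raise ValueError(f"no parameter formula for layer kind {kind!r}")


def count_model_params(arch: ArchitectureSpec) -> tuple[list[int], int]:
    """Per-layer analytic parameter counts (dropout layers contribute 0) and
    their total, in layer order."""
    counts: list[int] = []
    width = arch.input_features
    for layer in arch.layers:
        if layer.kind == "dropout":
            counts.append(0)
        else:
            counts.append(count_layer_params(layer.kind, width, layer.units))
            width = layer.units
    return counts, sum(counts)


# ---------------------------------------------------------------------------
# numpy layers with backpropagation
# ---------------------------------------------------------------------------

def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, n_in: int, n_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=shape)


class _LSTMLayer:
    """LSTM over (B, T, n) input; gate order in the fused matrix is
    [input, forget, cell candidate, output]."""

    def __init__(self, n_in: int, units: int, return_sequences: bool,
                 rng: np.random.Generator):
        m = units
        self.n_in, self.units, self.return_sequences = n_in, m, return_sequences
        self.W = _glorot(rng, n_in + m, m, (n_in + m, 4 * m))
        self.b = np.zeros(4 * m)
        self.b[m : 2 * m] = 1.0  # forget-gate bias init
        self.params = [self.W, self.b]

    @property
    def param_count(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, T, n = x.shape
        m = self.units
        h = np.zeros((B, m))
        c = np.zeros((B, m))
        cache = {"x": x, "h": [], "c": [], "i": [], "f": [], "g": [], "o": [],
                 "c_prev": [], "h_prev": []}
        hs = np.empty((B, T, m))
        for t in range(T):
            z = np.concatenate([h, x[:, t, :]], axis=1)
            gates = z @ self.W + self.b
            i = _sigmoid(gates[:, :m])
            f = _sigmoid(gates[:, m : 2 * m])
            g = np.tanh(gates[:, 2 * m : 3 * m])
            o = _sigmoid(gates[:, 3 * m :])
            cache["h_prev"].append(h)
            cache["c_prev"].append(c)
            c = f * c + i * g
            h = o * np.tanh(c)
            for key, val in (("h", h), ("c", c), ("i", i), ("f", f), ("g", g), ("o", o)):
                cache[key].append(val)
            hs[:, t, :] = h
        self._cache = cache
        return hs if self.return_sequences else h

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        cache = self._cache
        x = cache["x"]
        B, T, n = x.shape
        m = self.units
        dW = np.zeros_like(self.W)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, m))
        dc_next = np.zeros((B, m))
        for t in range(T - 1, -1, -1):
            dh = dh_next.copy()
            if self.return_sequences:
                dh += grad_out[:, t, :]
            elif t == T - 1:
                dh += grad_out
            c_t = cache["c"][t]
            i, f, g, o = (cache[k][t] for k in ("i", "f", "g", "o"))
            tanh_c = np.tanh(c_t)
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * cache["c_prev"][t]
            dc_next = dc * f
            dgates = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            z = np.concatenate([cache["h_prev"][t], x[:, t, :]], axis=1)
            dW += z.T @ dgates
            db += dgates.sum(axis=0)
            dz = dgates @ self.W.T
            dh_next = dz[:, :m]
            dx[:, t, :] = dz[:, m:]
        self.grads = [dW, db]
        return dx


class _RNNLayer:
    """Simple tanh recurrent layer over (B, T, n) input."""

    def __init__(self, n_in: int, units: int, return_sequences: bool,
                 rng: np.random.Generator):
        m = units
        self.n_in, self.units, self.return_sequences = n_in, m, return_sequences
        self.W = _glorot(rng, n_in + m, m, (n_in + m, m))
        self.b = np.zeros(m)
        self.params = [self.W, self.b]

    @property
    def param_count(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, T, n = x.shape
        m = self.units
        h = np.zeros((B, m))
        self._cache = {"x": x, "h": [], "h_prev": []}
        hs = np.empty((B, T, m))
        for t in range(T):
            self._cache["h_prev"].append(h)
            z = np.concatenate([h, x[:, t, :]], axis=1)
            h = np.tanh(z @ self.W + self.b)
            self._cache["h"].append(h)
            hs[:, t, :] = h
        return hs if self.return_sequences else h

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        cache = self._cache
        x = cache["x"]
        B, T, n = x.shape
        m = self.units
        dW = np.zeros_like(self.W)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, m))
        for t in range(T - 1, -1, -1):
            dh = dh_next.copy()
            if self.return_sequences:
                dh += grad_out[:, t, :]
            elif t == T - 1:
                dh += grad_out
            h = cache["h"][t]
            dpre = dh * (1.0 - h**2)
            z = np.concatenate([cache["h_prev"][t], x[:, t, :]], axis=1)
            dW += z.T @ dpre
            db += dpre.sum(axis=0)
            dz = dpre @ self.W.T
            dh_next = dz[:, :m]
            dx[:, t, :] = dz[:, m:]
        self.grads = [dW, db]
        return dx


class _DenseLayer:
    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        self.n_in, self.units = n_in, units
        self.W = _glorot(rng, n_in, units, (n_in, units))
        self.b = np.zeros(units)
        self.params = [self.W, self.b]

    @property
    def param_count(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.grads = [self._x.T @ grad_out, grad_out.sum(axis=0)]
        return grad_out @ self.W.T


class _DropoutLayer:
    """Inverted dropout; identity at inference."""

    def __init__(self, fraction: float, rng: np.random.Generator):
        self.fraction = fraction
        self.rng = rng
        self.params: list[np.ndarray] = []

    @property
    def param_count(self) -> int:
        return 0

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.fraction == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.fraction
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad_out
        return grad_out * self._mask


class SequenceNetwork:
    """Instantiated stack of layers per an :class:`ArchitectureSpec`."""

    def __init__(self, arch: ArchitectureSpec, seed: int = 0):
        self.arch = arch
        rng = np.random.default_rng(seed)
        self.layers = []
        width = arch.input_features
        for spec in arch.layers:
            if spec.kind == "lstm":
                layer = _LSTMLayer(width, spec.units, spec.return_sequences, rng)
                width = spec.units
            elif spec.kind == "rnn":
                layer = _RNNLayer(width, spec.units, spec.return_sequences, rng)
                width = spec.units
            elif spec.kind == "dense":
                layer = _DenseLayer(width, spec.units, rng)
                width = spec.units
            else:
                layer = _DropoutLayer(spec.dropout_fraction, np.random.default_rng(seed + 1))
            self.layers.append(layer)

    def layer_param_counts(self) -> list[int]:
        """Parameter counts read off the instantiated weight arrays —
        the model-summary route, independent of the analytic formulas."""
        return [layer.param_count for layer in self.layers]

    def total_param_count(self) -> int:
        return sum(self.layer_param_counts())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, training)
        return out

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def parameters(self):
        for layer in self.layers:
            yield from layer.params

    def gradients(self):
        for layer in self.layers:
            if layer.params:
                yield from layer.grads


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# windowing, training, prediction
# ---------------------------------------------------------------------------

def make_training_windows(
    series: Series | np.ndarray,
    window_length: int,
    segment: slice | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding (window, next-value target) pairs from an observed segment.

    Window k covers indices ``[k, k + window_length)`` of the segment and its
    target is the value at ``k + window_length``; a segment of length L gives
    L − window_length pairs.  The segment must be fully observed and strictly
    longer than the window.
    """
    if isinstance(series, Series):
        values = series.values
        mask = series.mask
    else:
        values = np.asarray(series, dtype=float)
        mask = np.isnan(values)
    if segment is not None:
        values = values[segment]
        mask = mask[segment]
    if mask.any():
        raise ValueError("training segment contains missing values")
    L = values.size
    if L <= window_length:
        raise ValueError(
            f"segment length {L} must exceed window length {window_length}"
        )
    k = L - window_length
    idx = np.arange(window_length)[None, :] + np.arange(k)[:, None]
    windows = values[idx][:, :, None]
    targets = values[window_length:]
    return windows, targets


@dataclass
class TrainedModel:
    """A fitted sequence model plus its normalization transform."""

    architecture: ArchitectureSpec
    network: SequenceNetwork
    transform: MinMaxTransform | None = None
    loss_trace: list[float] = field(default_factory=list)
    seed: int = 0

    def predict(self, windows: np.ndarray) -> np.ndarray:
        """Batched one-step prediction in normalized space (dropout off)."""
        windows = np.asarray(windows, dtype=float)
        if windows.ndim == 2:
            windows = windows[:, :, None]
        if windows.shape[1] != self.architecture.window_length:
            raise ValueError(
                f"window length {windows.shape[1]} != architecture "
                f"window_length {self.architecture.window_length}"
            )
        if windows.shape[2] != self.architecture.input_features:
            raise ValueError("window feature width mismatch")
        return self.network.forward(windows, training=False)[:, 0]

    def save(self, path) -> None:
        """Native .npz checkpoint plus a JSON sidecar with the architecture,
        normalization, seed and parameter-count table."""
        import pathlib

        path = pathlib.Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self.network.parameters())}
        np.savez(path.with_suffix(".npz"), **arrays)
        analytic, total = count_model_params(self.architecture)
        sidecar = {
            "architecture": self.architecture.to_dict(),
            "transform": None if self.transform is None else
            {"lo": self.transform.lo, "hi": self.transform.hi},
            "seed": self.seed,
            "loss_trace": self.loss_trace,
            "param_counts": {"per_layer": analytic, "total": total},
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "TrainedModel":
        import pathlib

        path = pathlib.Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        arch = ArchitectureSpec.from_dict(sidecar["architecture"])
        model = cls(
            architecture=arch,
            network=SequenceNetwork(arch, seed=sidecar["seed"]),
            transform=None if sidecar["transform"] is None else
            MinMaxTransform(**sidecar["transform"]),
            loss_trace=list(sidecar["loss_trace"]),
            seed=sidecar["seed"],
        )
        with np.load(path.with_suffix(".npz")) as data:
            for i, p in enumerate(model.network.parameters()):
                p[...] = data[f"p{i}"]
        return model


def train(
    arch: ArchitectureSpec,
    windows: np.ndarray,
    targets: np.ndarray,
    *,
    epochs: int = 100,
    seed: int = 0,
    learning_rate: float = 1e-3,
    transform: MinMaxTransform | None = None,
) -> TrainedModel:
    """Fit a sequence model by MSE backpropagation-through-time with Adam.

    *windows* is (k, window_length) or (k, window_length, features), already
    normalized via the supplied transform; *targets* is (k,).  The per-epoch
    mean MSE over minibatches is recorded in the loss trace.  With a fixed
    seed the trace and the fitted weights are reproducible.
    """
    windows = np.asarray(windows, dtype=float)
    if windows.ndim == 2:
        windows = windows[:, :, None]
    targets = np.asarray(targets, dtype=float).reshape(-1)
    if windows.shape[0] != targets.size or windows.shape[0] < 1:
        raise ValueError("need >= 1 window with matching targets")
    if windows.shape[1] != arch.window_length:
        raise ValueError("window length does not match architecture")
    if windows.shape[2] != arch.input_features:
        raise ValueError(
            f"window feature width {windows.shape[2]} != "
            f"architecture input_features {arch.input_features}"
        )
    net = SequenceNetwork(arch, seed=seed)
    opt = _Adam(net.parameters(), lr=learning_rate)
    shuffle_rng = np.random.default_rng(seed + 10_000)
    k = windows.shape[0]
    loss_trace: list[float] = []
    for _ in range(epochs):
        order = shuffle_rng.permutation(k)
        epoch_losses = []
        for lo in range(0, k, arch.batch_size):
            sel = order[lo : lo + arch.batch_size]
            xb, yb = windows[sel], targets[sel]
            pred = net.forward(xb, training=True)[:, 0]
            err = pred - yb
            epoch_losses.append(float(np.mean(err**2)))
            grad = (2.0 * err / err.size)[:, None]
            net.backward(grad)
            opt.step(net.gradients())
        loss_trace.append(float(np.mean(epoch_losses)))
    return TrainedModel(
        architecture=arch,
        network=net,
        transform=transform,
        loss_trace=loss_trace,
        seed=seed,
    )


def predict_next(model: TrainedModel, window: np.ndarray) -> float:
    """Deterministic one-step prediction for a single normalized window."""
    window = np.asarray(window, dtype=float)
    if window.ndim == 1:
        window = window[:, None]
    if window.shape[0] != model.architecture.window_length:
        raise ValueError(
            f"window length {window.shape[0]} != architecture "
            f"window_length {model.architecture.window_length}"
        )
    return float(model.predict(window[None, :, :])[0])
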