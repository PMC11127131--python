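"""1D convolutional encoder + feedforward classifier, in pure NumPy.

The architecture is a U-Net-style encoder followed by a small feedforward
head: three blocks of [conv1d(k=3) → SiLU → conv1d(k=3) → SiLU →
maxpool(k=2)], channel width doubling per block, a 15% dropout layer
between blocks, then flatten → fully-connected → SiLU → fully-connected →
3-class output. Convolutions use same-padding so the temporal length per
block is 64 → 32 → 16 → 8.

Forward and backward passes are implemented directly (im2col convolution,
explicit gradients) so training is fully deterministic on a fixed device
given a seed. ``forward`` returns logits by default; probabilities are a
softmax on top and the cross-entropy loss consumes logits for numerical
stability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class ShapeContractError(ValueError):
    """Input tensor does not match the model's expected shape."""


class ConfigError(ValueError):
    """Architecture configuration violates its invariants."""


@dataclass(frozen=True)
class ModelConfig:
    """Structural hyperparameters of the classifier.

    ``n_blocks``, ``conv_kernel``, ``pool_kernel``, ``dropout`` and ``n_fc``
    default to the reference architecture (3 blocks, kernel 3, pool 2, 15%
    dropout, 2 fully connected layers, SiLU). ``base_channels`` and
    ``fc_hidden`` control capacity; channel counts per block are
    base, 2*base, 4*base, ...
    """

    in_channels: int = 8
    window: int = 64
    n_blocks: int = 3
    base_channels: int = 16
    conv_kernel: int = 3
    pool_kernel: int = 2
    dropout: float = 0.15
    n_fc: int = 2
    fc_hidden: int = 64
    n_classes: int = 3

    def __post_init__(self) -> None:
        if self.window % (self.pool_kernel**self.n_blocks) != 0:
            raise ConfigError(
                f"window {self.window} not divisible by "
                f"pool_kernel^n_blocks = {self.pool_kernel ** self.n_blocks}"
            )
        if not 0 <= self.dropout < 1:
            raise ConfigError("dropout must lie in [0, 1)")
        if self.n_fc != 2:
            raise ConfigError("the head has exactly 2 fully connected layers")
        if min(self.in_channels, self.window, self.n_blocks, self.base_channels,
               self.fc_hidden, self.n_classes) < 1:
            raise ConfigError("all size fields must be >= 1")

    @property
    def block_channels(self) -> list[int]:
        return [self.base_channels * 2**i for i in range(self.n_blocks)]

    @property
    def encoder_out_len(self) -> int:
        return self.window // self.pool_kernel**self.n_blocks

    @property
    def flat_features(self) -> int:
        return self.block_channels[-1] * self.encoder_out_len


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # exp overflow for very negative x saturates to 1/inf = 0, the right limit
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def silu(x: np.ndarray) -> np.ndarray:
    return x * _sigmoid(x)


def _silu_grad(x: np.ndarray) -> np.ndarray:
    s = _sigmoid(x)
    return s * (1.0 + x * (1.0 - s))


def _uniform_init(rng: np.random.Generator, shape, fan_in: int,
                  dtype=np.float32) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class _Conv1dSame:
    """k-tap 1D convolution with same-padding, via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        fan_in = c_in * k
        self.W = _uniform_init(rng, (c_out, c_in * k), fan_in, dtype)
        self.b = _uniform_init(rng, (c_out,), fan_in, dtype)
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, L = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        # [B, C, L, k] -> [B, L, C*k]
        cols = sliding_window_view(xp, self.k, axis=2)
        cols = cols.transpose(0, 2, 1, 3).reshape(B, L, C * self.k)
        self._cols = cols if train else None
        self._in_shape = (B, C, L)
        y = cols @ self.W.T + self.b  # [B, L, c_out]
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, L = self._in_shape
        pad = self.k // 2
        dyt = dy.transpose(0, 2, 1).reshape(B * L, self.c_out)
        cols = self._cols.reshape(B * L, C * self.k)
        self.dW = dyt.T @ cols
        self.db = dyt.sum(axis=0)
        dcols = (dyt @ self.W).reshape(B, L, C, self.k)
        dxp = np.zeros((B, C, L + 2 * pad), dtype=dy.dtype)
        for j in range(self.k):
            dxp[:, :, j : j + L] += dcols[:, :, :, j].transpose(0, 2, 1)
        self._cols = None
        return dxp[:, :, pad : pad + L]


class _SiLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x if train else None
        return silu(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        g = dy * _silu_grad(self._x)
        self._x = None
        return g


class _MaxPool1d:
    def __init__(self, k: int):
        self.k = k

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, L = x.shape
        if L % self.k:
            raise ShapeContractError(f"pool input length {L} not divisible by {self.k}")
        xr = x.reshape(B, C, L // self.k, self.k)
        self._idx = np.argmax(xr, axis=3) if train else None
        self._in_shape = (B, C, L)
        return np.max(xr, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, L = self._in_shape
        dxr = np.zeros((B, C, L // self.k, self.k), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=3)
        self._idx = None
        return dxr.reshape(B, C, L)


class _Dropout:
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float):
        self.p = p

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = rng.random(x.shape) >= self.p
        self._mask = keep.astype(x.dtype) / np.asarray(1.0 - self.p, dtype=x.dtype)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        g = dy * self._mask
        self._mask = None
        return g


class _Flatten:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], int(np.prod(x.shape[1:])))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.W = _uniform_init(rng, (n_out, n_in), n_in, dtype)
        self.b = _uniform_init(rng, (n_out,), n_in, dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x if train else None
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = dy.T @ self._x
        self.db = dy.sum(axis=0)
        dx = dy @ self.W
        self._x = None
        return dx


class Classifier:
    """Encoder + head with a strict forward contract.

    Use :func:`build_model` to construct one with seeded initialization.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator,
                 dtype=np.float32):
        self.config = config
        self.dtype = np.dtype(dtype)
        k, pk = config.conv_kernel, config.pool_kernel
        self.convs: list[_Conv1dSame] = []
        self.pools: list[_MaxPool1d] = []
        self.dropouts: list[_Dropout] = []
        c_prev = config.in_channels
        for i, c in enumerate(config.block_channels):
            self.convs.append(_Conv1dSame(c_prev, c, k, rng, dtype))
            self.convs.append(_Conv1dSame(c, c, k, rng, dtype))
            self.pools.append(_MaxPool1d(pk))
            if i < config.n_blocks - 1:  # dropout sits between blocks
                self.dropouts.append(_Dropout(config.dropout))
            c_prev = c
        self.fc1 = _Dense(config.flat_features, config.fc_hidden, rng, dtype)
        self.fc2 = _Dense(config.fc_hidden, config.n_classes, rng, dtype)
        self.flatten = _Flatten()
        self.acts = [_SiLU() for _ in range(2 * config.n_blocks + 1)]

    # ---- parameter plumbing -------------------------------------------------

    def _param_layers(self):
        return [*self.convs, self.fc1, self.fc2]

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self._param_layers():
            out.extend([layer.W, layer.b])
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self._param_layers():
            out.extend([layer.dW, layer.db])
        return out

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        it = iter(state)
        for layer in self._param_layers():
            layer.W = next(it).copy()
            layer.b = next(it).copy()

    # ---- forward / backward -------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        mode: str = "logits",
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Run a batch [B, in_channels, window] through the network.

        ``mode`` is "logits" or "proba" (softmax rows on the 3-simplex).
        Eval mode (``train=False``) disables dropout and is a pure function
        of (parameters, input).
        """
        x = np.asarray(x, dtype=self.dtype)
        cfg = self.config
        if x.ndim != 3 or x.shape[1:] != (cfg.in_channels, cfg.window):
            raise ShapeContractError(
                f"expected batch of shape [B, {cfg.in_channels}, {cfg.window}], "
                f"got {tuple(x.shape)}"
            )
        h = x
        ai = 0
        for i in range(cfg.n_blocks):
            h = self.convs[2 * i].forward(h, train)
            h = self.acts[ai].forward(h, train); ai += 1
            h = self.convs[2 * i + 1].forward(h, train)
            h = self.acts[ai].forward(h, train); ai += 1
            h = self.pools[i].forward(h, train)
            if i < cfg.n_blocks - 1:
                h = self.dropouts[i].forward(h, train, rng)
        h = self.flatten.forward(h, train)
        h = self.fc1.forward(h, train)
        h = self.acts[ai].forward(h, train)
        logits = self.fc2.forward(h, train)
        if mode == "logits":
            return logits
        if mode == "proba":
            return softmax(logits)
        raise ValueError(f"unknown mode: {mode!r}")

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate d(loss)/d(logits); gradients land in the layers."""
        cfg = self.config
        g = self.fc2.backward(dlogits)
        g = self.acts[-1].backward(g)
        g = self.fc1.backward(g)
        g = self.flatten.backward(g)
        ai = 2 * cfg.n_blocks - 1
        for i in reversed(range(cfg.n_blocks)):
            if i < cfg.n_blocks - 1:
                g = self.dropouts[i].backward(g)
            g = self.pools[i].backward(g)
            g = self.acts[ai].backward(g); ai -= 1
            g = self.convs[2 * i + 1].backward(g)
            g = self.acts[ai].backward(g); ai -= 1
            g = self.convs[2 * i].backward(g)

    def predict(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Eval-mode class predictions for an arbitrary-size input."""
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(np.argmax(self.forward(x[i : i + batch_size]), axis=1))
        return np.concatenate(outs) if outs else np.empty(0, dtype=np.int64)

    # ---- persistence --------------------------------------------------------

    def save(self, path, seed: int | None = None) -> None:
        """Single-file checkpoint holding config, seed provenance, weights."""
        meta = {"config": asdict(self.config), "seed": seed}
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "Classifier":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            cfg = ModelConfig(**meta["config"])
            model = build_model(cfg, seed=0)
            state = [z[f"p{i}"] for i in range(len(model.parameters()))]
        model.set_state(state)
        return model


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True) if len(logits) else logits
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True) if len(logits) else e


def build_model(config: ModelConfig, seed: int, dtype=np.float32) -> Classifier:
    """Instantiate the classifier with deterministic seeded initialization.

    Weights and biases are drawn from U(-1/sqrt(fan_in), 1/sqrt(fan_in));
    identical seeds give identical initial parameters. ``dtype`` selects the
    compute precision: float32 (default) for speed, float64 when exact
    gradients are being checked numerically.
    """
    return Classifier(config, np.random.default_rng(seed), dtype=dtype)


def parameter_count(config: ModelConfig) -> int:
    """Closed-form number of trainable parameters for a config.

    Per block (two convs c_in→c and c→c, kernel k):
    ``c*(c_in*k) + c  +  c*(c*k) + c``; head:
    ``h*F + h + n_classes*h + n_classes`` with F the flattened encoder
    output. Matches the instantiated model exactly.
    """
    k = config.conv_kernel
    total = 0
    c_prev = config.in_channels
    for c in config.block_channels:
        total += c * (c_prev * k) + c  # conv 1
        total += c * (c * k) + c  # conv 2
        c_prev = c
    total += config.fc_hidden * config.flat_features + config.fc_hidden
    total += config.n_classes * config.fc_hidden + config.n_classes
    return total


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over a batch and its gradient w.r.t. logits."""
    B = len(y)
    z = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1))
    loss = float(np.mean(logsumexp - z[np.arange(B), y]))
    p = softmax(logits)
    p[np.arange(B), y] -= 1.0
    return loss, p / B
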