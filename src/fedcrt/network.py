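"""A small trainable 3D convolutional network for tumor-patch classification.

Architecture: three blocks of [3D convolution -> ReLU -> 2x2x2 max-pool],
then flatten -> fully-connected -> ReLU -> fully-connected(2) -> softmax.
Convolutions are stride-1 with same-padding, so each pool halves the cube:
a 64-voxel input reaches the classifier head at 8^3 spatial resolution.

The network is implemented directly on NumPy arrays (float64) with
hand-written backpropagation: convolution via im2col + matmul, max-pool
backward by argmax scatter, and a fused softmax/cross-entropy head.  All
computation is deterministic given the initialisation seed, there is no
normalisation or dropout, and samples in a batch never interact — so
predictions are batch-size invariant and federated parameter exchange is
exactly reproducible.

Weights are exported/imported as an ordered :class:`ParameterSet`, the unit
of client/server exchange in federated averaging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ModelConfig", "ParameterSet", "Conv3DNet", "reduced_config", "softmax"]


@dataclass
class ModelConfig:
    """Hyperparameters of the 3-conv-block classifier.

    The layer structure (3 conv + 3 pool + 2 fully-connected + softmax) is
    fixed; channel counts, kernel size and hidden width are configurable.
    ``input_size`` must be divisible by ``pool_size ** 3``.
    """

    input_size: int = 64
    conv_channels: tuple[int, int, int] = (16, 32, 64)
    kernel_size: int = 3
    pool_size: int = 2
    fc_hidden: int = 128
    n_classes: int = 2
    init_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 3:
            raise ValueError("conv_channels must have exactly three entries")
        if self.kernel_size % 2 != 1 or self.kernel_size < 1:
            raise ValueError("kernel_size must be odd and positive")
        if self.input_size % self.pool_size ** 3 != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by "
                f"pool_size^3 = {self.pool_size ** 3}"
            )
        if self.n_classes != 2:
            raise ValueError("this classifier is two-class (softmax over 2 logits)")

    @property
    def final_spatial(self) -> int:
        return self.input_size // self.pool_size ** 3

    def to_json(self) -> str:
        return json.dumps(self.__dict__, default=list)

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        d = json.loads(s)
        d["conv_channels"] = tuple(d["conv_channels"])
        return cls(**d)


def reduced_config(init_seed: int = 0) -> ModelConfig:
    """Desk-scale preset: 16^3 input, channels (4, 8, 16), hidden width 32."""
    return ModelConfig(input_size=16, conv_channels=(4, 8, 16), fc_hidden=32, init_seed=init_seed)


@dataclass
class ParameterSet:
    """Ordered, named collection of weight arrays; the unit of federated exchange."""

    entries: list[tuple[str, np.ndarray]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    def arrays(self) -> list[np.ndarray]:
        return [a for _, a in self.entries]

    def copy(self) -> "ParameterSet":
        return ParameterSet([(n, a.copy()) for n, a in self.entries])

    def n_parameters(self) -> int:
        return int(sum(a.size for _, a in self.entries))

    def save(self, path: str) -> None:
        """Archive as .npz plus a JSON manifest of names/shapes alongside."""
        np.savez(path, **dict(self.entries))
        manifest = {n: list(a.shape) for n, a in self.entries}
        with open(str(path) + ".manifest.json", "w") as fh:
            json.dump({"order": self.names, "shapes": manifest}, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "ParameterSet":
        with open(str(path) + ".manifest.json") as fh:
            manifest = json.load(fh)
        with np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz") as npz:
            return cls([(n, np.array(npz[n])) for n in manifest["order"]])


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# layers


def _conv3d(x: np.ndarray, w: np.ndarray, pad: int) -> tuple[np.ndarray, np.ndarray]:
    """Stride-1 3D cross-correlation with symmetric zero padding.

    Returns (output, cols) where ``cols`` is the im2col matrix
    (N*D*H*W, C*k^3) reused by the weight-gradient computation.
    """
    n, c, d, h, wdt = x.shape
    o, _, k, _, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    # win: (N, C, D, H, W, k, k, k) -> cols (N*D*H*W, C*k^3)
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * d * h * wdt, c * k ** 3)
    out = cols @ w.reshape(o, -1).T
    return out.reshape(n, d, h, wdt, o).transpose(0, 4, 1, 2, 3), cols


class _Conv3D:
    def __init__(self, name: str, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        fan_in = in_ch * k ** 3
        self.name, self.k, self.pad = name, k, k // 2
        self.params = {
            f"{name}.weight": rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, k, k, k)),
            f"{name}.bias": np.zeros(out_ch),
        }
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        w = self.params[f"{self.name}.weight"]
        out, cols = _conv3d(x, w, self.pad)
        out += self.params[f"{self.name}.bias"][None, :, None, None, None]
        if train:
            self._cache = (x.shape, cols)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xshape, cols = self._cache
        w = self.params[f"{self.name}.weight"]
        o = w.shape[0]
        dyc = dy.transpose(0, 2, 3, 4, 1).reshape(-1, o)
        self.grads[f"{self.name}.weight"] = (dyc.T @ cols).reshape(w.shape)
        self.grads[f"{self.name}.bias"] = dyc.sum(axis=0)
        # input gradient = correlation of dy with the flipped, transposed kernel
        wt = w.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
        dx, _ = _conv3d(dy, np.ascontiguousarray(wt), self.pad)
        self._cache = None
        return dx


class _ReLU:
    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class _MaxPool3D:
    """2x2x2 (or p^3) max pooling; ties resolve to the first window position."""

    params: dict = {}
    grads: dict = {}

    def __init__(self, p: int):
        self.p = p

    def _windows(self, x: np.ndarray) -> np.ndarray:
        n, c, d, h, w = x.shape
        p = self.p
        xr = x.reshape(n, c, d // p, p, h // p, p, w // p, p)
        return xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, d // p, h // p, w // p, p ** 3)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        win = self._windows(x)
        idx = win.argmax(axis=-1)
        if train:
            self._cache = (x.shape, idx)
        return np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xshape, idx = self._cache
        n, c, d, h, w = xshape
        p = self.p
        dwin = np.zeros((n, c, d // p, h // p, w // p, p ** 3))
        np.put_along_axis(dwin, idx[..., None], dy[..., None], axis=-1)
        dx = dwin.reshape(n, c, d // p, h // p, w // p, p, p, p)
        dx = dx.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(xshape)
        self._cache = None
        return dx


class _Flatten:
    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class _Dense:
    def __init__(self, name: str, n_in: int, n_out: int, rng: np.random.Generator):
        self.name = name
        self.params = {
            f"{name}.weight": rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)),
            f"{name}.bias": np.zeros(n_out),
        }
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params[f"{self.name}.weight"] + self.params[f"{self.name}.bias"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[f"{self.name}.weight"] = self._x.T @ dy
        self.grads[f"{self.name}.bias"] = dy.sum(axis=0)
        dx = dy @ self.params[f"{self.name}.weight"].T
        self._x = None
        return dx


# ---------------------------------------------------------------------------
# model


class Conv3DNet:
    """The classifier, with seeded initialisation and ParameterSet exchange."""

    def __init__(self, cfg: ModelConfig | None = None):
        self.cfg = cfg or ModelConfig()
        rng = np.random.default_rng(np.random.SeedSequence(self.cfg.init_seed))
        c = self.cfg
        chans = (1,) + tuple(c.conv_channels)
        self.layers: list = []
        for i in range(3):
            self.layers += [
                _Conv3D(f"conv{i + 1}", chans[i], chans[i + 1], c.kernel_size, rng),
                _ReLU(),
                _MaxPool3D(c.pool_size),
            ]
        flat = c.conv_channels[-1] * c.final_spatial ** 3
        self.layers += [
            _Flatten(),
            _Dense("fc1", flat, c.fc_hidden, rng),
            _ReLU(),
            _Dense("fc2", c.fc_hidden, c.n_classes, rng),
        ]

    # -- parameter exchange -------------------------------------------------

    def get_parameters(self) -> ParameterSet:
        """Export weights as an ordered ParameterSet of copies (no aliasing)."""
        out = []
        for layer in self.layers:
            for name, arr in layer.params.items():
                out.append((name, arr.copy()))
        return ParameterSet(out)

    def set_parameters(self, ps: ParameterSet) -> None:
        """Import weights; names, order and shapes must match exactly."""
        own = self.get_parameters()
        if ps.names != own.names:
            for got, want in zip(ps.names + ["<missing>"] * 99, own.names + ["<extra>"] * 99):
                if got != want:
                    raise ValueError(f"parameter name mismatch: got {got!r}, expected {want!r}")
        flat = dict(ps.entries)
        for layer in self.layers:
            for name in layer.params:
                if flat[name].shape != layer.params[name].shape:
                    raise ValueError(
                        f"shape mismatch for {name!r}: got {flat[name].shape}, "
                        f"expected {layer.params[name].shape}"
                    )
                layer.params[name] = np.array(flat[name], dtype=np.float64)

    def parameter_count(self) -> int:
        return self.get_parameters().n_parameters()

    def named_parameters(self) -> dict[str, np.ndarray]:
        """Live (aliased) views of the weights, for optimiser updates."""
        out = {}
        for layer in self.layers:
            out.update(layer.params)
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for layer in self.layers:
            out.update(layer.grads)
        return out

    # -- forward / backward --------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        s = self.cfg.input_size
        if x.ndim != 4 or x.shape[1:] != (s, s, s):
            raise ValueError(f"expected patches of shape ({s},{s},{s}), got {x.shape[1:]}")
        return x[:, None]  # add channel axis

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self._check_input(x)
        for layer in self.layers:
            h = layer.forward(h, train)
        return h

    def predict_proba(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Class probabilities, evaluation mode; batch-size invariant."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        outs = [softmax(self.forward(x[i : i + batch_size])) for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def loss_and_backward(
        self, x: np.ndarray, y: np.ndarray, class_weights: np.ndarray | None = None
    ) -> float:
        """Mean cross-entropy on a batch; leaves gradients in the layers."""
        y = np.asarray(y, dtype=int)
        logits = self.forward(x, train=True)
        probs = softmax(logits)
        n = len(y)
        w = np.ones(n) if class_weights is None else np.asarray(class_weights)[y]
        wsum = w.sum()
        loss = float(-(w * np.log(probs[np.arange(n), y] + 1e-300)).sum() / wsum)
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits *= (w / wsum)[:, None]
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return loss

    def cross_entropy(self, x: np.ndarray, y: np.ndarray) -> float:
        """Evaluation-mode mean cross-entropy (no gradients)."""
        probs = self.predict_proba(x)
        y = np.asarray(y, dtype=int)
        return float(-np.log(probs[np.arange(len(y)), y] + 1e-300).mean())
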