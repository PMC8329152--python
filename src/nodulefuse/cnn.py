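"""Malignet: a VGG-style 3D CNN for 32×32×16 nodule boxes, in pure NumPy.

Architecture
------------
Five blocks of two 3×3×3 same-padded convolutions (ReLU), widths
(32, 32), (64, 64), (128, 128), (256, 256), (512, 512), with (2,2,2) max
pooling after the first four blocks, so the spatial trace is
32×32×16 → 16×16×8 → 8×8×4 → 4×4×2 → 2×2×1 (final conv stack output
2×2×1×512).  The head is three dense layers of 1024, 64, and 1 neurons;
the scalar output passes through a sigmoid and the 64-unit penultimate
activation is the "deep image feature" vector consumed downstream.
All convolution and dense kernels carry an L2 penalty with factor 0.01.

Implementation
--------------
Convolutions run as im2col + BLAS matrix products, sample by sample to
bound memory; gradients are computed by hand (the input gradient of a
same-padded correlation is a same-padded correlation with spatially
flipped, channel-transposed kernels).  Training uses binary cross-entropy
on logits plus the L2 penalty, optimized with Adam.  Everything is
float32 and fully deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import ConfigurationError, TrainingError

DEEP_FEATURE_LENGTH = 64


@dataclass(frozen=True)
class ArchitectureSpec:
    """Static description of the network; the default is the full model."""

    input_shape: tuple[int, int, int] = (32, 32, 16)
    conv_blocks: tuple[tuple[int, int], ...] = (
        (32, 32),
        (64, 64),
        (128, 128),
        (256, 256),
        (512, 512),
    )
    dense: tuple[int, ...] = (1024, DEEP_FEATURE_LENGTH, 1)
    l2_factor: float = 0.01

    def __post_init__(self) -> None:
        if len(self.dense) < 2 or self.dense[-1] != 1:
            raise ConfigurationError("dense head must end in a single output neuron")
        if self.dense[-2] != DEEP_FEATURE_LENGTH:
            raise ConfigurationError(
                f"penultimate dense width must be {DEEP_FEATURE_LENGTH}"
            )
        n_pools = len(self.conv_blocks) - 1  # pool after all but the last block
        for dim in self.input_shape:
            if dim % (2**n_pools) and dim // (2**n_pools) < 1:
                raise ConfigurationError(
                    f"input dim {dim} not divisible through {n_pools} poolings"
                )

    def scaled(self, divisor: int) -> "ArchitectureSpec":
        """A narrow variant (conv widths and first dense divided) for quick
        experiments; the 64-dim feature layer and scalar output are kept."""
        blocks = tuple(
            (max(c1 // divisor, 1), max(c2 // divisor, 1)) for c1, c2 in self.conv_blocks
        )
        dense = (max(self.dense[0] // divisor, DEEP_FEATURE_LENGTH),) + self.dense[1:]
        return ArchitectureSpec(self.input_shape, blocks, dense, self.l2_factor)

    @property
    def spatial_trace(self) -> list[tuple[int, int, int]]:
        """Spatial shape at the input of each conv block."""
        shapes = [self.input_shape]
        for _ in range(len(self.conv_blocks) - 1):
            shapes.append(tuple(max(s // 2, 1) for s in shapes[-1]))
        return shapes

    def parameter_count(self) -> int:
        total = 0
        cin = 1
        for c1, c2 in self.conv_blocks:
            total += c1 * (cin * 27 + 1) + c2 * (c1 * 27 + 1)
            cin = c2
        flat = int(np.prod(self.spatial_trace[-1])) * self.conv_blocks[-1][1]
        nin = flat
        for nout in self.dense:
            total += nin * nout + nout
            nin = nout
        return total


@dataclass
class TrainConfig:
    """Training hyperparameters (none are stated by the architecture itself;
    these are the package defaults, all exposed)."""

    epochs: int = 5
    batch_size: int = 16
    learning_rate: float = 1e-4
    optimizer_name: str = "adam"
    seed: int = 0
    early_stop_patience: int | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be positive")
        if self.learning_rate < 0:
            raise ConfigurationError("learning_rate must be non-negative")
        if self.optimizer_name != "adam":
            raise ConfigurationError(f"unknown optimizer {self.optimizer_name!r}")


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray) -> np.ndarray:
    """(C, X, Y, Z) -> (X*Y*Z, C*27) patch matrix for a same-padded 3³ kernel."""
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3, 3), axis=(1, 2, 3))  # (C, X, Y, Z, 3,3,3)
    c = x.shape[0]
    return win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(-1, c * 27)


class _Conv3D:
    """3×3×3 same-padded cross-correlation, stride 1."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, l2: float):
        std = np.sqrt(2.0 / (cin * 27))
        self.w = rng.normal(0.0, std, size=(cout, cin * 27)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.cin, self.cout, self.l2 = cin, cout, l2
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    @property
    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        # x: (N, C, X, Y, Z)
        if train:
            self._x = x
        n, _, sx, sy, sz = x.shape
        out = np.empty((n, self.cout, sx, sy, sz), dtype=x.dtype)
        for i in range(n):
            cols = _im2col(x[i])
            out[i] = (cols @ self.w.T + self.b).T.reshape(self.cout, sx, sy, sz)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        n, _, sx, sy, sz = x.shape
        self.gw[...] = 2.0 * self.l2 * self.w
        self.gb[...] = 0.0
        # input gradient kernel: flip spatially, swap in/out channels
        wf = self.w.reshape(self.cout, self.cin, 3, 3, 3)[:, :, ::-1, ::-1, ::-1]
        wback = np.ascontiguousarray(wf.transpose(1, 0, 2, 3, 4)).reshape(
            self.cin, self.cout * 27
        )
        dx = np.empty_like(x)
        for i in range(n):
            dmat = dout[i].reshape(self.cout, -1).T  # (V, cout)
            cols = _im2col(x[i])
            self.gw += dmat.T @ cols
            self.gb += dmat.sum(axis=0)
            dcols = _im2col(dout[i])
            dx[i] = (dcols @ wback.T).T.reshape(self.cin, sx, sy, sz)
        self._x = None
        return dx

    def l2_penalty(self) -> float:
        return float(self.l2 * np.sum(self.w.astype(np.float64) ** 2))


class _ReLU:
    params: list = []

    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout):
        return dout * self._mask

    def l2_penalty(self):
        return 0.0


class _MaxPool3D:
    """(2,2,2) max pooling, stride 2."""

    params: list = []

    def forward(self, x, train):
        n, c, sx, sy, sz = x.shape
        r = x.reshape(n, c, sx // 2, 2, sy // 2, 2, sz // 2, 2)
        r = r.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            n, c, sx // 2, sy // 2, sz // 2, 8
        )
        idx = r.argmax(axis=-1)
        if train:
            self._idx, self._inshape = idx, x.shape
        return np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, sx, sy, sz = self._inshape
        scat = np.zeros((n, c, sx // 2, sy // 2, sz // 2, 8), dtype=dout.dtype)
        np.put_along_axis(scat, self._idx[..., None], dout[..., None], axis=-1)
        scat = scat.reshape(n, c, sx // 2, sy // 2, sz // 2, 2, 2, 2)
        return scat.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, sx, sy, sz)

    def l2_penalty(self):
        return 0.0


class _Flatten:
    params: list = []

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def l2_penalty(self):
        return 0.0


class _Dense:
    def __init__(self, nin: int, nout: int, rng: np.random.Generator, l2: float,
                 relu_fan: bool = True):
        std = np.sqrt((2.0 if relu_fan else 1.0) / nin)
        self.w = rng.normal(0.0, std, size=(nin, nout)).astype(np.float32)
        self.b = np.zeros(nout, dtype=np.float32)
        self.l2 = l2
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    @property
    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.gw[...] = self._x.T @ dout + 2.0 * self.l2 * self.w
        self.gb[...] = dout.sum(axis=0)
        dx = dout @ self.w.T
        self._x = None
        return dx

    def l2_penalty(self):
        return float(self.l2 * np.sum(self.w.astype(np.float64) ** 2))


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class MaligNet:
    """The assembled network; see the module docstring for the trace."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers: list = []
        cin = 1
        for bi, (c1, c2) in enumerate(spec.conv_blocks):
            layers += [_Conv3D(cin, c1, rng, spec.l2_factor), _ReLU(),
                       _Conv3D(c1, c2, rng, spec.l2_factor), _ReLU()]
            if bi < len(spec.conv_blocks) - 1:
                layers.append(_MaxPool3D())
            cin = c2
        layers.append(_Flatten())
        flat = int(np.prod(spec.spatial_trace[-1])) * spec.conv_blocks[-1][1]
        nin = flat
        for nout in spec.dense[:-1]:
            layers += [_Dense(nin, nout, rng, spec.l2_factor), _ReLU()]
            nin = nout
        layers.append(_Dense(nin, 1, rng, spec.l2_factor, relu_fan=False))
        self.layers = layers
        self._feature_layer = len(layers) - 2  # ReLU after the 64-unit dense

    # -- plumbing ----------------------------------------------------------
    @property
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def parameter_count(self) -> int:
        return int(sum(p.size for p, _ in self.params))

    def _check_input(self, boxes: np.ndarray) -> np.ndarray:
        boxes = np.asarray(boxes, dtype=np.float32)
        if boxes.ndim == 3:
            boxes = boxes[None]
        if boxes.ndim != 4 or boxes.shape[1:] != tuple(self.spec.input_shape):
            raise ConfigurationError(
                f"boxes must be (n, {self.spec.input_shape}), got {boxes.shape}"
            )
        return boxes[:, None]  # add channel axis

    def _forward(self, x: np.ndarray, train: bool) -> tuple[np.ndarray, np.ndarray]:
        """Returns (logits (n,), penultimate features (n, 64))."""
        feats = None
        for li, layer in enumerate(self.layers):
            x = layer.forward(x, train)
            if li == self._feature_layer:
                feats = x
        return x[:, 0], feats

    def _backward(self, dlogits: np.ndarray) -> None:
        d = dlogits[:, None].astype(np.float32)
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def l2_penalty(self) -> float:
        return float(sum(layer.l2_penalty() for layer in self.layers))

    # -- inference ---------------------------------------------------------
    def predict_scores(self, boxes: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Sigmoid malignancy-suspicion score in [0, 1] per box."""
        x = self._check_input(boxes)
        out = np.empty(len(x), dtype=np.float32)
        for lo in range(0, len(x), batch_size):
            logits, _ = self._forward(x[lo:lo + batch_size], train=False)
            out[lo:lo + batch_size] = 1.0 / (1.0 + np.exp(-logits))
        return out

    def extract_features(self, boxes: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """The 64-dim penultimate-layer deep feature vector per box."""
        x = self._check_input(boxes)
        out = np.empty((len(x), self.spec.dense[-2]), dtype=np.float32)
        for lo in range(0, len(x), batch_size):
            _, feats = self._forward(x[lo:lo + batch_size], train=False)
            out[lo:lo + batch_size] = feats
        return out

    # -- serialization -----------------------------------------------------
    def save(self, path_prefix: str) -> None:
        """Write weights (<prefix>.npz) and architecture JSON (<prefix>.json)."""
        os.makedirs(os.path.dirname(path_prefix) or ".", exist_ok=True)
        arrays = {f"p{i}": p for i, (p, _) in enumerate(self.params)}
        np.savez_compressed(path_prefix + ".npz", **arrays)
        with open(path_prefix + ".json", "w") as fh:
            json.dump(asdict(self.spec), fh, indent=2)

    @classmethod
    def load(cls, path_prefix: str) -> "MaligNet":
        with open(path_prefix + ".json") as fh:
            raw = json.load(fh)
        spec = ArchitectureSpec(
            tuple(raw["input_shape"]),
            tuple(tuple(b) for b in raw["conv_blocks"]),
            tuple(raw["dense"]),
            raw["l2_factor"],
        )
        model = cls(spec)
        data = np.load(path_prefix + ".npz")
        for i, (p, _) in enumerate(model.params):
            p[...] = data[f"p{i}"]
        return model


def build_model(spec: ArchitectureSpec | None = None, seed: int = 0) -> MaligNet:
    """Construct a freshly initialized Malignet."""
    return MaligNet(spec or ArchitectureSpec(), seed=seed)


def normalize_boxes(boxes: np.ndarray) -> np.ndarray:
    """Per-box zero-mean / unit-variance intensity normalization."""
    boxes = np.asarray(boxes, dtype=np.float32)
    if boxes.ndim == 3:
        boxes = boxes[None]
    flat = boxes.reshape(len(boxes), -1)
    mean = flat.mean(axis=1, keepdims=True)
    std = flat.std(axis=1, keepdims=True)
    std = np.maximum(std, 1e-6)
    return ((flat - mean) / std).reshape(boxes.shape)


def train(
    model: MaligNet,
    boxes: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig | None = None,
) -> dict:
    """Train in place with BCE + L2 via Adam; returns the loss history.

    ``boxes`` should already be intensity-normalized (see
    :func:`normalize_boxes`).  Raises :class:`TrainingError` on
    single-class labels.
    """
    config = config or TrainConfig()
    labels = np.asarray(labels, dtype=np.float32)
    if len(np.unique(labels)) < 2:
        raise TrainingError("training labels contain a single class")
    x_all = model._check_input(boxes)
    if len(x_all) != len(labels):
        raise TrainingError("boxes/labels length mismatch")
    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.params, config.learning_rate)
    history: dict = {"loss": [], "bce": []}
    best = np.inf
    stale = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(len(x_all))
        losses, bces = [], []
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            xb, yb = x_all[idx], labels[idx]
            logits, _ = model._forward(xb, train=True)
            # numerically stable BCE on logits
            bce = float(
                np.mean(np.maximum(logits, 0) - logits * yb + np.log1p(np.exp(-np.abs(logits))))
            )
            probs = 1.0 / (1.0 + np.exp(-logits))
            model._backward((probs - yb) / len(yb))
            opt.step()
            bces.append(bce)
            losses.append(bce + model.l2_penalty())
        history["bce"].append(float(np.mean(bces)))
        history["loss"].append(float(np.mean(losses)))
        if config.early_stop_patience is not None:
            if history["loss"][-1] < best - 1e-6:
                best, stale = history["loss"][-1], 0
            else:
                stale += 1
                if stale > config.early_stop_patience:
                    break
    return history


def predict_scores(model: MaligNet, boxes: np.ndarray) -> np.ndarray:
    return model.predict_scores(boxes)


def extract_features(model: MaligNet, boxes: np.ndarray) -> np.ndarray:
    return model.extract_features(boxes)
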