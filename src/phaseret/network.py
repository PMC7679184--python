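"""PhaseNet: a compact 3D CNN that regresses Zernike amplitudes from a PSF.

The architecture is five stacked blocks, each two 3x3x3 convolutions
(stride 1, zero "same" padding, channels doubling per block starting at the
base width) followed by a factor-2 max-pool, then two dense layers of 64
units and a linear output layer with one neuron per Zernike amplitude.
Hidden activations are tanh. For a 32x32x32 input with 11 outputs this
totals ~0.9 million trainable parameters.

The network is implemented directly on NumPy: im2col convolutions,
hand-written backpropagation and an Adam optimizer, all in float32. That
keeps the package dependency-light and the arithmetic fully inspectable;
at the stack sizes used here a CPU forward pass takes milliseconds.

Pooling axes are configurable per block. By default each block pools every
axis whose current extent is even, which for a cubic power-of-two input pools
all three axes in every block and reproduces the reference parameter count;
see the methods note for the trade-offs around lateral-only pooling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .config import MicroscopeConfig
from .psf import PSFStack, standardize
from .zernike import AmplitudeVector, DEFAULT_INDEX_LIST

__all__ = ["ModelSpec", "PhaseNet", "build_model", "train", "predict"]

_AXIS_NAMES = ("z", "y", "x")


def auto_pool_schedule(
    input_shape: Sequence[int], blocks: int
) -> tuple[tuple[str, ...], ...]:
    """Pool every axis whose extent is still even, block by block."""
    sizes = list(input_shape)
    schedule = []
    for _ in range(blocks):
        axes = []
        for ax in range(3):
            if sizes[ax] > 1 and sizes[ax] % 2 == 0:
                axes.append(_AXIS_NAMES[ax])
                sizes[ax] //= 2
        schedule.append(tuple(axes))
    return tuple(schedule)


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters.

    ``pool_schedule`` is one tuple of axis names per block (subset of
    ``("z", "y", "x")``); ``None`` selects the automatic schedule above.
    """

    input_shape: tuple[int, int, int]
    n_outputs: int = len(DEFAULT_INDEX_LIST)
    blocks: int = 5
    convs_per_block: int = 2
    kernel: int = 3
    base_channels: int = 8
    dense_widths: tuple[int, ...] = (64, 64)
    pool_schedule: tuple[tuple[str, ...], ...] | None = None
    index_list: tuple[int, ...] = DEFAULT_INDEX_LIST

    def __post_init__(self):
        object.__setattr__(self, "input_shape", tuple(int(s) for s in self.input_shape))
        if len(self.input_shape) != 3:
            raise ValueError("input_shape must be (nz, ny, nx)")
        if self.n_outputs < 1:
            raise ValueError("need at least one output")
        if len(self.index_list) != self.n_outputs:
            raise ValueError("index_list length must equal n_outputs")
        schedule = (
            self.pool_schedule
            if self.pool_schedule is not None
            else auto_pool_schedule(self.input_shape, self.blocks)
        )
        if len(schedule) != self.blocks:
            raise ValueError("pool_schedule must list axes for every block")
        object.__setattr__(
            self, "pool_schedule", tuple(tuple(a) for a in schedule)
        )
        # divisibility contract: pooling must divide the spatial extent
        sizes = list(self.input_shape)
        for b, axes in enumerate(self.pool_schedule):
            for name in axes:
                ax = _AXIS_NAMES.index(name)
                if sizes[ax] % 2:
                    raise ValueError(
                        f"axis {name!r} has extent {sizes[ax]} at block {b}, "
                        "not divisible by the pooling factor 2"
                    )
                sizes[ax] //= 2

    @property
    def final_spatial(self) -> tuple[int, int, int]:
        sizes = list(self.input_shape)
        for axes in self.pool_schedule:
            for name in axes:
                sizes[_AXIS_NAMES.index(name)] //= 2
        return tuple(sizes)

    def channel_widths(self) -> list[int]:
        return [self.base_channels * 2**b for b in range(self.blocks)]


# ---------------------------------------------------------------------------
# layers


class _Conv3d:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in, fan_out = c_in * k**3, c_out * k**3
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.w = rng.uniform(-limit, limit, (c_out, c_in * k**3)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k,) * 3, axis=(2, 3, 4))
        bsz, c = x.shape[:2]
        # (B, C, D, H, W, k, k, k) -> (B, D*H*W, C*k^3)
        win = win.transpose(0, 2, 3, 4, 1, 5, 6, 7)
        return win.reshape(bsz, -1, c * self.k**3)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        cols = self._im2col(x)
        if train:
            self._cols = cols
        y = cols @ self.w.T + self.b
        bsz, _, d, h, w = x.shape
        return y.transpose(0, 2, 1).reshape(bsz, self.c_out, d, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        bsz, _, d, h, w = dy.shape
        dyf = dy.reshape(bsz, self.c_out, -1).transpose(0, 2, 1)  # (B, P, Cout)
        self.grads[0][...] = np.einsum("bpo,bpi->oi", dyf, self._cols)
        self.grads[1][...] = dyf.sum(axis=(0, 1))
        self._cols = None
        # gradient w.r.t. input: convolution with spatially flipped,
        # channel-transposed kernels (stride 1, same padding)
        w_rot = (
            self.w.reshape(self.c_out, self.c_in, self.k, self.k, self.k)[
                :, :, ::-1, ::-1, ::-1
            ]
            .transpose(1, 0, 2, 3, 4)
            .reshape(self.c_in, self.c_out * self.k**3)
        )
        back = _Conv3d.__new__(_Conv3d)
        back.k = self.k
        cols_dy = back._im2col(dy)
        dx = cols_dy @ w_rot.T
        return dx.transpose(0, 2, 1).reshape(self._shape)


class _Tanh:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.tanh(x)
        if train:
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * (1.0 - self._y**2)
        self._y = None
        return dx


class _MaxPool:
    """Factor-2 max pooling over a configurable subset of spatial axes."""

    params: list = []
    grads: list = []

    def __init__(self, axes: Sequence[str]):
        self.pool = tuple(2 if name in axes else 1 for name in _AXIS_NAMES)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        bsz, c, d, h, w = x.shape
        pz, py, px = self.pool
        xr = x.reshape(bsz, c, d // pz, pz, h // py, py, w // px, px)
        xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            bsz, c, d // pz, h // py, w // px, pz * py * px
        )
        if train:
            self._idx = xr.argmax(axis=-1)
            self._shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        bsz, c, d, h, w = self._shape
        pz, py, px = self.pool
        dxr = np.zeros(dy.shape + (pz * py * px,), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(bsz, c, d // pz, h // py, w // px, pz, py, px)
        dx = dxr.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(bsz, c, d, h, w)
        self._idx = None
        return dx


class _Flatten:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        self._x = None
        return dy @ self.w.T


# ---------------------------------------------------------------------------
# model


class PhaseNet:
    """The regressor: stack of conv blocks + dense head, with training state."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        layers: list = []
        c_in = 1
        for b, c_out in enumerate(spec.channel_widths()):
            for _ in range(spec.convs_per_block):
                layers.append(_Conv3d(c_in, c_out, spec.kernel, rng))
                layers.append(_Tanh())
                c_in = c_out
            if spec.pool_schedule[b]:
                layers.append(_MaxPool(spec.pool_schedule[b]))
        layers.append(_Flatten())
        n_in = c_in * int(np.prod(spec.final_spatial))
        for width in spec.dense_widths:
            layers.append(_Dense(n_in, width, rng))
            layers.append(_Tanh())
            n_in = width
        layers.append(_Dense(n_in, spec.n_outputs, rng))  # linear output
        self.layers = layers
        self.metadata: dict = {"trained_steps": 0}
        self.config: MicroscopeConfig | None = None

    # -- parameters ---------------------------------------------------------

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        """Total trainable parameter count."""
        return sum(p.size for p in self.parameters)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map a (B, nz, ny, nx) batch to (B, n_outputs) amplitudes in um."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != self.spec.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model input "
                f"{self.spec.input_shape}"
            )
        h = x[:, None]  # single input channel
        for layer in self.layers:
            h = layer.forward(h, train)
        return h

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> float:
        """MSE between predicted and true amplitudes (um^2); fills gradients."""
        y = np.asarray(y, dtype=np.float32)
        pred = self.forward(x, train=True)
        diff = pred - y
        loss = float(np.mean(diff**2))
        dy = (2.0 / diff.size) * diff
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return loss

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Weights as .npz plus a JSON sidecar with the spec and metadata."""
        path = Path(path)
        np.savez(path, **{f"p{i}": p for i, p in enumerate(self.parameters)})
        sidecar = {
            "spec": asdict(self.spec),
            "metadata": self.metadata,
            "config": self.config.to_dict() if self.config else None,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "PhaseNet":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        sd = sidecar["spec"]
        for key in ("input_shape", "dense_widths", "index_list"):
            sd[key] = tuple(sd[key])
        sd["pool_schedule"] = tuple(tuple(a) for a in sd["pool_schedule"])
        model = cls(ModelSpec(**sd))
        data = np.load(path if path.suffix == ".npz" else str(path))
        for i, p in enumerate(model.parameters):
            p[...] = data[f"p{i}"]
        model.metadata = sidecar["metadata"]
        if sidecar.get("config"):
            model.config = MicroscopeConfig.from_dict(sidecar["config"])
        return model


def build_model(spec: ModelSpec, seed: int = 0) -> PhaseNet:
    """Instantiate an untrained PhaseNet with seeded Glorot initialization."""
    return PhaseNet(spec, seed=seed)


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def train(
    model: PhaseNet,
    stream: Iterator,
    steps: int = 50_000,
    batch_size: int = 2,
    learning_rate: float = 1e-4,
    log_every: int = 100,
    checkpoint_path: str | Path | None = None,
    progress: Callable[[int, float], None] | None = None,
) -> PhaseNet:
    """Train on a stream of (amplitudes, stack) pairs by Adam on the MSE loss.

    ``stream`` yields objects with ``network_input()`` (standardized stack)
    and ``amplitudes``; see :func:`phaseret.training_data.pair_stream`. The
    reference recipe is 50000 steps at batch size 2 with learning rate 1e-4;
    pass smaller values for the fast CPU-scale variants.
    """
    first = next(stream)
    if first.network_input().shape != model.spec.input_shape:
        raise ValueError(
            f"stream produces stacks of shape {first.network_input().shape}, "
            f"model expects {model.spec.input_shape}"
        )

    def batches():
        pending = [first]
        while True:
            while len(pending) < batch_size:
                pending.append(next(stream))
            x = np.stack([p.network_input() for p in pending])
            y = np.stack([p.amplitudes.values for p in pending])
            pending.clear()
            yield x.astype(np.float32), y.astype(np.float32)

    opt = _Adam(model.parameters, lr=learning_rate)
    history = []
    for step, (x, y) in zip(range(1, steps + 1), batches()):
        loss = model.loss_and_grad(x, y)
        opt.step(model.gradients)
        if step % log_every == 0 or step == steps:
            history.append((step, loss))
            if progress is not None:
                progress(step, loss)
    model.metadata.update(
        trained_steps=model.metadata.get("trained_steps", 0) + steps,
        batch_size=batch_size,
        learning_rate=learning_rate,
        loss_history=history,
    )
    if checkpoint_path is not None:
        model.save(checkpoint_path)
    return model


def predict(
    model: PhaseNet, stacks: PSFStack | np.ndarray | Sequence
) -> AmplitudeVector | list[AmplitudeVector]:
    """Predict Zernike amplitudes for one stack or a batch of stacks.

    Applies the same per-volume standardization used during training, then
    the forward pass. Input shape (and, for :class:`PSFStack` inputs with a
    config-carrying model, voxel sizes) must match the training setup;
    silent resampling is never attempted.
    """
    single = isinstance(stacks, PSFStack) or (
        isinstance(stacks, np.ndarray) and stacks.ndim == 3
    )
    items = [stacks] if single else list(stacks)
    arrays = []
    for s in items:
        if isinstance(s, PSFStack):
            if model.config is not None:
                cfg = model.config
                if (
                    s.config.lateral_voxel != cfg.lateral_voxel
                    or s.config.axial_voxel != cfg.axial_voxel
                ):
                    raise ValueError(
                        "stack voxel sizes differ from the training config; "
                        "resampling is not supported"
                    )
            arrays.append(standardize(s))
        else:
            arrays.append(standardize(np.asarray(s)))
    x = np.stack(arrays)
    if x.shape[1:] != model.spec.input_shape:
        raise ValueError(
            f"stack shape {x.shape[1:]} does not match model input "
            f"{model.spec.input_shape}"
        )
    out = model.forward(x)
    vecs = [AmplitudeVector(row, model.spec.index_list) for row in out]
    return vecs[0] if single else vecs
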