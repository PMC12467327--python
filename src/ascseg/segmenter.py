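"""Pluggable 2-D segmenters and a NumPy reference encoder-decoder.

The recurrent pipeline only requires a *segmenter contract*: a callable
mapping one 2-D intensity grid (non-negative, possibly exceeding 1.0 after
contrast enhancement) to a same-shaped foreground-probability map, with an
exactly known trainable-parameter count.  Any external model satisfying
the contract can be plugged in through the registry.

The reference implementation is the canonical U-Net encoder-decoder —
two 3x3 convolutions + ReLU per level, 2x max-pool downsampling, nearest
upsampling followed by a channel-halving convolution, skip concatenation,
and a final 1x1 convolution to two classes with softmax — written directly
in NumPy with hand-derived backpropagation so the whole pipeline runs and
trains on a plain CPU.  Gradient correctness is verified against finite
differences in the test suite.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "Segmenter",
    "ReferenceUNetConfig",
    "ReferenceUNet",
    "reference_unet",
    "param_count",
    "register_segmenter",
    "get_segmenter_builder",
    "softmax_cross_entropy",
    "analytic_flops_per_slice",
]


# ---------------------------------------------------------------------------
# contract and registry

class Segmenter(ABC):
    """Contract: 2-D image -> same-shape probability map, deterministic in
    evaluation mode, with an exact trainable-parameter count."""

    channel_width: int = 0

    @abstractmethod
    def predict(self, image: np.ndarray) -> np.ndarray:
        """Map (H, W) or (N, H, W) intensities to foreground probabilities."""

    def forward(self, image: np.ndarray) -> np.ndarray:
        return self.predict(image)

    @property
    @abstractmethod
    def trainable_parameter_count(self) -> int:
        ...


def param_count(segmenter: Segmenter) -> int:
    """Exact number of trainable scalars in a segmenter."""
    return int(segmenter.trainable_parameter_count)


_REGISTRY: dict[str, Callable] = {}


def register_segmenter(name: str):
    def deco(builder):
        _REGISTRY[name] = builder
        return builder
    return deco


def get_segmenter_builder(name: str) -> Callable:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown segmenter {name!r}; available: {sorted(_REGISTRY)}") from None


# ---------------------------------------------------------------------------
# numpy layers (stride-1 'same' cross-correlation, odd kernels)

class _Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    N, C, H, W = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(N * H * W, C * kh * kw)


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None):
    """Same-padded stride-1 cross-correlation. Returns (out, cols)."""
    Co, Ci, kh, kw = w.shape
    N, C, H, W = x.shape
    cols = _im2col(x, kh, kw)
    out = cols @ w.reshape(Co, -1).T
    if b is not None:
        out += b
    return out.reshape(N, H, W, Co).transpose(0, 3, 1, 2), cols


class _Conv:
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 dtype=np.float64):
        scale = np.sqrt(2.0 / (cin * k * k))  # He initialization
        self.w = _Param(rng.normal(0.0, scale, size=(cout, cin, k, k)).astype(dtype))
        self.b = _Param(np.zeros(cout, dtype=dtype))
        self._cols = None
        self._xshape = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out, cols = _conv2d(x, self.w.value, self.b.value)
        if train:
            self._cols, self._xshape = cols, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        Co = self.w.value.shape[0]
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, Co)
        self.w.grad += (dflat.T @ self._cols).reshape(self.w.value.shape)
        self.b.grad += dflat.sum(axis=0)
        # input gradient = same-padded correlation with transposed, flipped kernel
        w_rot = self.w.value.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        dx, _ = _conv2d(dout, np.ascontiguousarray(w_rot), None)
        self._cols = None
        return dx

    def params(self):
        return [self.w, self.b]


class _ReLU:
    def forward(self, x, train):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        return dout * self._mask


class _MaxPool2:
    def forward(self, x, train):
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(3, 5))
        if train:
            mask = xr == out[:, :, :, None, :, None]
            # split gradient among ties; deterministic and exact in expectation
            self._mask = mask / mask.sum(axis=(3, 5), keepdims=True)
            self._shape = x.shape
        return out

    def backward(self, dout):
        N, C, H, W = self._shape
        d = self._mask * dout[:, :, :, None, :, None]
        return d.reshape(N, C, H, W)


class _NearestUp2:
    def forward(self, x, train):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        N, C, H, W = dout.shape
        return dout.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


# ---------------------------------------------------------------------------
# reference U-Net

@dataclass(frozen=True)
class ReferenceUNetConfig:
    """Architecture hyperparameters of the reference encoder-decoder.

    ``channel_width`` is B, the feature channels after the first
    convolution; channels double at each of ``depth`` encoder levels.
    Default B=64 matches the complexity-analysis setting; B=8 with 64x64
    inputs is the fast CPU-scale configuration used throughout the tests.
    """

    channel_width: int = 64
    depth: int = 4
    n_classes: int = 2
    in_channels: int = 1
    dtype: str = "float32"  # float64 for numerical-gradient verification

    def __post_init__(self) -> None:
        if self.channel_width < 1 or self.depth < 1:
            raise ValueError("channel_width and depth must be >= 1")
        if self.n_classes < 2:
            raise ValueError("need at least 2 output classes")
        if self.dtype not in ("float32", "float64"):
            raise ValueError(f"unsupported dtype {self.dtype!r}")


class ReferenceUNet(Segmenter):
    """Canonical U-Net in NumPy with hand-written backpropagation."""

    def __init__(self, cfg: ReferenceUNetConfig = ReferenceUNetConfig(), seed: int = 0):
        self.cfg = cfg
        self.channel_width = cfg.channel_width
        self.frozen = False
        self.dtype = np.dtype(cfg.dtype)
        rng = np.random.default_rng(seed)
        B, d = cfg.channel_width, cfg.depth

        def block(cin, cout):
            return [_Conv(cin, cout, 3, rng, self.dtype), _ReLU(),
                    _Conv(cout, cout, 3, rng, self.dtype), _ReLU()]

        self.enc = []
        cin = cfg.in_channels
        for i in range(d):
            cout = B * 2 ** i
            self.enc.append(block(cin, cout))
            cin = cout
        self.pools = [_MaxPool2() for _ in range(d)]
        self.bottleneck = block(cin, B * 2 ** d)
        self.ups = []
        self.upconvs = []
        self.dec = []
        for i in reversed(range(d)):
            cout = B * 2 ** i
            self.ups.append(_NearestUp2())
            self.upconvs.append(_Conv(cout * 2, cout, 3, rng))
            self.dec.append(block(cout * 2, cout))
        self.head = _Conv(B, cfg.n_classes, 1, rng)

    # -- parameter bookkeeping ------------------------------------------
    def _convs(self):
        for blk in self.enc:
            yield blk[0]; yield blk[2]
        yield self.bottleneck[0]; yield self.bottleneck[2]
        for up, blk in zip(self.upconvs, self.dec):
            yield up; yield blk[0]; yield blk[2]
        yield self.head

    def params(self) -> list[_Param]:
        return [p for conv in self._convs() for p in conv.params()]

    @property
    def trainable_parameter_count(self) -> int:
        if self.frozen:
            return 0
        return int(sum(p.value.size for p in self.params()))

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    # -- forward / backward ---------------------------------------------
    @staticmethod
    def _run(layers, x, train):
        for lay in layers:
            x = lay.forward(x, train)
        return x

    def forward_logits(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, H, W) or (H, W) non-negative intensities -> (N, K, H, W) logits.

        H and W must be divisible by 2**depth.
        """
        x = np.asarray(images, dtype=self.dtype)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        N, H, W = x.shape
        f = 2 ** self.cfg.depth
        if H % f or W % f:
            raise ValueError(f"input {H}x{W} not divisible by 2^depth = {f}")
        x = x[:, None]  # (N, 1, H, W)
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = self._run(blk, x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self._run(self.bottleneck, x, train)
        self._skip_channels = []
        for up, upconv, blk, skip in zip(self.ups, self.upconvs, self.dec, reversed(skips)):
            x = up.forward(x, train)
            x = upconv.forward(x, train)
            x = np.concatenate([skip, x], axis=1)
            self._skip_channels.append(skip.shape[1])
            x = self._run(blk, x, train)
        logits = self.head.forward(x, train)
        return logits[0] if squeeze and not train else logits

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        dx = self.head.backward(np.asarray(dlogits, dtype=self.dtype))
        dskips = []
        for blk, upconv, up, nskip in zip(reversed(self.dec), reversed(self.upconvs),
                                          reversed(self.ups),
                                          reversed(self._skip_channels)):
            for lay in reversed(blk):
                dx = lay.backward(dx)
            dskips.append(dx[:, :nskip])
            dx = up.backward(upconv.backward(dx[:, nskip:]))
        for lay in reversed(self.bottleneck):
            dx = lay.backward(dx)
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                    reversed(dskips)):
            dx = pool.backward(dx)
            dx = dx + dskip
            for lay in reversed(blk):
                dx = lay.backward(dx)

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Foreground probability map via softmax over the two classes."""
        arr = np.asarray(image)
        squeeze = arr.ndim == 2
        logits = self.forward_logits(arr if not squeeze else arr[None], train=False)
        prob = _softmax(logits)[:, 1]
        return prob[0] if squeeze else prob

    # -- (de)serialization ----------------------------------------------
    def save_weights(self, path) -> None:
        np.savez(path, *[p.value for p in self.params()])

    def load_weights(self, path) -> None:
        data = np.load(path)
        for p, key in zip(self.params(), data.files):
            p.value[...] = data[key]


@register_segmenter("reference_unet")
def reference_unet(cfg: ReferenceUNetConfig = ReferenceUNetConfig(), seed: int = 0) -> ReferenceUNet:
    """Build a contract-satisfying reference U-Net."""
    return ReferenceUNet(cfg, seed=seed)


# ---------------------------------------------------------------------------
# loss and optimizer

def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean per-pixel two-class cross-entropy.

    Parameters: logits (N, K, H, W); targets (N, H, W) integer class ids.
    Returns (loss, dlogits) with dlogits already averaged over pixels.
    """
    N, K, H, W = logits.shape
    p = _softmax(logits)
    t = np.asarray(targets).astype(np.int64)
    onehot = np.eye(K)[t].transpose(0, 3, 1, 2)
    eps = 1e-12
    loss = float(-(onehot * np.log(p + eps)).sum() / (N * H * W))
    dlogits = (p - onehot) / (N * H * W)
    return loss, dlogits


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[_Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p in self.params:
            p.m = self.b1 * p.m + (1 - self.b1) * p.grad
            p.v = self.b2 * p.v + (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# analytic complexity accounting

def analytic_flops_per_slice(cfg: ReferenceUNetConfig, height: int, width: int) -> int:
    """Analytic FLOPs of one forward pass (1 multiply-accumulate = 2 FLOPs,
    convolutions only) for the reference U-Net at the given resolution."""
    B, d = cfg.channel_width, cfg.depth
    flops = 0
    h, w = height, width
    cin = cfg.in_channels
    for i in range(d):
        cout = B * 2 ** i
        flops += 2 * h * w * 9 * (cin * cout + cout * cout)
        cin = cout
        h, w = h // 2, w // 2
    cbot = B * 2 ** d
    flops += 2 * h * w * 9 * (cin * cbot + cbot * cbot)
    for i in reversed(range(d)):
        cout = B * 2 ** i
        h, w = h * 2, w * 2
        flops += 2 * h * w * 9 * (2 * cout * cout)          # up-convolution
        flops += 2 * h * w * 9 * (2 * cout * cout + cout * cout)  # double conv
    flops += 2 * height * width * B * cfg.n_classes         # 1x1 head
    return int(flops)
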