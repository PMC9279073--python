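"""Channel/spatial attention blocks: Shuffle Attention (SA) and ECA.

SA splits the channel axis into ``G`` groups.  Each group is halved: the first
half passes through a channel gate (global average pooling, a per-channel
affine, sigmoid), the second half through a spatial gate (per-channel group
normalization over spatial positions, per-channel affine, sigmoid).  The gated
halves are concatenated, the groups reassembled, and a channel shuffle mixes
information across groups.  The affine gate parameters are shared across
groups, so SA costs only 4·C/(2G) parameters.

ECA applies a 1-D convolution of adaptive odd size K across the channel axis
of the pooled descriptor, followed by a sigmoid gate.  K grows with log2 of
the channel count: K = nearest odd integer to log2(C)/r + b/r (ties toward
the smaller odd value, floor 1), with r = 2 and b = 1 by default.

Both transforms preserve the (batch, channel, height, width) shape, and every
gate value lies strictly inside (0, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import Module, Parameter


class ConfigurationError(ValueError):
    """Raised when module parameters are inconsistent with the input."""


# ---------------------------------------------------------------------------
# parameter containers (functional API)
# ---------------------------------------------------------------------------

@dataclass
class SAParams:
    """Shuffle-Attention parameters for a fixed channel count C.

    The four gate vectors have length C/(2·groups) and are shared across
    groups.  Zero weights and biases give the neutral gate sigmoid(0) = 0.5.
    """

    groups: int
    channel_gate_weight: np.ndarray
    channel_gate_bias: np.ndarray
    spatial_gate_weight: np.ndarray
    spatial_gate_bias: np.ndarray
    groupnorm_epsilon: float = 1e-5
    shuffle: bool = True

    @classmethod
    def neutral(cls, channels: int, groups: int, shuffle: bool = True) -> "SAParams":
        if channels % (2 * groups):
            raise ConfigurationError(
                f"channel count {channels} not divisible by 2*groups={2 * groups}")
        half = channels // (2 * groups)
        z = np.zeros(half, dtype=np.float32)
        return cls(groups, z.copy(), z.copy(), z.copy(), z.copy(), shuffle=shuffle)


@dataclass
class ECAParams:
    """ECA parameters; ``kernel_size`` is derived from the channel count."""

    r: float = 2.0
    b: float = 1.0
    kernel_size: int = field(default=0)
    conv_weights: np.ndarray | None = None

    @classmethod
    def for_channels(cls, channels: int, r: float = 2.0, b: float = 1.0,
                     conv_weights: np.ndarray | None = None) -> "ECAParams":
        k = eca_kernel_size(channels, r, b)
        if conv_weights is None:
            conv_weights = np.zeros(k, dtype=np.float32)
        conv_weights = np.asarray(conv_weights, dtype=np.float64)
        if conv_weights.shape != (k,):
            raise ConfigurationError(
                f"ECA kernel weights must have shape ({k},), got {conv_weights.shape}")
        return cls(r=r, b=b, kernel_size=k, conv_weights=conv_weights)


def eca_kernel_size(c: int, r: float = 2.0, b: float = 1.0) -> int:
    """Adaptive odd 1-D kernel size: nearest odd to log2(c)/r + b/r.

    Ties (an even target value) round toward the smaller odd integer; the
    result is floored at 1.  Non-decreasing in ``c`` for fixed r, b.
    """
    if c < 1:
        raise ValueError(f"channel count must be >= 1, got {c}")
    if r <= 0:
        raise ValueError(f"r must be positive, got {r}")
    t = (math.log2(c) + b) / r
    lo = int(math.floor(t))
    if lo % 2 == 0:
        lo -= 1
    lo = max(lo, 1)
    hi = lo + 2
    return lo if (t - lo) <= (hi - t) else hi


# ---------------------------------------------------------------------------
# autograd modules
# ---------------------------------------------------------------------------

class ShuffleAttention(Module):
    """SA as a trainable module; gates start neutral (zero affine)."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5,
                 shuffle: bool = True):
        super().__init__()
        if channels % (2 * groups):
            raise ConfigurationError(
                f"SA requires C divisible by 2G (C={channels}, G={groups})")
        self.channels = channels
        self.groups = groups
        self.eps = eps
        self.shuffle = shuffle
        half = channels // (2 * groups)
        self.cweight = Parameter(np.zeros((1, half, 1, 1)))
        self.cbias = Parameter(np.zeros((1, half, 1, 1)))
        self.sweight = Parameter(np.zeros((1, half, 1, 1)))
        self.sbias = Parameter(np.zeros((1, half, 1, 1)))

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.channels:
            raise ConfigurationError(
                f"SA built for C={self.channels}, got C={c}")
        g = self.groups
        half = c // (2 * g)
        xg = ag.reshape(x, (n * g, c // g, h, w))
        x1 = xg[:, :half]
        x2 = xg[:, half:]
        # channel gate: GAP -> affine -> sigmoid
        s = ag.mean(x1, axis=(2, 3), keepdims=True)
        x1o = x1 * ag.sigmoid(s * self.cweight + self.cbias)
        # spatial gate: per-channel GN over (H, W) -> affine -> sigmoid
        gn = ag.instancenorm(x2, self.eps)
        x2o = x2 * ag.sigmoid(gn * self.sweight + self.sbias)
        out = ag.concat([x1o, x2o], axis=1)
        out = ag.reshape(out, (n, c, h, w))
        if self.shuffle:
            out = channel_shuffle(out, 2)
        return out


def channel_shuffle(x: Tensor, groups: int) -> Tensor:
    """Interleave channel blocks (transpose of the grouped channel axis)."""
    n, c, h, w = x.shape
    x = ag.reshape(x, (n, groups, c // groups, h, w))
    x = ag.transpose(x, (0, 2, 1, 3, 4))
    return ag.reshape(x, (n, c, h, w))


class ECA(Module):
    """Efficient Channel Attention with adaptive 1-D kernel.

    The convolution weights start at zero so the gate begins at the neutral
    value 0.5; the gradient through the pooled descriptor is nonzero, so the
    kernel trains away from zero immediately.
    """

    def __init__(self, channels: int, r: float = 2.0, b: float = 1.0):
        super().__init__()
        self.channels = channels
        self.r = r
        self.b = b
        self.kernel_size = eca_kernel_size(channels, r, b)
        self.weight = Parameter(np.zeros(self.kernel_size))

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.channels:
            raise ConfigurationError(f"ECA built for C={self.channels}, got C={c}")
        k = self.kernel_size
        s = ag.mean(x, axis=(2, 3))  # (N, C)
        p = k // 2
        sp = ag.pad(s, ((0, 0), (p, p))) if p else s
        acc = None
        for j in range(k):
            term = self.weight[j] * sp[:, j:j + c]
            acc = term if acc is None else acc + term
        gate = ag.reshape(ag.sigmoid(acc), (n, c, 1, 1))
        return x * gate


# ---------------------------------------------------------------------------
# functional API on plain arrays
# ---------------------------------------------------------------------------

def global_avg_pool(x: np.ndarray) -> np.ndarray:
    """Spatial mean per channel; (N, C, H, W) -> (N, C)."""
    x = np.asarray(x)
    if x.ndim != 4:
        raise ValueError(f"expected a 4-D (N, C, H, W) array, got ndim={x.ndim}")
    return x.mean(axis=(2, 3))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _check_gate(name: str, vec: np.ndarray, channels: int) -> np.ndarray:
    vec = np.asarray(vec, dtype=np.float64).reshape(-1)
    if vec.shape != (channels,):
        raise ConfigurationError(
            f"{name} has length {vec.size}, expected {channels}")
    return vec


def channel_attention_branch(x_half: np.ndarray, w1, b1) -> np.ndarray:
    """sigmoid(w1 * GAP(x) + b1) applied multiplicatively per channel."""
    x_half = np.asarray(x_half, dtype=np.float64)
    c = x_half.shape[1]
    w1 = _check_gate("w1", w1, c)
    b1 = _check_gate("b1", b1, c)
    s = global_avg_pool(x_half)  # (N, C)
    gate = _sigmoid(w1 * s + b1)[:, :, None, None]
    return x_half * gate


def spatial_attention_branch(x_half: np.ndarray, w2, b2,
                             eps: float = 1e-5) -> np.ndarray:
    """sigmoid(w2 * GN(x) + b2) applied elementwise.

    GN normalizes each channel of the half-group to zero mean / unit variance
    over its spatial positions (biased variance, stabilized by ``eps``).
    """
    x_half = np.asarray(x_half, dtype=np.float64)
    c = x_half.shape[1]
    w2 = _check_gate("w2", w2, c)
    b2 = _check_gate("b2", b2, c)
    mu = x_half.mean(axis=(2, 3), keepdims=True)
    var = x_half.var(axis=(2, 3), keepdims=True)
    gn = (x_half - mu) / np.sqrt(var + eps)
    gate = _sigmoid(w2[None, :, None, None] * gn + b2[None, :, None, None])
    return x_half * gate


def shuffle_attention(x: np.ndarray, p: SAParams) -> np.ndarray:
    """Full SA transform of a (N, C, H, W) array under fixed parameters."""
    x = np.asarray(x, dtype=np.float64)
    n, c, h, w = x.shape
    g = p.groups
    if c % (2 * g):
        raise ConfigurationError(
            f"channel count C={c} not divisible by 2*G={2 * g}")
    half = c // (2 * g)
    xg = x.reshape(n * g, c // g, h, w)
    x1 = channel_attention_branch(xg[:, :half], p.channel_gate_weight,
                                  p.channel_gate_bias)
    x2 = spatial_attention_branch(xg[:, half:], p.spatial_gate_weight,
                                  p.spatial_gate_bias, p.groupnorm_epsilon)
    out = np.concatenate([x1, x2], axis=1).reshape(n, c, h, w)
    if p.shuffle:
        out = out.reshape(n, 2, c // 2, h, w).transpose(0, 2, 1, 3, 4)
        out = out.reshape(n, c, h, w)
    return out


def eca(x: np.ndarray, p: ECAParams) -> np.ndarray:
    """ECA transform of a (N, C, H, W) array under fixed parameters."""
    x = np.asarray(x, dtype=np.float64)
    n, c, h, w = x.shape
    k = p.kernel_size
    expected = eca_kernel_size(c, p.r, p.b)
    if k != expected:
        raise ConfigurationError(
            f"kernel_size {k} inconsistent with C={c} (expected {expected})")
    weights = np.asarray(p.conv_weights, dtype=np.float64)
    if weights.shape != (k,):
        raise ConfigurationError(
            f"conv_weights shape {weights.shape} != ({k},)")
    s = global_avg_pool(x)  # (N, C)
    pad = k // 2
    sp = np.pad(s, ((0, 0), (pad, pad)))
    z = np.zeros_like(s)
    for j in range(k):
        z += weights[j] * sp[:, j:j + c]
    gate = _sigmoid(z)[:, :, None, None]
    return x * gate
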