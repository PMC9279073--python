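"""Independent scalar-loop reference implementations used by the tests.

Everything here is written with explicit Python loops over array indices and
math.* scalar functions, deliberately sharing no code with the package's
vectorized implementations.
"""

import math

import numpy as np


def sigmoid_scalar(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def gap_oracle(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    out = np.zeros((n, c))
    for ni in range(n):
        for ci in range(c):
            s = 0.0
            for i in range(h):
                for j in range(w):
                    s += x[ni, ci, i, j]
            out[ni, ci] = s / (h * w)
    return out


def channel_branch_oracle(x, w1, b1):
    n, c, h, w = x.shape
    out = np.zeros_like(x, dtype=float)
    s = gap_oracle(x)
    for ni in range(n):
        for ci in range(c):
            gate = sigmoid_scalar(w1[ci] * s[ni, ci] + b1[ci])
            for i in range(h):
                for j in range(w):
                    out[ni, ci, i, j] = gate * x[ni, ci, i, j]
    return out


def spatial_branch_oracle(x, w2, b2, eps=1e-5):
    n, c, h, w = x.shape
    out = np.zeros_like(x, dtype=float)
    for ni in range(n):
        for ci in range(c):
            vals = [x[ni, ci, i, j] for i in range(h) for j in range(w)]
            mu = sum(vals) / len(vals)
            var = sum((v - mu) ** 2 for v in vals) / len(vals)
            for i in range(h):
                for j in range(w):
                    gn = (x[ni, ci, i, j] - mu) / math.sqrt(var + eps)
                    gate = sigmoid_scalar(w2[ci] * gn + b2[ci])
                    out[ni, ci, i, j] = gate * x[ni, ci, i, j]
    return out


def shuffle_attention_oracle(x, groups, w1, b1, w2, b2, eps=1e-5,
                             shuffle=True):
    n, c, h, w = x.shape
    half = c // (2 * groups)
    gated = np.zeros_like(x, dtype=float)
    for g in range(groups):
        base = g * (c // groups)
        x1 = x[:, base:base + half]
        x2 = x[:, base + half:base + 2 * half]
        gated[:, base:base + half] = channel_branch_oracle(x1, w1, b1)
        gated[:, base + half:base + 2 * half] = spatial_branch_oracle(
            x2, w2, b2, eps)
    if not shuffle:
        return gated
    # channel shuffle with 2 blocks: out channel i*2+j <- in channel j*(c//2)+i
    out = np.zeros_like(gated)
    c2 = c // 2
    for j in range(2):
        for i in range(c2):
            out[:, i * 2 + j] = gated[:, j * c2 + i]
    return out


def eca_kernel_size_oracle(c, r=2.0, b=1.0):
    t = math.log2(c) / r + b / r
    best, best_d = None, None
    k = 1
    while k <= max(3, int(t) + 3):
        d = abs(t - k)
        if best is None or d < best_d - 1e-12:
            best, best_d = k, d
        k += 2
    return best


def eca_oracle(x, weights):
    n, c, h, w = x.shape
    k = len(weights)
    pad = k // 2
    s = gap_oracle(x)
    out = np.zeros_like(x, dtype=float)
    for ni in range(n):
        for ci in range(c):
            z = 0.0
            for t in range(k):
                src = ci + t - pad
                if 0 <= src < c:
                    z += weights[t] * s[ni, src]
            gate = sigmoid_scalar(z)
            for i in range(h):
                for j in range(w):
                    out[ni, ci, i, j] = gate * x[ni, ci, i, j]
    return out


def conv2d_oracle(x, w, stride=1):
    n, c, h, wd = x.shape
    f, _, k, _ = w.shape
    p = k // 2
    ho = (h + 2 * p - k) // stride + 1
    wo = (wd + 2 * p - k) // stride + 1
    out = np.zeros((n, f, ho, wo))
    for ni in range(n):
        for fi in range(f):
            for oi in range(ho):
                for oj in range(wo):
                    acc = 0.0
                    for ci in range(c):
                        for ki in range(k):
                            for kj in range(k):
                                ii = oi * stride + ki - p
                                jj = oj * stride + kj - p
                                if 0 <= ii < h and 0 <= jj < wd:
                                    acc += w[fi, ci, ki, kj] * x[ni, ci, ii, jj]
                    out[ni, fi, oi, oj] = acc
    return out


def batchnorm_oracle(x, gamma, beta, eps=1e-5):
    """Training-mode BN: biased batch statistics over (N, H, W)."""
    n, c, h, w = x.shape
    out = np.zeros_like(x, dtype=float)
    for ci in range(c):
        vals = [x[ni, ci, i, j] for ni in range(n)
                for i in range(h) for j in range(w)]
        mu = sum(vals) / len(vals)
        var = sum((v - mu) ** 2 for v in vals) / len(vals)
        for ni in range(n):
            for i in range(h):
                for j in range(w):
                    xhat = (x[ni, ci, i, j] - mu) / math.sqrt(var + eps)
                    out[ni, ci, i, j] = gamma[ci] * xhat + beta[ci]
    return out


def block1_oracle(x, conv3_w, bn1_gamma, bn1_beta, conv1_w, bn2_gamma,
                  bn2_beta, eca_weights, eps=1e-5):
    """y = ReLU(x) + ECA(BN(Conv1x1(ReLU(BN(Conv3x3(x))))))."""
    h1 = conv2d_oracle(x, conv3_w)
    h2 = batchnorm_oracle(h1, bn1_gamma, bn1_beta, eps)
    h3 = np.maximum(h2, 0.0)
    h4 = conv2d_oracle(h3, conv1_w)
    h5 = batchnorm_oracle(h4, bn2_gamma, bn2_beta, eps)
    h6 = eca_oracle(h5, eca_weights)
    return np.maximum(x, 0.0) + h6
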