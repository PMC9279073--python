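"""Neural-network layers used by the segmentation backbone.

A deliberately small module system: ``Module`` walks its attributes to find
parameters and buffers, ``Conv2d``/``BatchNorm2d``/``Upsample2d`` wrap the
autograd primitives.  BatchNorm is composed from differentiable reductions so
gradients flow through the batch statistics, matching the reference behaviour
of mainstream frameworks.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    """Trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffer_names", ()):
            yield prefix + name, getattr(self, name)
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def register_buffer(self, name: str, value: np.ndarray):
        if not hasattr(self, "_buffer_names"):
            self._buffer_names: list[str] = []
        self._buffer_names.append(name)
        setattr(self, name, value)

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- flat state dict (checkpointing) -------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{k}": p.data.copy() for k, p in self.named_parameters()}
        state.update({f"buffer:{k}": b.copy() for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        expected = {f"param:{k}" for k in params} | {f"buffer:{k}" for k in buffers}
        if expected != set(state):
            missing = expected - set(state)
            extra = set(state) - expected
            raise ValueError(f"state mismatch: missing={sorted(missing)} "
                             f"unexpected={sorted(extra)}")
        for key, value in state.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                target = params[name]
                if target.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name}")
                target.data = value.astype(np.float32).copy()
            else:
                # buffers are replaced on the owning module
                *path, attr = name.split(".")
                mod: Module = self
                for part in path:
                    mod = getattr(mod, part) if not part.isdigit() else mod[int(part)]
                setattr(mod, attr, value.copy())

    def __call__(self, x):
        return self.forward(x)


class Conv2d(Module):
    """Same-padding convolution, He-normal init, no bias (BN follows)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, size=(out_channels, in_channels, kernel, kernel)))

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, stride=self.stride)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, self.channels, 1, 1)
        if self.training:
            out, mu, var = ag.batchnorm(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.astype(np.float32))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.astype(np.float32))
            return out
        mu = Tensor(self.running_mean.reshape(shape).astype(x.data.dtype))
        var = Tensor(self.running_var.reshape(shape).astype(x.data.dtype))
        xhat = (x - mu) * (var + self.eps) ** -0.5
        gamma = ag.reshape(self.gamma, shape)
        beta = ag.reshape(self.beta, shape)
        return gamma * xhat + beta

    def forward_relu(self, x: Tensor) -> Tensor:
        """BN followed by ReLU; fused in training mode."""
        if self.training:
            out, mu, var = ag.batchnorm_relu(x, self.gamma, self.beta,
                                             self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.astype(np.float32))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.astype(np.float32))
            return out
        return ag.relu(self.forward(x))


class Upsample2d(Module):
    def __init__(self, factor: int, mode: str = "bilinear"):
        super().__init__()
        self.factor = factor
        self.mode = mode

    def forward(self, x: Tensor) -> Tensor:
        return ag.upsample2d(x, self.factor, self.mode)


class Adam:
    """Adam optimizer with externally scheduled learning rate."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
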