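"""Dual-attention multiscale feature-fusion backbone.

The network consumes 64×64 RGB patches and produces a same-size per-pixel
map.  Topology (channels×height×width for the default 64×64 input):

    stem:    input → C_B_R(32,k3,s1) → SA → C_B_R(16,k3,s1)            = F1 (16×64×64)
    branchA: F1 → SA → C_B_R(64,k3,s2)                                 = F4 (64×32×32)
    branchB: F1 → SA → C_B_R(32,k1,s2) → Block1 → C_B_R(64,k1,s2)      = F2 (64×16×16)
    F5:      F2 → ECA → upsample×2                                     = F5 (64×32×32)
    F3:      F2 → Block1 → C_B_R(64,k1,s1) → upsample×2                = F3 (64×32×32)
    fusion:  (F4 + F5) concat F3                                       = F6 (128×32×32)
    head:    F6 → C_B_R(32,k1,s1) → C_B_R(out,k1,s1) → upsample×2      = output

C_B_R is Convolution → BatchNorm → ReLU.  Block1 is the residual unit
y = ReLU(x) + ECA(BN(Conv1×1(ReLU(BN(Conv3×3(x)))))), which preserves shape.

Note on the F3 upsampling factor: the source description of this topology
nominally gives the F3 upsampler a stride of 4, which contradicts the declared
32×32 shape of F3 (its input is 16×16) and would make the fusion concat
impossible.  The declared shapes win: both upsamplers in the fusion stage use
factor 2 (``upsample_erratum`` in NetworkConfig records the choice).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autograd as ag
from .attention import ECA, ConfigurationError, ShuffleAttention
from .autograd import Tensor
from .layers import BatchNorm2d, Conv2d, Module, Upsample2d

CHECKPOINT_FORMAT_VERSION = 1

TAP_NAMES = ("F1", "F2", "F3", "F4", "F5", "F6", "output")


@dataclass
class NetworkConfig:
    """Full wiring description of the backbone.

    ``sa_groups`` gives the SA group count for the three SA sites
    (stem on 32 channels, branch A on 16, branch B on 16).
    """

    input_size: tuple[int, int] = (64, 64)
    input_channels: int = 3
    stem_filters: tuple[int, int] = (32, 16)
    branch_a_filters: int = 64
    branch_b_filters: tuple[int, int] = (32, 64)
    head_filters: tuple[int, int] = (32, 3)
    sa_groups: tuple[int, int, int] = (8, 8, 8)
    sa_shuffle: bool = True
    eca_r: float = 2.0
    eca_b: float = 1.0
    upsample_mode: str = "bilinear"
    # The fusion-stage upsamplers use factor 2 (declared tap shapes), not the
    # nominal stride-4 of the textual description; see the module docstring.
    upsample_erratum: str = "F3 upsampler runs at factor 2, honoring the declared 32x32 shape"

    @property
    def output_channels(self) -> int:
        return self.head_filters[1]

    def validate(self) -> None:
        h, w = self.input_size
        if h % 4 or w % 4:
            raise ConfigurationError(
                f"input size {self.input_size} must be divisible by 4 "
                "(two stride-2 stages)")
        if self.input_channels < 1:
            raise ConfigurationError("input_channels must be >= 1")
        for g, c in zip(self.sa_groups,
                        (self.stem_filters[0], self.stem_filters[1],
                         self.stem_filters[1])):
            if c % (2 * g):
                raise ConfigurationError(
                    f"SA group count {g} does not divide channels {c} by 2G")
        if self.upsample_mode not in ("bilinear", "nearest"):
            raise ConfigurationError(
                f"unknown upsample_mode {self.upsample_mode!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("input_size", "stem_filters", "branch_b_filters",
                    "head_filters", "sa_groups"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown NetworkConfig keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("input_size", "stem_filters", "branch_b_filters",
                    "head_filters", "sa_groups"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class TapRecord:
    name: str
    shape: tuple[int, int, int, int]


class CBR(Module):
    """Convolution → BatchNorm → ReLU."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 stride: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(in_channels, filters, kernel, stride, rng)
        self.bn = BatchNorm2d(filters)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn.forward_relu(self.conv(x))


class Block1(Module):
    """Residual unit with an ECA-gated 3×3 → 1×1 bottleneck path.

    y = ReLU(x) + ECA(BN(Conv1×1(ReLU(BN(Conv3×3(x)))))); channel count and
    spatial size are unchanged.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 eca_r: float = 2.0, eca_b: float = 1.0):
        super().__init__()
        self.conv3 = Conv2d(channels, channels, 3, 1, rng)
        self.bn1 = BatchNorm2d(channels)
        self.conv1 = Conv2d(channels, channels, 1, 1, rng)
        self.bn2 = BatchNorm2d(channels)
        self.eca = ECA(channels, eca_r, eca_b)

    def forward(self, x: Tensor) -> Tensor:
        h = ag.relu(self.bn1(self.conv3(x)))
        h = self.eca(self.bn2(self.conv1(h)))
        return ag.relu(x) + h


class VesselFusionNet(Module):
    """The full backbone with named tap points F1–F6."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        cin = cfg.input_channels
        f_stem1, f_stem2 = cfg.stem_filters
        f_b1, f_b2 = cfg.branch_b_filters
        f_a = cfg.branch_a_filters
        f_h1, f_h2 = cfg.head_filters
        g_stem, g_a, g_b = cfg.sa_groups
        mode = cfg.upsample_mode

        self.stem_cbr1 = CBR(cin, f_stem1, 3, 1, rng)
        self.stem_sa = ShuffleAttention(f_stem1, g_stem, shuffle=cfg.sa_shuffle)
        self.stem_cbr2 = CBR(f_stem1, f_stem2, 3, 1, rng)

        self.a_sa = ShuffleAttention(f_stem2, g_a, shuffle=cfg.sa_shuffle)
        self.a_cbr = CBR(f_stem2, f_a, 3, 2, rng)

        self.b_sa = ShuffleAttention(f_stem2, g_b, shuffle=cfg.sa_shuffle)
        self.b_cbr1 = CBR(f_stem2, f_b1, 1, 2, rng)
        self.b_block = Block1(f_b1, rng, cfg.eca_r, cfg.eca_b)
        self.b_cbr2 = CBR(f_b1, f_b2, 1, 2, rng)

        self.f5_eca = ECA(f_b2, cfg.eca_r, cfg.eca_b)
        self.f5_up = Upsample2d(2, mode)

        self.f3_block = Block1(f_b2, rng, cfg.eca_r, cfg.eca_b)
        self.f3_cbr = CBR(f_b2, f_b2, 1, 1, rng)
        self.f3_up = Upsample2d(2, mode)

        self.head_cbr1 = CBR(f_a + f_b2, f_h1, 1, 1, rng)
        self.head_cbr2 = CBR(f_h1, f_h2, 1, 1, rng)
        self.head_up = Upsample2d(2, mode)

    def forward(self, x: Tensor, record_taps: bool = True):
        x = x if isinstance(x, Tensor) else Tensor(x)
        n, c, h, w = x.shape
        eh, ew = self.cfg.input_size
        if c != self.cfg.input_channels:
            raise ConfigurationError(
                f"expected {self.cfg.input_channels} input channels, got {c}")
        if h % 4 or w % 4:
            raise ConfigurationError(
                f"input spatial size {h}x{w} must be divisible by 4 "
                f"(configured for {eh}x{ew})")

        f1 = self.stem_cbr2(self.stem_sa(self.stem_cbr1(x)))
        f4 = self.a_cbr(self.a_sa(f1))
        f2 = self.b_cbr2(self.b_block(self.b_cbr1(self.b_sa(f1))))
        f5 = self.f5_up(self.f5_eca(f2))
        f3 = self.f3_up(self.f3_cbr(self.f3_block(f2)))
        f6 = ag.concat([f4 + f5, f3], axis=1)
        out = self.head_up(self.head_cbr2(self.head_cbr1(f6)))

        if not record_taps:
            return out, []
        taps = [TapRecord(name, tuple(t.shape)) for name, t in
                (("F1", f1), ("F2", f2), ("F3", f3), ("F4", f4),
                 ("F5", f5), ("F6", f6), ("output", out))]
        return out, taps


def expected_tap_shapes(cfg: NetworkConfig, batch: int = 1) -> dict[str, tuple]:
    """Analytic tap shapes implied by the configuration."""
    h, w = cfg.input_size
    f_stem2 = cfg.stem_filters[1]
    f_a = cfg.branch_a_filters
    f_b2 = cfg.branch_b_filters[1]
    return {
        "F1": (batch, f_stem2, h, w),
        "F2": (batch, f_b2, h // 4, w // 4),
        "F3": (batch, f_b2, h // 2, w // 2),
        "F4": (batch, f_a, h // 2, w // 2),
        "F5": (batch, f_b2, h // 2, w // 2),
        "F6": (batch, f_a + f_b2, h // 2, w // 2),
        "output": (batch, cfg.output_channels, h, w),
    }


def build_network(cfg: NetworkConfig | None = None,
                  seed: int = 0) -> VesselFusionNet:
    """Construct the backbone and verify every declared tap shape.

    A dry forward pass on a zero input checks the computed shape of each tap
    against the analytic declaration; a disagreement raises
    ``ConfigurationError`` naming the offending tap.
    """
    cfg = cfg or NetworkConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    model = VesselFusionNet(cfg, rng)
    model.eval()
    with ag.no_grad():
        probe = np.zeros((1, cfg.input_channels, *cfg.input_size),
                         dtype=np.float32)
        _, taps = model.forward(Tensor(probe))
    expected = expected_tap_shapes(cfg)
    for tap in taps:
        if tuple(tap.shape) != expected[tap.name]:
            raise ConfigurationError(
                f"tap {tap.name}: computed shape {tap.shape} != declared "
                f"{expected[tap.name]}")
    model.train()
    return model


# ---------------------------------------------------------------------------
# checkpoint serialization
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: VesselFusionNet, extra: dict | None = None):
    """Single-file .npz checkpoint carrying weights, buffers and config."""
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": model.cfg.to_dict(),
        "extra": extra or {},
    }
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[VesselFusionNet, dict]:
    """Rebuild the model from a checkpoint; returns (model, extra-metadata)."""
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"].tobytes()).decode())
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"unsupported checkpoint format: {meta.get('format_version')}")
        cfg = NetworkConfig.from_dict(meta["config"])
        model = build_network(cfg, seed=0)
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    model.load_state_dict(state)
    model.eval()
    return model, meta.get("extra", {})
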