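"""HIRD-Net: a hierarchical inception-residual-dense CNN for retinopathy grading.

The network reads a 224×224×3 fundus image and produces class probabilities
over five severity grades (or two screening classes).  Its wiring:

* a hierarchical feature-fusion (HFF) stem: eleven small convolutions whose
  outputs are concatenated across three depth levels, ending in 28×28×128;
* at each of four depths, a squeeze-and-excitation channel attention (SECA)
  block recalibrates channels and feeds both a global-average-pooling (GAP)
  descriptor and the next block;
* three multi-scale inception blocks (1×1 / 3×3 / 5×5 / pooled branches,
  480 channels out), two residual connection blocks (three bottleneck units
  with additive shortcuts, 256 channels out) with 2×2 max-pool downsampling,
  and one dense connection block (six units with growth 64, 864 channels out);
* the four GAP descriptors (128+256+256+864 = 1504 wide) are concatenated,
  dropout-regularized and classified by a softmax head.

Hard-Swish follows every convolution–batch-norm pair outside SECA internals.
All widths scale with ``width_multiplier`` so a topologically identical tiny
model can be trained quickly in tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn.layers import BatchNorm2d, Conv2d, Dense, Dropout, MaxPool2d, Module
from .nn.tensor import Tensor, concat, global_avg_pool, max_pool2d, softmax

__all__ = [
    "HIRDNetConfig",
    "HIRDNet",
    "build_hff_stem",
    "build_hirdnet",
    "seca_block",
    "count_parameters",
    "PRINTED_SHAPES",
]

#: every intermediate spatial/channel shape the architecture pins down for a
#: 224-pixel input, in forward order (H, W, C)
PRINTED_SHAPES = {
    "stem.pool1_concat": (112, 112, 64),
    "stem.layer3_fusion": (112, 112, 96),
    "stem.layers5_7": (56, 56, 96),
    "stem.layer4_fusion": (56, 56, 128),
    "stem.out": (28, 28, 128),
    "inception1": (28, 28, 480),
    "rcb1": (28, 28, 256),
    "pool_rcb1": (14, 14, 256),
    "inception2": (14, 14, 480),
    "rcb2_pooled": (7, 7, 256),
    "inception3": (7, 7, 480),
    "dcb": (7, 7, 864),
}


@dataclass(frozen=True)
class HIRDNetConfig:
    """Pinned channel/stride plan plus the few free knobs of the network."""

    num_classes: int = 5
    input_size: int = 224
    seca_reduction: int = 8
    dropout_rate: float = 0.2
    width_multiplier: float = 1.0
    #: width of the leading 1×1 projection inside each residual bottleneck unit
    rcb_bottleneck: int = 128
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        if self.input_size % 16 != 0 or self.input_size < 32:
            raise ValueError("input_size must be a multiple of 16 and at least 32")
        for c in (128, 256, 864):
            if self.scaled(c) % self.seca_reduction != 0:
                raise ValueError(
                    f"seca_reduction {self.seca_reduction} does not divide the "
                    f"scaled channel width {self.scaled(c)}")

    def scaled(self, channels: int) -> int:
        return max(1, int(round(channels * self.width_multiplier)))

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "HIRDNetConfig":
        return cls(**json.loads(s))


class ConvBN(Module):
    """Convolution → batch norm → (optionally) Hard-Swish."""

    def __init__(self, cin, cout, kernel, stride=1, padding=0, activation=True, rng=None):
        self.conv = Conv2d(cin, cout, kernel, stride, padding, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.activation = activation

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        y = self.bn(self.conv(x), train)
        return y.hard_swish() if self.activation else y


class HFFStem(Module):
    """Hierarchical feature-fusion stem: parallel multi-kernel convolutions
    fused by concatenation at three depth levels (224×224×3 → 28×28×128)."""

    def __init__(self, cfg: HIRDNetConfig, rng: np.random.Generator):
        s = cfg.scaled
        w = s(32)
        self.l1 = ConvBN(3, w, 3, 1, 1, rng=rng)
        self.l2 = ConvBN(3, w, 5, 1, 2, rng=rng)
        self.l3 = ConvBN(3, w, 5, 2, 2, rng=rng)
        self.l4 = ConvBN(3, w, 7, 4, 3, rng=rng)
        self.l5 = ConvBN(3 * w, w, 3, 1, 1, rng=rng)
        self.l6 = ConvBN(3 * w, w, 5, 1, 2, rng=rng)
        self.l7 = ConvBN(3 * w, w, 5, 2, 2, rng=rng)
        self.l8 = ConvBN(4 * w, w, 3, 1, 1, rng=rng)
        self.l9 = ConvBN(4 * w, w, 5, 1, 2, rng=rng)
        self.l10 = ConvBN(4 * w, w, 5, 2, 2, rng=rng)
        self.l11 = ConvBN(4 * w, w, 7, 2, 3, rng=rng)
        self.pool = MaxPool2d(2, 2)

    def __call__(self, x: Tensor, train: bool, shapes: dict | None = None) -> Tensor:
        p1 = self.pool(concat([self.l1(x, train), self.l2(x, train)]))
        _record(shapes, "stem.pool1_concat", p1)
        f3 = concat([p1, self.l3(x, train)])
        _record(shapes, "stem.layer3_fusion", f3)
        p2 = self.pool(concat([self.l5(f3, train), self.l6(f3, train)]))
        mid = concat([p2, self.l7(f3, train)])
        _record(shapes, "stem.layers5_7", mid)
        f4 = concat([mid, self.l4(x, train)])
        _record(shapes, "stem.layer4_fusion", f4)
        p3 = self.pool(concat([self.l8(f4, train), self.l9(f4, train)]))
        out = concat([p3, self.l10(f4, train), self.l11(f4, train)])
        _record(shapes, "stem.out", out)
        return out


class SECABlock(Module):
    """Squeeze-and-excitation channel attention: GAP → FC(C/r) + ReLU →
    FC(C) + sigmoid → channel-wise rescaling of the input."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        if channels % reduction != 0:
            raise ValueError(f"reduction {reduction} must divide channel count {channels}")
        self.fc1 = Dense(channels, channels // reduction, rng=rng)
        self.fc2 = Dense(channels // reduction, channels, rng=rng)
        self.channels = channels

    def attention(self, x: Tensor) -> Tensor:
        z = global_avg_pool(x)
        return self.fc2(self.fc1(z).relu()).sigmoid()

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        w = self.attention(x)
        b, c = w.shape
        return x * w.reshape(b, c, 1, 1)


def seca_block(x: Tensor, block: SECABlock) -> Tensor:
    """Functional form of SECA recalibration."""
    return block(x)


class InceptionBlock(Module):
    """Four parallel branches concatenated on channels (spatial size kept):
    1×1(128); 1×1(128)→3×3(192); 1×1(32)→5×5(96); 3×3 max-pool→1×1(64)."""

    def __init__(self, cin: int, cfg: HIRDNetConfig, rng: np.random.Generator):
        s = cfg.scaled
        self.b1 = ConvBN(cin, s(128), 1, rng=rng)
        self.b2a = ConvBN(cin, s(128), 1, rng=rng)
        self.b2b = ConvBN(s(128), s(192), 3, 1, 1, rng=rng)
        self.b3a = ConvBN(cin, s(32), 1, rng=rng)
        self.b3b = ConvBN(s(32), s(96), 5, 1, 2, rng=rng)
        self.b4 = ConvBN(cin, s(64), 1, rng=rng)
        self.out_channels = s(128) + s(192) + s(96) + s(64)

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        pooled = max_pool2d(x, 3, 1, 1)
        return concat([
            self.b1(x, train),
            self.b2b(self.b2a(x, train), train),
            self.b3b(self.b3a(x, train), train),
            self.b4(pooled, train),
        ])


class ResidualUnit(Module):
    """Bottleneck 1×1 → 3×3(64) → 1×1(256) with an additive shortcut; the
    shortcut is a 1×1 projection when input and output widths differ."""

    def __init__(self, cin: int, cfg: HIRDNetConfig, rng: np.random.Generator):
        s = cfg.scaled
        out = s(256)
        self.reduce = ConvBN(cin, s(cfg.rcb_bottleneck), 1, rng=rng)
        self.spatial = ConvBN(s(cfg.rcb_bottleneck), s(64), 3, 1, 1, rng=rng)
        self.expand = ConvBN(s(64), out, 1, rng=rng)
        self.project = ConvBN(cin, out, 1, activation=False, rng=rng) if cin != out else None

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        branch = self.expand(self.spatial(self.reduce(x, train), train), train)
        shortcut = self.project(x, train) if self.project is not None else x
        return branch + shortcut


class ResidualBlock(Module):
    """Three stacked bottleneck units; output width 256."""

    def __init__(self, cin: int, cfg: HIRDNetConfig, rng: np.random.Generator):
        out = cfg.scaled(256)
        self.units = [ResidualUnit(cin, cfg, rng),
                      ResidualUnit(out, cfg, rng),
                      ResidualUnit(out, cfg, rng)]
        self.out_channels = out

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        for unit in self.units:
            x = unit(x, train)
        return x


class DenseUnit(Module):
    """Pre-activation dense unit: BN → Hard-Swish → 1×1(256) → BN →
    Hard-Swish → 3×3(64)."""

    def __init__(self, cin: int, cfg: HIRDNetConfig, rng: np.random.Generator):
        s = cfg.scaled
        self.bn1 = BatchNorm2d(cin)
        self.conv1 = Conv2d(cin, s(256), 1, rng=rng)
        self.bn2 = BatchNorm2d(s(256))
        self.conv2 = Conv2d(s(256), s(64), 3, 1, 1, rng=rng)

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        y = self.conv1(self.bn1(x, train).hard_swish())
        return self.conv2(self.bn2(y, train).hard_swish())


class DenseBlock(Module):
    """Six densely connected units; each consumes the concatenation of the
    block input and all previous unit outputs and emits 64 channels, so the
    output width is C_in + 6·64."""

    def __init__(self, cin: int, cfg: HIRDNetConfig, rng: np.random.Generator, n_units: int = 6):
        growth = cfg.scaled(64)
        self.units = [DenseUnit(cin + i * growth, cfg, rng) for i in range(n_units)]
        self.out_channels = cin + n_units * growth

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        feats = [x]
        for unit in self.units:
            feats.append(unit(concat(feats) if len(feats) > 1 else feats[0], train))
        return concat(feats)


class HIRDNet(Module):
    """The full wired network; see the module docstring for the topology."""

    def __init__(self, cfg: HIRDNetConfig):
        rng = np.random.default_rng(cfg.seed)
        s = cfg.scaled
        self.cfg = cfg
        self.stem = HFFStem(cfg, rng)
        self.seca1 = SECABlock(4 * s(32), cfg.seca_reduction, rng)
        self.inc1 = InceptionBlock(4 * s(32), cfg, rng)
        self.rcb1 = ResidualBlock(self.inc1.out_channels, cfg, rng)
        self.seca2 = SECABlock(s(256), cfg.seca_reduction, rng)
        self.inc2 = InceptionBlock(s(256), cfg, rng)
        self.rcb2 = ResidualBlock(self.inc2.out_channels, cfg, rng)
        self.seca3 = SECABlock(s(256), cfg.seca_reduction, rng)
        self.inc3 = InceptionBlock(s(256), cfg, rng)
        self.dcb = DenseBlock(self.inc3.out_channels, cfg, rng)
        self.seca4 = SECABlock(self.dcb.out_channels, cfg.seca_reduction, rng)
        self.pool = MaxPool2d(2, 2)
        self.dropout = Dropout(cfg.dropout_rate)
        self.descriptor_width = 4 * s(32) + 2 * s(256) + self.dcb.out_channels
        self.head = Dense(self.descriptor_width, cfg.num_classes, rng=rng)
        self._dropout_rng = np.random.default_rng(cfg.seed + 1)
        self.last_shapes: dict[str, tuple[int, int, int]] = {}
        self.cam_features: Tensor | None = None
        self.last_logits: Tensor | None = None

    def reseed_dropout(self, seed: int) -> None:
        self._dropout_rng = np.random.default_rng(seed)

    def __call__(self, x, train: bool = False) -> Tensor:
        """Forward pass (B,H,W,3) or (B,3,H,W) float input in [0,1] → (B, num_classes) probabilities."""
        if not isinstance(x, Tensor):
            x = np.asarray(x, dtype=np.float32)
            if x.ndim == 4 and x.shape[-1] == 3:
                x = x.transpose(0, 3, 1, 2)
            x = Tensor(x)
        shapes = self.last_shapes = {}
        h = self.stem(x, train, shapes)
        h = self.seca1(h)
        d1 = global_avg_pool(h)
        h = self.inc1(h, train)
        _record(shapes, "inception1", h)
        h = self.rcb1(h, train)
        _record(shapes, "rcb1", h)
        h = self.pool(h)
        _record(shapes, "pool_rcb1", h)
        h = self.seca2(h)
        d2 = global_avg_pool(h)
        h = self.inc2(h, train)
        _record(shapes, "inception2", h)
        h = self.pool(self.rcb2(h, train))
        _record(shapes, "rcb2_pooled", h)
        h = self.seca3(h)
        d3 = global_avg_pool(h)
        h = self.inc3(h, train)
        _record(shapes, "inception3", h)
        h = self.dcb(h, train)
        _record(shapes, "dcb", h)
        self.cam_features = h
        h = self.seca4(h)
        d4 = global_avg_pool(h)
        desc = concat([d1, d2, d3, d4], axis=1)
        desc = self.dropout(desc, train, self._dropout_rng)
        self.last_logits = self.head(desc)
        return softmax(self.last_logits, axis=1)

    def shape_ledger(self, batch: int = 1) -> dict[str, tuple[int, int, int]]:
        """Run a forward pass on random input and report every recorded
        intermediate shape as (H, W, C)."""
        rng = np.random.default_rng(0)
        x = rng.random((batch, 3, self.cfg.input_size, self.cfg.input_size), dtype=np.float32)
        self(Tensor(x), train=False)
        return dict(self.last_shapes)


def _record(shapes: dict | None, name: str, t: Tensor) -> None:
    if shapes is not None:
        b, c, h, w = t.shape
        shapes[name] = (h, w, c)


def build_hff_stem(cfg: HIRDNetConfig) -> HFFStem:
    return HFFStem(cfg, np.random.default_rng(cfg.seed))


def build_hirdnet(cfg: HIRDNetConfig = HIRDNetConfig()) -> HIRDNet:
    return HIRDNet(cfg)


def count_parameters(model: Module) -> int:
    """Total number of trainable scalars (conv/FC weights, biases, and
    batch-norm affine terms)."""
    return model.num_parameters()
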