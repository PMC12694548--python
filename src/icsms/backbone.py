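"""MobileNetV3-Small backbone with pluggable per-bottleneck attention.

The network is the stock small mobile architecture: a stride-2 stem, eleven
inverted-residual bottlenecks ("expand 1x1 -> depthwise kxk -> attention ->
project 1x1", residual added when stride is 1 and channel widths match), a
1x1 head convolution to 576 channels, global average pooling, and a
1024-hidden classifier.  Input images are 224x224x3 in the study setting,
but any spatial size whose five stride-2 stages stay non-degenerate works
(the tests train at reduced resolution).

The eleven bottleneck rows are data (`MOBILENET_V3_SMALL_ROWS`), not logic,
so variant builders can rewrite the attention column wholesale.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .attention import AttentionKind, build_attention
from .nn import core
from .nn.core import Tensor
from .nn.layers import (ConvBNAct, Dropout, GlobalAvgPool, HardSwish,
                        Identity, Linear, Module, ReLU)

# re-exported activation closed forms (piecewise-linear mobile-net family)
hard_swish = core.hard_swish
hard_sigmoid = core.hard_sigmoid


@dataclasses.dataclass(frozen=True)
class BottleneckSpec:
    """One inverted-residual stage row."""

    in_channels: int
    expand_channels: int
    out_channels: int
    kernel: int            # 3 or 5
    stride: int            # 1 or 2
    attention: AttentionKind
    activation: str        # "relu" or "hard-swish"

    def __post_init__(self):
        if self.kernel not in (3, 5):
            raise ValueError(f"invalid kernel {self.kernel} in {self}")
        if self.stride not in (1, 2):
            raise ValueError(f"invalid stride {self.stride} in {self}")
        if min(self.in_channels, self.expand_channels, self.out_channels) <= 0:
            raise ValueError(f"non-positive channel count in {self}")

    @property
    def has_residual(self) -> bool:
        return self.stride == 1 and self.in_channels == self.out_channels


def _row(cin, exp, cout, k, s, att, act) -> BottleneckSpec:
    return BottleneckSpec(cin, exp, cout, k, s, AttentionKind(att), act)


# canonical MobileNetV3-Small stage table (kernel, expand, out, SE, act, stride)
MOBILENET_V3_SMALL_ROWS: tuple[BottleneckSpec, ...] = (
    _row(16, 16, 16, 3, 2, "SE", "relu"),
    _row(16, 72, 24, 3, 2, "none", "relu"),
    _row(24, 88, 24, 3, 1, "none", "relu"),
    _row(24, 96, 40, 5, 2, "SE", "hard-swish"),
    _row(40, 240, 40, 5, 1, "SE", "hard-swish"),
    _row(40, 240, 40, 5, 1, "SE", "hard-swish"),
    _row(40, 120, 48, 5, 1, "SE", "hard-swish"),
    _row(48, 144, 48, 5, 1, "SE", "hard-swish"),
    _row(48, 288, 96, 5, 2, "SE", "hard-swish"),
    _row(96, 576, 96, 5, 1, "SE", "hard-swish"),
    _row(96, 576, 96, 5, 1, "SE", "hard-swish"),
)

# index (exclusive) of the last 28x28 row: rows 0-2 form stages 1-2
STAGE2_END = 3


@dataclasses.dataclass
class BackboneConfig:
    rows: tuple[BottleneckSpec, ...] = MOBILENET_V3_SMALL_ROWS
    stem_channels: int = 16
    head_channels: int = 576
    classifier_hidden: int = 1024
    num_classes: int = 11
    dropout: float = 0.2

    def validate(self) -> None:
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        cin = self.stem_channels
        for i, row in enumerate(self.rows):
            if row.in_channels != cin:
                raise ValueError(
                    f"row {i}: in_channels {row.in_channels} does not chain "
                    f"from previous width {cin}")
            cin = row.out_channels


def _act(name: str) -> Module:
    return ReLU() if name == "relu" else HardSwish()


class Bottleneck(Module):
    """Inverted residual: expand -> depthwise -> attention -> project."""

    def __init__(self, spec: BottleneckSpec,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.spec = spec
        if spec.expand_channels != spec.in_channels:
            self.expand = ConvBNAct(spec.in_channels, spec.expand_channels, 1,
                                    act=_act(spec.activation), rng=rng)
        else:
            self.expand = Identity()
        self.depthwise = ConvBNAct(spec.expand_channels, spec.expand_channels,
                                   spec.kernel, stride=spec.stride,
                                   groups=spec.expand_channels,
                                   act=_act(spec.activation), rng=rng)
        self.attention = build_attention(spec.attention, spec.expand_channels,
                                         rng=rng)
        self.project = ConvBNAct(spec.expand_channels, spec.out_channels, 1,
                                 act=None, rng=rng)

    def forward(self, x):
        y = self.project(self.attention(self.depthwise(self.expand(x))))
        if self.spec.has_residual:
            y = core.add(y, x)
        return y


class Classifier(Module):
    """576 -> 1024 (hard-swish, dropout 0.2) -> num_classes."""

    def __init__(self, in_features: int, hidden: int, num_classes: int,
                 dropout: float, rng: np.random.Generator | None = None,
                 dropout_seed: int = 0):
        super().__init__()
        self.fc1 = Linear(in_features, hidden, rng=rng)
        self.act = HardSwish()
        self.drop = Dropout(dropout, seed=dropout_seed)
        self.fc2 = Linear(hidden, num_classes, rng=rng)

    def forward(self, x):
        return self.fc2(self.drop(self.act(self.fc1(x))))


class GrapeLeafNet(Module):
    """Backbone + optional fusion stage + classifier.

    ``forward`` returns logits; :meth:`forward_with_features` additionally
    returns the pooled penultimate feature (needed by the center loss) and,
    when the model carries a center-projection head, the projected center
    feature.
    """

    def __init__(self, config: BackboneConfig, blocks_end: int | None = None,
                 fusion: Module | None = None, use_head_conv: bool = True,
                 center_dim: int | None = None, seed: int = 0,
                 name: str = "MS"):
        super().__init__()
        config.validate()
        rng = np.random.default_rng(seed)
        self.config = config
        self.name = name
        rows = config.rows[:blocks_end] if blocks_end is not None \
            else config.rows
        self.stem = ConvBNAct(3, config.stem_channels, 3, stride=2,
                              act=HardSwish(), rng=rng)
        self.blocks = [Bottleneck(r, rng=rng) for r in rows]
        for i, b in enumerate(self.blocks):
            setattr(self, f"block{i}", b)
        if fusion is not None:
            fusion_width = getattr(getattr(fusion, "config", None),
                                   "concat_out_channels", None)
            if fusion_width is not None and \
                    fusion_width != config.head_channels:
                raise ValueError(
                    f"fusion stage emits {fusion_width} channels but the "
                    f"classifier expects {config.head_channels}")
        self.fusion = fusion
        self.head = ConvBNAct(rows[-1].out_channels, config.head_channels, 1,
                              act=HardSwish(), rng=rng) if use_head_conv \
            else Identity()
        self.pool = GlobalAvgPool()
        self.classifier = Classifier(config.head_channels,
                                     config.classifier_hidden,
                                     config.num_classes, config.dropout,
                                     rng=rng, dropout_seed=seed + 1)
        self.center_proj = Linear(config.head_channels, center_dim, rng=rng) \
            if center_dim else None
        self.center_dim = center_dim
        if center_dim:
            # class-center matrix of the center loss; owned by the model so
            # the joint-loss variant's budget includes it
            self.centers = Tensor(
                np.zeros((config.num_classes, center_dim), dtype=np.float32),
                requires_grad=True)

    # -- forward passes --------------------------------------------------
    def _features(self, x) -> Tensor:
        x = _ensure_tensor(x)
        y = self.stem(x)
        stage2 = None
        for i, b in enumerate(self.blocks):
            y = b(y)
            if i == STAGE2_END - 1:
                stage2 = y
        if self.fusion is not None:
            y = self.fusion(stage2, y)
        y = self.head(y)
        return self.pool(y)   # (N, 576)

    def forward(self, x):
        return self.classifier(self._features(x))

    def forward_with_features(self, x):
        pooled = self._features(x)
        logits = self.classifier(pooled)
        center_feat = self.center_proj(pooled) if self.center_proj else None
        return logits, pooled, center_feat

    def center_features(self, x) -> Tensor:
        if self.center_proj is None:
            raise ValueError(
                f"variant {self.name!r} has no center-projection head "
                "(built without joint-loss support)")
        return self.center_proj(self._features(x))


def _ensure_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 4 or x.shape[1] != 3:
        raise ValueError("expected an (N, 3, H, W) image batch")
    return Tensor(x)


def build_backbone(config: BackboneConfig, seed: int = 0) -> GrapeLeafNet:
    """The standard 11-row backbone (SE attention as published)."""
    return GrapeLeafNet(config, seed=seed, name="MS")
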