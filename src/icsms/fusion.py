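"""ICS-Inception: the multi-branch, dual-attention fusion stage.

The stage replaces the backbone's final bottleneck stage (the two
576-expansion blocks and the 1x1 head convolution) and fuses two views of
the image:

* three **deep branches** on the 96-channel 7x7 feature map — a linear 1x1
  convolution (conv + BN, no activation), a ReLU6-activated 1x1 convolution,
  and a 3x3 stride-1 max-pool followed by a 1x1 projection — capturing the
  macroscopic morphology the deep pathway has already abstracted;
* one **high-resolution detail branch** tapping the 24-channel 28x28
  stage-2 feature map (1x1 ReLU6 expansion to a wide texture basis, then a
  linear 1x1 projection, then average pooling down to the deep resolution),
  which carries the microscopic vein/serration texture that no longer
  survives at 7x7.

All branch outputs are concatenated to exactly the 576-channel width the
classifier expects, then filtered by CBAM dual attention (channel then
spatial).  Branch widths are pinned by the published parameter/MAC budget of
the assembled model (see docs/methods.md); they live in
:data:`ICS_INCEPTION_DEFAULT` as data.

A conventional single-scale Inception block (1x1 / 3x3 / 5x5 / pool
branches, no attention) is provided for the "-I" comparison variant.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .attention import CBAM, CBAM_FUSION_REDUCTION
from .nn import core
from .nn.layers import (AvgPool2d, ConvBNAct, Identity, MaxPool2d, Module,
                        ReLU6, Sequential)


@dataclasses.dataclass(frozen=True)
class BranchSpec:
    kind: str           # conv1x1_linear | conv1x1_relu6 | maxpool_project | highres_detail
    out_channels: int
    hidden_channels: int = 0   # highres_detail only: width of the texture basis

    VALID = ("conv1x1_linear", "conv1x1_relu6", "maxpool_project",
             "highres_detail")

    def __post_init__(self):
        if self.kind not in self.VALID:
            raise ValueError(f"unknown branch kind {self.kind!r}")
        if self.out_channels <= 0:
            raise ValueError("branch out_channels must be positive")


@dataclasses.dataclass(frozen=True)
class ICSInceptionConfig:
    in_channels: int                      # deep feature width
    highres_channels: int                 # stage-2 feature width
    branches: tuple[BranchSpec, ...]
    concat_out_channels: int
    apply_cbam: bool = True
    cbam_reduction: int = CBAM_FUSION_REDUCTION

    def validate(self) -> None:
        if len(self.branches) < 2:
            raise ValueError("ICS-Inception needs at least 2 branches")
        total = sum(b.out_channels for b in self.branches)
        if total != self.concat_out_channels:
            raise ValueError(
                f"branch widths sum to {total}, expected concat width "
                f"{self.concat_out_channels}")


# Widths solved so the assembled CE-only model meets its published budgets
# (1.12 M parameters, 0.21 G MACs at 224x224x3); see docs/methods.md.
ICS_INCEPTION_DEFAULT = ICSInceptionConfig(
    in_channels=96,
    highres_channels=24,
    branches=(
        BranchSpec("conv1x1_linear", 128),
        BranchSpec("conv1x1_relu6", 96),
        BranchSpec("maxpool_project", 64),
        BranchSpec("highres_detail", 288, hidden_channels=672),
    ),
    concat_out_channels=576,
)


class ICSInception(Module):
    def __init__(self, config: ICSInceptionConfig = ICS_INCEPTION_DEFAULT,
                 rng: np.random.Generator | None = None):
        super().__init__()
        config.validate()
        self.config = config
        cin, chr_ = config.in_channels, config.highres_channels
        self.branch_mods: list[tuple[str, Module]] = []
        for i, b in enumerate(config.branches):
            if b.kind == "conv1x1_linear":
                m = ConvBNAct(cin, b.out_channels, 1, act=None, rng=rng)
            elif b.kind == "conv1x1_relu6":
                m = ConvBNAct(cin, b.out_channels, 1, act=ReLU6(), rng=rng)
            elif b.kind == "maxpool_project":
                m = Sequential(MaxPool2d(3, stride=1, padding=1),
                               ConvBNAct(cin, b.out_channels, 1, act=None,
                                         rng=rng))
            else:  # highres_detail
                if b.hidden_channels <= 0:
                    raise ValueError("highres_detail needs hidden_channels")
                m = Sequential(
                    ConvBNAct(chr_, b.hidden_channels, 1, act=ReLU6(),
                              rng=rng),
                    ConvBNAct(b.hidden_channels, b.out_channels, 1, act=None,
                              rng=rng))
            self.branch_mods.append((b.kind, m))
            setattr(self, f"branch{i}", m)
        self.cbam = CBAM(config.concat_out_channels,
                         reduction=config.cbam_reduction, rng=rng) \
            if config.apply_cbam else Identity()

    def forward(self, stage2, deep):
        """stage2: (N, 24, Hs, Ws); deep: (N, 96, Hd, Wd); Hs = k*Hd."""
        if deep.shape[1] != self.config.in_channels:
            raise ValueError(
                f"deep feature has {deep.shape[1]} channels, config expects "
                f"{self.config.in_channels}")
        factor = stage2.shape[2] // deep.shape[2]
        outs = []
        for kind, m in self.branch_mods:
            if kind == "highres_detail":
                y = m(stage2)
                if factor > 1:
                    y = core.avg_pool2d(y, factor)
            else:
                y = m(deep)
            outs.append(y)
        y = core.concat(outs, axis=1)
        return self.cbam(y)


@dataclasses.dataclass(frozen=True)
class InceptionConfig:
    """Conventional (single-scale) Inception block for the "-I" variant."""

    in_channels: int = 96
    w1: int = 224            # 1x1 branch
    r3: int = 96             # 3x3 reduce
    w3: int = 128            # 3x3 branch
    r5: int = 32             # 5x5 reduce
    w5: int = 96             # 5x5 branch
    wp: int = 128            # pool-projection branch
    concat_out_channels: int = 576

    def validate(self) -> None:
        if self.w1 + self.w3 + self.w5 + self.wp != self.concat_out_channels:
            raise ValueError("Inception branch widths must sum to concat width")


class ConventionalInception(Module):
    def __init__(self, config: InceptionConfig = InceptionConfig(),
                 rng: np.random.Generator | None = None):
        super().__init__()
        config.validate()
        self.config = config
        cin = config.in_channels
        self.b1 = ConvBNAct(cin, config.w1, 1, act=ReLU6(), rng=rng)
        self.b3 = Sequential(ConvBNAct(cin, config.r3, 1, act=ReLU6(), rng=rng),
                             ConvBNAct(config.r3, config.w3, 3, act=ReLU6(),
                                       rng=rng))
        self.b5 = Sequential(ConvBNAct(cin, config.r5, 1, act=ReLU6(), rng=rng),
                             ConvBNAct(config.r5, config.w5, 5, act=ReLU6(),
                                       rng=rng))
        self.bp = Sequential(MaxPool2d(3, stride=1, padding=1),
                             ConvBNAct(cin, config.wp, 1, act=ReLU6(),
                                       rng=rng))

    def forward(self, stage2, deep):
        del stage2  # single-scale block: reads only the deep feature
        return core.concat([self.b1(deep), self.b3(deep), self.b5(deep),
                            self.bp(deep)], axis=1)
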