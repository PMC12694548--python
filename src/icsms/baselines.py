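"""Reference CNN baselines for the budget audit.

Canonical architectures (ImageNet definitions with the final classifier
resized to ``num_classes``): ResNet-50, MobileNetV2, MobileNetV3-Large and
ShuffleNetV2 x1.0.  They exist so the parameter/MAC counter can be checked
against published budgets and so the training pipeline has comparison
points; nothing here deviates from the standard layer tables.
"""

from __future__ import annotations

import numpy as np

from .attention import AttentionKind
from .backbone import BottleneckSpec, Bottleneck, _row
from .nn import core
from .nn.layers import (ConvBNAct, Dropout, GlobalAvgPool, HardSwish, Identity,
                        Linear, MaxPool2d, Module, ReLU, ReLU6, Sequential)


# ---------------------------------------------------------------- ResNet-50

class _ResNetBottleneck(Module):
    expansion = 4

    def __init__(self, cin, width, stride, rng):
        super().__init__()
        cout = width * self.expansion
        self.conv1 = ConvBNAct(cin, width, 1, act=ReLU(), rng=rng)
        self.conv2 = ConvBNAct(width, width, 3, stride=stride, act=ReLU(),
                               rng=rng)
        self.conv3 = ConvBNAct(width, cout, 1, act=None, rng=rng)
        self.down = ConvBNAct(cin, cout, 1, stride=stride, act=None, rng=rng) \
            if (stride != 1 or cin != cout) else Identity()
        self.act = ReLU()

    def forward(self, x):
        y = self.conv3(self.conv2(self.conv1(x)))
        return self.act(core.add(y, self.down(x)))


class ResNet50(Module):
    def __init__(self, num_classes: int = 11, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.stem = ConvBNAct(3, 64, 7, stride=2, act=ReLU(), rng=rng)
        self.pool = MaxPool2d(3, stride=2, padding=1)
        blocks = []
        cin = 64
        for width, n, stride in ((64, 3, 1), (128, 4, 2),
                                 (256, 6, 2), (512, 3, 2)):
            for i in range(n):
                blocks.append(_ResNetBottleneck(
                    cin, width, stride if i == 0 else 1, rng))
                cin = width * 4
        self.blocks = Sequential(*blocks)
        self.gap = GlobalAvgPool()
        self.fc = Linear(2048, num_classes, rng=rng)

    def forward(self, x):
        return self.fc(self.gap(self.blocks(self.pool(self.stem(x)))))


# ------------------------------------------------------------- MobileNetV2

class _MBV2Block(Module):
    def __init__(self, cin, cout, expand_ratio, stride, rng):
        super().__init__()
        hidden = cin * expand_ratio
        self.use_res = stride == 1 and cin == cout
        self.expand = ConvBNAct(cin, hidden, 1, act=ReLU6(), rng=rng) \
            if expand_ratio != 1 else Identity()
        self.depthwise = ConvBNAct(hidden, hidden, 3, stride=stride,
                                   groups=hidden, act=ReLU6(), rng=rng)
        self.project = ConvBNAct(hidden, cout, 1, act=None, rng=rng)

    def forward(self, x):
        y = self.project(self.depthwise(self.expand(x)))
        return core.add(y, x) if self.use_res else y


class MobileNetV2(Module):
    SETTINGS = ((1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2), (6, 64, 4, 2),
                (6, 96, 3, 1), (6, 160, 3, 2), (6, 320, 1, 1))

    def __init__(self, num_classes: int = 11, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.stem = ConvBNAct(3, 32, 3, stride=2, act=ReLU6(), rng=rng)
        blocks = []
        cin = 32
        for t, c, n, s in self.SETTINGS:
            for i in range(n):
                blocks.append(_MBV2Block(cin, c, t, s if i == 0 else 1, rng))
                cin = c
        self.blocks = Sequential(*blocks)
        self.head = ConvBNAct(320, 1280, 1, act=ReLU6(), rng=rng)
        self.gap = GlobalAvgPool()
        self.drop = Dropout(0.2, seed=seed + 1)
        self.fc = Linear(1280, num_classes, rng=rng)

    def forward(self, x):
        return self.fc(self.drop(self.gap(self.head(self.blocks(self.stem(x))))))


# ------------------------------------------------------- MobileNetV3-Large

MOBILENET_V3_LARGE_ROWS: tuple[BottleneckSpec, ...] = (
    _row(16, 16, 16, 3, 1, "none", "relu"),
    _row(16, 64, 24, 3, 2, "none", "relu"),
    _row(24, 72, 24, 3, 1, "none", "relu"),
    _row(24, 72, 40, 5, 2, "SE", "relu"),
    _row(40, 120, 40, 5, 1, "SE", "relu"),
    _row(40, 120, 40, 5, 1, "SE", "relu"),
    _row(40, 240, 80, 3, 2, "none", "hard-swish"),
    _row(80, 200, 80, 3, 1, "none", "hard-swish"),
    _row(80, 184, 80, 3, 1, "none", "hard-swish"),
    _row(80, 184, 80, 3, 1, "none", "hard-swish"),
    _row(80, 480, 112, 3, 1, "SE", "hard-swish"),
    _row(112, 672, 112, 3, 1, "SE", "hard-swish"),
    _row(112, 672, 160, 5, 2, "SE", "hard-swish"),
    _row(160, 960, 160, 5, 1, "SE", "hard-swish"),
    _row(160, 960, 160, 5, 1, "SE", "hard-swish"),
)


class MobileNetV3Large(Module):
    def __init__(self, num_classes: int = 11, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.stem = ConvBNAct(3, 16, 3, stride=2, act=HardSwish(), rng=rng)
        self.blocks = Sequential(*[Bottleneck(r, rng=rng)
                                   for r in MOBILENET_V3_LARGE_ROWS])
        self.head = ConvBNAct(160, 960, 1, act=HardSwish(), rng=rng)
        self.gap = GlobalAvgPool()
        self.fc1 = Linear(960, 1280, rng=rng)
        self.act = HardSwish()
        self.drop = Dropout(0.2, seed=seed + 1)
        self.fc2 = Linear(1280, num_classes, rng=rng)

    def forward(self, x):
        y = self.gap(self.head(self.blocks(self.stem(x))))
        return self.fc2(self.drop(self.act(self.fc1(y))))


# --------------------------------------------------------- ShuffleNetV2 x1.0

def _channel_shuffle(x, groups: int = 2):
    n, c, h, w = x.shape
    y = core.reshape(x, (n, groups, c // groups, h, w))
    y = core.transpose(y, (0, 2, 1, 3, 4))
    return core.reshape(y, (n, c, h, w))


class _ShuffleUnit(Module):
    def __init__(self, cin, cout, stride, rng):
        super().__init__()
        self.stride = stride
        half = cout // 2
        if stride == 2:
            self.branch1 = Sequential(
                ConvBNAct(cin, cin, 3, stride=2, groups=cin, act=None,
                          rng=rng),
                ConvBNAct(cin, half, 1, act=ReLU(), rng=rng))
            b2_in = cin
        else:
            self.branch1 = Identity()
            b2_in = cin // 2
        self.branch2 = Sequential(
            ConvBNAct(b2_in, half, 1, act=ReLU(), rng=rng),
            ConvBNAct(half, half, 3, stride=stride, groups=half, act=None,
                      rng=rng),
            ConvBNAct(half, half, 1, act=ReLU(), rng=rng))

    def forward(self, x):
        if self.stride == 2:
            y = core.concat([self.branch1(x), self.branch2(x)], axis=1)
        else:
            c = x.shape[1]
            x1 = core.narrow(x, 1, 0, c // 2)
            x2 = core.narrow(x, 1, c // 2, c - c // 2)
            y = core.concat([x1, self.branch2(x2)], axis=1)
        return _channel_shuffle(y)


class ShuffleNetV2(Module):
    STAGE_OUT = (116, 232, 464)
    REPEATS = (4, 8, 4)

    def __init__(self, num_classes: int = 11, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.stem = ConvBNAct(3, 24, 3, stride=2, act=ReLU(), rng=rng)
        self.pool = MaxPool2d(3, stride=2, padding=1)
        units = []
        cin = 24
        for cout, n in zip(self.STAGE_OUT, self.REPEATS):
            for i in range(n):
                units.append(_ShuffleUnit(cin, cout, 2 if i == 0 else 1, rng))
                cin = cout
        self.stages = Sequential(*units)
        self.conv5 = ConvBNAct(464, 1024, 1, act=ReLU(), rng=rng)
        self.gap = GlobalAvgPool()
        self.fc = Linear(1024, num_classes, rng=rng)

    def forward(self, x):
        return self.fc(self.gap(self.conv5(self.stages(self.pool(self.stem(x))))))
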