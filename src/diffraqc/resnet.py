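"""Residual-network backbones with a single-channel input stage.

The standard 18/34/50-layer residual networks map an RGB image to 1000
features.  Here the first convolution is reshaped to accept one-channel
(greyscale) diffraction quadrants; everything else — the 7x7 stem, the
four block stages, global average pooling and the 512/2048 -> 1000 fully
connected layer — follows the canonical design, so the trainable-parameter
counts are the canonical ones minus exactly ``64*7*7*2`` weights in the
first convolution.

These deep backbones are built and counted natively; the desk-scale
"toy" backbone used for training in the test suite lives in
:mod:`diffraqc.model`.
"""

from __future__ import annotations

import numpy as np

from .nn import (BatchNorm2d, Conv2d, GlobalAvgPool, Layer, Linear,
                 MaxPool2d, ReLU, Sequential)

__all__ = ["ResNet", "RESNET_LAYERS", "resnet_param_shapes", "count_shapes"]

# blocks per stage and block kind for each canonical depth
RESNET_LAYERS = {
    18: ([2, 2, 2, 2], "basic"),
    34: ([3, 4, 6, 3], "basic"),
    50: ([3, 4, 6, 3], "bottleneck"),
}
_EXPANSION = {"basic": 1, "bottleneck": 4}


class _Residual(Layer):
    """A residual block: main branch + identity/projection shortcut."""

    def __init__(self, main: Sequential, shortcut: Sequential | None):
        self.main = main
        self.shortcut = shortcut
        self.relu = ReLU()

    def params(self):
        ps = self.main.params()
        if self.shortcut:
            ps = ps + self.shortcut.params()
        return ps

    def forward(self, x, train=False):
        out = self.main.forward(x, train=train)
        idn = self.shortcut.forward(x, train=train) if self.shortcut else x
        return self.relu.forward(out + idn, train=train)

    def backward(self, gout):
        g = self.relu.backward(gout)
        gx = self.main.backward(g)
        gx += self.shortcut.backward(g) if self.shortcut else g
        return gx


def _basic_block(c_in, planes, stride, rng, tag):
    main = Sequential(
        Conv2d(c_in, planes, 3, stride=stride, pad=1, rng=rng, name=f"{tag}.conv1"),
        BatchNorm2d(planes, name=f"{tag}.bn1"),
        ReLU(),
        Conv2d(planes, planes, 3, stride=1, pad=1, rng=rng, name=f"{tag}.conv2"),
        BatchNorm2d(planes, name=f"{tag}.bn2"),
    )
    shortcut = None
    if stride != 1 or c_in != planes:
        shortcut = Sequential(
            Conv2d(c_in, planes, 1, stride=stride, rng=rng, name=f"{tag}.down"),
            BatchNorm2d(planes, name=f"{tag}.downbn"),
        )
    return _Residual(main, shortcut), planes


def _bottleneck_block(c_in, planes, stride, rng, tag):
    out_c = planes * 4
    main = Sequential(
        Conv2d(c_in, planes, 1, rng=rng, name=f"{tag}.conv1"),
        BatchNorm2d(planes, name=f"{tag}.bn1"),
        ReLU(),
        Conv2d(planes, planes, 3, stride=stride, pad=1, rng=rng, name=f"{tag}.conv2"),
        BatchNorm2d(planes, name=f"{tag}.bn2"),
        ReLU(),
        Conv2d(planes, out_c, 1, rng=rng, name=f"{tag}.conv3"),
        BatchNorm2d(out_c, name=f"{tag}.bn3"),
    )
    shortcut = None
    if stride != 1 or c_in != out_c:
        shortcut = Sequential(
            Conv2d(c_in, out_c, 1, stride=stride, rng=rng, name=f"{tag}.down"),
            BatchNorm2d(out_c, name=f"{tag}.downbn"),
        )
    return _Residual(main, shortcut), out_c


class ResNet(Layer):
    """Canonical residual network mapping (B, in_channels, H, W) -> (B, 1000)."""

    def __init__(self, depth: int, in_channels: int = 1, n_features: int = 1000,
                 rng: np.random.Generator | None = None):
        if depth not in RESNET_LAYERS:
            raise ValueError(f"unsupported depth {depth}; choose from {sorted(RESNET_LAYERS)}")
        rng = rng or np.random.default_rng(0)
        blocks_per_stage, kind = RESNET_LAYERS[depth]
        make = _basic_block if kind == "basic" else _bottleneck_block
        layers: list[Layer] = [
            Conv2d(in_channels, 64, 7, stride=2, pad=3, rng=rng, name="conv1"),
            BatchNorm2d(64, name="bn1"),
            ReLU(),
            MaxPool2d(3, stride=2, pad=1),
        ]
        c = 64
        for stage, (planes, n_blocks) in enumerate(zip((64, 128, 256, 512), blocks_per_stage)):
            for i in range(n_blocks):
                stride = 2 if (stage > 0 and i == 0) else 1
                block, c = make(c, planes, stride, rng, f"layer{stage + 1}.{i}")
                layers.append(block)
        layers += [GlobalAvgPool(),
                   Linear(c, n_features, rng=rng, name="fc")]
        self.net = Sequential(*layers)

    def params(self):
        return self.net.params()

    def forward(self, x, train=False):
        return self.net.forward(x, train=train)

    def backward(self, gout):
        return self.net.backward(gout)


def resnet_param_shapes(depth: int, in_channels: int = 1,
                        n_features: int = 1000) -> dict[str, tuple[int, ...]]:
    """Name -> shape table of every trainable tensor, without allocating weights.

    Convolutions carry no bias (a following batch norm supplies the shift);
    each batch norm has a scale and a shift per channel; the final fully
    connected layer has weight and bias.
    """
    if depth not in RESNET_LAYERS:
        raise ValueError(f"unsupported depth {depth}")
    blocks_per_stage, kind = RESNET_LAYERS[depth]
    exp = _EXPANSION[kind]
    shapes: dict[str, tuple[int, ...]] = {
        "conv1.weight": (64, in_channels, 7, 7),
        "bn1.weight": (64,), "bn1.bias": (64,),
    }

    def add_bn(tag, c):
        shapes[f"{tag}.weight"] = (c,)
        shapes[f"{tag}.bias"] = (c,)

    c = 64
    for stage, (planes, n_blocks) in enumerate(zip((64, 128, 256, 512), blocks_per_stage)):
        for i in range(n_blocks):
            tag = f"layer{stage + 1}.{i}"
            stride = 2 if (stage > 0 and i == 0) else 1
            out_c = planes * exp
            if kind == "basic":
                shapes[f"{tag}.conv1.weight"] = (planes, c, 3, 3)
                add_bn(f"{tag}.bn1", planes)
                shapes[f"{tag}.conv2.weight"] = (planes, planes, 3, 3)
                add_bn(f"{tag}.bn2", planes)
            else:
                shapes[f"{tag}.conv1.weight"] = (planes, c, 1, 1)
                add_bn(f"{tag}.bn1", planes)
                shapes[f"{tag}.conv2.weight"] = (planes, planes, 3, 3)
                add_bn(f"{tag}.bn2", planes)
                shapes[f"{tag}.conv3.weight"] = (out_c, planes, 1, 1)
                add_bn(f"{tag}.bn3", out_c)
            if stride != 1 or c != out_c:
                shapes[f"{tag}.down.weight"] = (out_c, c, 1, 1)
                add_bn(f"{tag}.downbn", out_c)
            c = out_c
    shapes["fc.weight"] = (n_features, c)
    shapes["fc.bias"] = (n_features,)
    return shapes


def count_shapes(shapes: dict[str, tuple[int, ...]]) -> int:
    return int(sum(int(np.prod(s)) for s in shapes.values()))
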