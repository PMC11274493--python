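"""Compact 3D residual and densely connected extractor architectures.

The residual network follows the classic layout: a stem convolution and max
pooling, then residual blocks of two 3x3x3 convolutions each (with batch
normalization and ReLU), channels doubling stage by stage. With eight blocks
the network has 18 weight layers (stem + 16 block convolutions + the
classification layer). The densely connected network has a stem followed by
dense blocks — each layer computes BN -> ReLU -> conv and concatenates its
output to the running feature map — separated by transition layers
(1x1x1 compression convolution, average pooling while spatial extent
allows).

Latent features are the flattened activation of the network's last
convolutional feature map (before global pooling), named
``<Family>_Latent_<index>``; their count is channels x spatial voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from radguide.deepnet._nn import (
    AvgPool3d,
    BatchNorm3d,
    Conv3d,
    GlobalAvgPool,
    Layer,
    Linear,
    MaxPool3d,
    ReLU,
    Sequential,
)
from radguide.io_core import latent_column


@dataclass
class ArchConfig:
    family: str = "densenet"  # "resnet" | "densenet"
    input_shape: tuple[int, int, int] = (48, 48, 48)
    n_classes: int = 4
    # resnet
    n_blocks: int = 8
    base_channels: int = 16
    # densenet
    n_dense_blocks: int = 4
    growth_rate: int = 6
    layers_per_block: int = 2
    init_channels: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.family not in ("resnet", "densenet"):
            raise ValueError(f"unknown family {self.family!r}")
        if min(self.input_shape) < 8:
            raise ValueError("input shape too small for the stem stride")


class ResidualBlock(Layer):
    def __init__(self, c_in: int, c_out: int, stride: int, rng):
        self.conv1 = Conv3d(c_in, c_out, 3, stride, rng)
        self.bn1 = BatchNorm3d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(c_out, c_out, 3, 1, rng)
        self.bn2 = BatchNorm3d(c_out)
        self.relu_out = ReLU()
        if c_in != c_out or stride != 1:
            self.proj: Sequential | None = Sequential(
                Conv3d(c_in, c_out, 1, stride, rng), BatchNorm3d(c_out))
        else:
            self.proj = None

    def params(self):
        out = (self.conv1.params() + self.bn1.params()
               + self.conv2.params() + self.bn2.params())
        if self.proj is not None:
            out += self.proj.params()
        return out

    def forward(self, x, train):
        main = self.conv1.forward(x, train)
        main = self.bn1.forward(main, train)
        main = self.relu1.forward(main, train)
        main = self.conv2.forward(main, train)
        main = self.bn2.forward(main, train)
        skip = x if self.proj is None else self.proj.forward(x, train)
        return self.relu_out.forward(main + skip, train)

    def backward(self, dout):
        dsum = self.relu_out.backward(dout)
        dmain = self.bn2.backward(dsum)
        dmain = self.conv2.backward(dmain)
        dmain = self.relu1.backward(dmain)
        dmain = self.bn1.backward(dmain)
        dmain = self.conv1.backward(dmain)
        dskip = dsum if self.proj is None else self.proj.backward(dsum)
        return dmain + dskip


class DenseLayer(Layer):
    def __init__(self, c_in: int, growth: int, rng):
        self.bn = BatchNorm3d(c_in)
        self.relu = ReLU()
        self.conv = Conv3d(c_in, growth, 3, 1, rng)
        self.c_in = c_in

    def params(self):
        return self.bn.params() + self.conv.params()

    def forward(self, x, train):
        new = self.conv.forward(self.relu.forward(self.bn.forward(x, train), train), train)
        return np.concatenate([x, new], axis=1)

    def backward(self, dout):
        dx_direct = dout[:, :self.c_in]
        dnew = dout[:, self.c_in:]
        dx = self.bn.backward(self.relu.backward(self.conv.backward(dnew)))
        return dx_direct + dx


class Network:
    """A feature extractor plus classification head (pool + linear)."""

    def __init__(self, config: ArchConfig, features: Sequential,
                 n_feature_channels: int, n_weight_layers: int):
        self.config = config
        self.features = features
        self.pool = GlobalAvgPool()
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
        self.head = Linear(n_feature_channels, config.n_classes, rng)
        self.n_weight_layers = n_weight_layers
        self.family_name = "ResNet" if config.family == "resnet" else "DenseNet"
        zero = np.zeros((1, 1) + tuple(config.input_shape), dtype=np.float32)
        fmap = self.features.forward(zero, train=False)
        self.latent_shape = fmap.shape[1:]
        self.n_latent = int(np.prod(self.latent_shape))

    def params(self):
        return self.features.params() + self.head.params()

    def forward_logits(self, x, train):
        self._fmap = self.features.forward(x, train)
        pooled = self.pool.forward(self._fmap, train)
        return self.head.forward(pooled, train)

    def backward_logits(self, dlogits):
        dpooled = self.head.backward(dlogits)
        dfmap = self.pool.backward(dpooled)
        return self.features.backward(dfmap)

    def latent(self, x: np.ndarray) -> np.ndarray:
        """Flattened last-conv activations, evaluation mode (frozen BN)."""
        fmap = self.features.forward(x.astype(np.float32), train=False)
        return fmap.reshape(fmap.shape[0], -1).astype(np.float64)

    def latent_names(self) -> list[str]:
        return [latent_column(self.family_name, i) for i in range(self.n_latent)]


def _build_resnet(cfg: ArchConfig, rng) -> tuple[Sequential, int, int]:
    base = cfg.base_channels
    layers: list[Layer] = [Conv3d(1, base, 3, 2, rng), BatchNorm3d(base),
                           ReLU(), MaxPool3d()]
    n_stages = min(4, cfg.n_blocks)
    per_stage = [cfg.n_blocks // n_stages] * n_stages
    for i in range(cfg.n_blocks % n_stages):
        per_stage[i] += 1
    c_in = base
    spatial = min(cfg.input_shape) // 4
    n_weight = 1  # stem conv
    for stage, n_b in enumerate(per_stage):
        c_out = base * 2 ** stage
        for b in range(n_b):
            stride = 2 if (stage > 0 and b == 0 and spatial > 3) else 1
            if stride == 2:
                spatial = (spatial + 2 - 3) // 2 + 1
            layers.append(ResidualBlock(c_in, c_out, stride, rng))
            n_weight += 2
            c_in = c_out
    return Sequential(*layers), c_in, n_weight + 1  # + classification layer


def _build_densenet(cfg: ArchConfig, rng) -> tuple[Sequential, int, int]:
    c = cfg.init_channels
    layers: list[Layer] = [Conv3d(1, c, 3, 2, rng), BatchNorm3d(c), ReLU(),
                           MaxPool3d()]
    spatial = min(cfg.input_shape) // 4
    n_weight = 1
    for block in range(cfg.n_dense_blocks):
        for _ in range(cfg.layers_per_block):
            layers.append(DenseLayer(c, cfg.growth_rate, rng))
            c += cfg.growth_rate
            n_weight += 1
        if block < cfg.n_dense_blocks - 1:
            c_out = max(c // 2, cfg.growth_rate)
            layers += [BatchNorm3d(c), ReLU(), Conv3d(c, c_out, 1, 1, rng)]
            n_weight += 1
            c = c_out
            if spatial >= 6:  # pool until the map reaches minimal extent
                layers.append(AvgPool3d())
                spatial //= 2
    return Sequential(*layers), c, n_weight + 1


def build_extractor(config: ArchConfig) -> Network:
    """Build a compact extractor network with a classification head attached."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    if config.family == "resnet":
        features, c, n_weight = _build_resnet(config, rng)
    else:
        features, c, n_weight = _build_densenet(config, rng)
    return Network(config, features, c, n_weight)
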