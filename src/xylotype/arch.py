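"""Assembly of the truncated-backbone texture classifier.

The reference architecture keeps the first ten layers of VGG16 — seven 3x3
same-padded convolutions with ReLU and three 2x2/stride-2 max poolings
(blocks 1-3, 256 output channels) — as a texture feature extractor, then
adds a global pooling layer (average or max, read as per-channel texture
"energy"), batch normalization, dropout and a softmax-activated fully
connected layer with one output per class. A miniature backbone with the
same layer grammar (three convolutions of 8/16/32 channels, three poolings)
is provided for desk-scale experiments where the full backbone is
unnecessarily heavy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from xylotype.nn.layers import (
    BatchNorm1D,
    Conv2D,
    Dense,
    Dropout,
    GlobalAveragePool,
    GlobalMaxPool,
    MaxPool2,
    ReLU,
)
from xylotype.nn.network import Network

__all__ = [
    "ArchitectureSpec",
    "ConfigError",
    "assemble",
    "set_backbone_trainable",
]

# Channel layout per backbone: "C" entries are convolution output widths,
# "P" is a 2x2/stride-2 max pooling.
_BACKBONE_PLANS = {
    "vgg16_truncated": [64, 64, "P", 128, 128, "P", 256, 256, 256, "P"],
    "mini": [8, "P", 16, "P", 32, "P"],
}


class ConfigError(ValueError):
    """Invalid architecture configuration."""


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of the classifier.

    ``pretrained`` may be ``False`` (seeded random initialization) or a path
    to an ``.npz`` file holding backbone weights keyed like the layer
    summary (``backbone_convN.W`` / ``.b``). ``True`` is rejected with an
    explanatory error because no weight file ships with the package.
    """

    backbone: str = "vgg16_truncated"
    pooling_variant: str = "global_average"  # or "global_max"
    dropout_rate: float = 0.5
    n_classes: int = 10
    pretrained: bool | str = False
    conv_kernel: int = 3
    pool_window: int = 2
    pool_stride: int = 2

    def __post_init__(self) -> None:
        if self.backbone not in _BACKBONE_PLANS:
            raise ConfigError(f"unknown backbone {self.backbone!r}")
        if self.pooling_variant not in ("global_average", "global_max"):
            raise ConfigError(
                f"pooling_variant must be 'global_average' or 'global_max', "
                f"got {self.pooling_variant!r}"
            )
        if not 0 <= self.dropout_rate < 1:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if self.pretrained is True:
            raise ConfigError(
                "pretrained=True needs a checkpoint path: pass "
                "pretrained='/path/to/weights.npz' (no weight file is bundled)"
            )
        if self.pretrained and self.backbone == "mini":
            raise ConfigError("the mini backbone has no pretrained checkpoint")
        if (self.conv_kernel, self.pool_window, self.pool_stride) != (3, 2, 2):
            raise ConfigError(
                "only 3x3 convolutions with 2x2/stride-2 pooling are supported"
            )

    @property
    def n_backbone_conv_layers(self) -> int:
        return sum(1 for e in _BACKBONE_PLANS[self.backbone] if e != "P")

    @property
    def n_backbone_pool_layers(self) -> int:
        return sum(1 for e in _BACKBONE_PLANS[self.backbone] if e == "P")


def assemble(
    spec: ArchitectureSpec,
    input_dims: tuple[int, int],
    seed: int = 0,
) -> tuple[Network, list[dict]]:
    """Build the network and its layer summary for a given input size.

    ``input_dims`` is (height, width) of the (RGB) input patch; both must be
    divisible by 2**n_pool_layers so every pooling halves cleanly.

    Returns the trainable :class:`~xylotype.nn.network.Network` and a
    summary: one dict per layer with name, type, output shape and parameter
    count.
    """
    h, w = input_dims
    divisor = 2**spec.n_backbone_pool_layers
    if h % divisor or w % divisor:
        raise ConfigError(
            f"input dims {h}x{w} must be divisible by {divisor} "
            f"({spec.n_backbone_pool_layers} pooling layers)"
        )

    rng = np.random.default_rng(seed)
    plan = _BACKBONE_PLANS[spec.backbone]
    layers: list[tuple[str, object]] = []
    summary: list[dict] = []
    channels, cur_h, cur_w = 3, h, w
    conv_i = pool_i = 0
    for entry in plan:
        if entry == "P":
            pool_i += 1
            name = f"backbone_pool{pool_i}"
            layers.append((name, MaxPool2()))
            cur_h //= 2
            cur_w //= 2
            summary.append(
                dict(name=name, type="MaxPool2", output_shape=(channels, cur_h, cur_w), n_params=0)
            )
        else:
            conv_i += 1
            name = f"backbone_conv{conv_i}"
            conv = Conv2D(channels, int(entry), rng)
            layers.append((name, conv))
            channels = int(entry)
            summary.append(
                dict(name=name, type="Conv2D+ReLU", output_shape=(channels, cur_h, cur_w), n_params=conv.n_params)
            )
            layers.append((f"{name}_relu", ReLU()))
    n_backbone = len(layers)

    pool_cls = (
        GlobalAveragePool
        if spec.pooling_variant == "global_average"
        else GlobalMaxPool
    )
    layers.append(("head_global_pool", pool_cls()))
    summary.append(
        dict(
            name="head_global_pool",
            type=pool_cls.__name__,
            output_shape=(channels,),
            n_params=0,
        )
    )
    bn = BatchNorm1D(channels)
    layers.append(("head_batchnorm", bn))
    summary.append(
        dict(name="head_batchnorm", type="BatchNorm1D", output_shape=(channels,), n_params=bn.n_params)
    )
    layers.append(("head_dropout", Dropout(spec.dropout_rate)))
    summary.append(
        dict(name="head_dropout", type="Dropout", output_shape=(channels,), n_params=0)
    )
    dense = Dense(channels, spec.n_classes, rng)
    layers.append(("head_dense", dense))
    summary.append(
        dict(
            name="head_dense",
            type="Dense+Softmax",
            output_shape=(spec.n_classes,),
            n_params=dense.n_params,
        )
    )

    network = Network(layers, n_backbone=n_backbone)
    if spec.pretrained:
        _load_backbone_weights(network, Path(spec.pretrained))
    return network, summary


def _load_backbone_weights(network: Network, path: Path) -> None:
    if not path.exists():
        raise ConfigError(f"pretrained checkpoint not found: {path}")
    with np.load(path) as data:
        for name, layer in network.layers[: network.n_backbone]:
            for key in layer.params:
                full = f"{name}.{key}"
                if full not in data.files:
                    raise ConfigError(f"checkpoint {path} missing weight {full}")
                weight = data[full].astype(np.float32)
                if weight.shape != layer.params[key].shape:
                    raise ConfigError(
                        f"checkpoint weight {full} has shape {weight.shape}, "
                        f"expected {layer.params[key].shape}"
                    )
                layer.params[key] = weight


def set_backbone_trainable(network: Network, trainable: bool) -> Network:
    """Freeze or unfreeze the convolutional backbone (head stays trainable)."""
    network.set_backbone_trainable(trainable)
    return network
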