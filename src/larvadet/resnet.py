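"""Shape arithmetic for a standard 101-layer residual backbone.

A ResNet-101 backbone reduces the spatial side by an overall stride of 32
(initial 7x7 stride-2 conv, 3x3 stride-2 max-pool, then a stride-2
bottleneck entering each of stages 3-5) and ends with 2048 channels.  With
the conventional "same"-style padding every stride-2 stage maps a side of
n to ceil(n / 2), so a 300-px input traces 300 - 150 - 75 - 38 - 19 - 10
and flattens to 10 * 10 * 2048 = 204,800 features.  No weights are needed
for any of this; it is pure layer arithmetic, which is also cross-checked
here by walking every convolution of the backbone explicitly.
"""

from __future__ import annotations

from .exceptions import ConfigurationError

__all__ = [
    "resnet_head_flatten_size",
    "resnet101_stage_sides",
    "resnet101_conv_walk",
    "RESNET101_FINAL_CHANNELS",
    "RESNET101_BLOCKS",
]

RESNET101_FINAL_CHANNELS = 2048
#: Bottleneck blocks per stage (conv2_x .. conv5_x); 3+4+23+3 blocks of 3
#: convolutions each, plus the stem conv, gives the eponymous 100 conv
#: layers + 1 fully connected layer.
RESNET101_BLOCKS = (3, 4, 23, 3)


def _conv_out(n: int, kernel: int, stride: int, padding: int) -> int:
    return (n + 2 * padding - kernel) // stride + 1


def resnet101_stage_sides(input_side: int) -> list[int]:
    """Spatial side after the stem and after each of the four stages."""
    if input_side < 32:
        raise ConfigurationError(
            f"input side {input_side} is too small for five stride-2 stages"
        )
    sides = []
    n = _conv_out(input_side, 7, 2, 3)  # stem conv
    n = _conv_out(n, 3, 2, 1)  # stem max-pool
    sides.append(n)  # after conv2_x (stride 1)
    for _ in range(3):  # conv3_x..conv5_x enter with stride 2: n -> ceil(n/2)
        n = (n + 1) // 2
        sides.append(n)
    return sides


def resnet101_conv_walk(input_side: int) -> list[tuple[str, int, int]]:
    """Every convolution of the backbone as (name, side, channels).

    Walks the stem plus all 33 bottleneck blocks (1x1, 3x3 pad-1, 1x1
    convolutions each; stride 2 on the 3x3 of the first block of stages
    3-5), applying standard output-size arithmetic conv by conv.  Serves
    as the independent route to the final feature-map side.
    """
    if input_side < 32:
        raise ConfigurationError(
            f"input side {input_side} is too small for five stride-2 stages"
        )
    walk: list[tuple[str, int, int]] = []
    n = _conv_out(input_side, 7, 2, 3)
    walk.append(("conv1", n, 64))
    n = _conv_out(n, 3, 2, 1)
    walk.append(("maxpool", n, 64))
    mid = 64
    for stage, blocks in enumerate(RESNET101_BLOCKS, start=2):
        for b in range(blocks):
            stride = 2 if (stage > 2 and b == 0) else 1
            n1 = _conv_out(n, 1, 1, 0)
            n2 = _conv_out(n1, 3, stride, 1)
            n3 = _conv_out(n2, 1, 1, 0)
            walk.append((f"conv{stage}_{b + 1}a", n1, mid))
            walk.append((f"conv{stage}_{b + 1}b", n2, mid))
            walk.append((f"conv{stage}_{b + 1}c", n3, mid * 4))
            n = n3
        mid *= 2
    return walk


def resnet_head_flatten_size(input_side: int) -> int:
    """Flatten length after the backbone: final_side**2 * 2048."""
    final_side = resnet101_stage_sides(input_side)[-1]
    walk_side = resnet101_conv_walk(input_side)[-1][1]
    if walk_side != final_side:  # pragma: no cover - internal consistency
        raise AssertionError("stage arithmetic and conv walk disagree")
    return final_side * final_side * RESNET101_FINAL_CHANNELS
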