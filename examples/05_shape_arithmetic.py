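"""Layer-shape arithmetic for the compact CNN and the residual backbone.

The compact classifier uses unpadded 3x3 convolutions (side -> side - 2)
and 2x2 pooling (side -> floor(side/2)); a 300-px input flattens to
78,400 features. A standard 101-layer residual backbone reduces stride
by 32 with ceil-mode arithmetic and 2048 final channels: 300 -> 10,
flattening to 204,800 — computed without any weights.
"""

from larvadet import (
    CNNArchitectureSpec,
    build_cnn,
    compute_layer_shapes,
    resnet101_stage_sides,
    resnet_head_flatten_size,
)

spec = CNNArchitectureSpec(input_side=300)
print("compact CNN, 300x300x3 input:")
for name, shape in compute_layer_shapes(spec):
    print(f"  {name:12s} {shape}")

model = build_cnn(spec, seed=0)
print(f"built model: {model.layer_count} layers, {model.n_params():,} parameters")
print(f"backend agrees with the analytic chain: {model.logical_rows() == compute_layer_shapes(spec)}")

print(f"\nresidual backbone stage sides for 300 px: {resnet101_stage_sides(300)}")
print(f"flatten length: {resnet_head_flatten_size(300):,} (10 x 10 x 2048)")
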