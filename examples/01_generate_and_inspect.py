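"""Generate one synthetic multispectral capture and inspect its structure.

A capture is four co-registered 8-bit band images (GRE/NIR/RED/REG) of a
dark scene with one bright, elongated larva. The green band carries the
strongest larva/background contrast by construction, mirroring what the
imaging setup observes.
"""

import numpy as np

from larvadet import SceneSpec, generate_capture

spec = SceneSpec(
    image_side=600,
    larva_center=(300.0, 250.0),
    larva_length=75.0,
    larva_width=5.0,
    noise_sd=5.0,
)
capture = generate_capture(spec, seed=42)
mask = capture.truth_mask()

print(f"capture {capture.capture_id}: {capture.shape[0]}x{capture.shape[1]} per band")
print(f"larva covers {mask.sum()} px (planted truth)")
print(f"{'band':>5} {'bg mean':>8} {'larva mean':>11} {'gap':>6}")
for band, grid in capture.bands.items():
    g = grid.astype(float)
    gap = g[mask].mean() - g[~mask].mean()
    print(f"{band:>5} {g[~mask].mean():8.1f} {g[mask].mean():11.1f} {gap:6.1f}")
print("The GRE gap is the largest: that band is the one worth classifying on.")
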