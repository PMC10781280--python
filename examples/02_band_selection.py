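"""Score each spectral band and select the most discriminative one.

Each band image is wavelet-converted (Haar approximation) and scored by
(max - median) / (IQR + 1): a small, very bright larva over a flat
background gives a high score. The selected band is a majority vote over
captures — data-driven, not hard-coded.
"""

from larvadet import band_contrast_score, generate_dataset, select_band

captures = generate_dataset(8, 0, "chironomid", seed=7, image_side=600)

scores = band_contrast_score(captures[0])
print("capture 0 band scores (higher = sharper feature):")
for band, s in sorted(scores.items(), key=lambda kv: -kv[1]):
    print(f"  {band}: {s:6.1f}")

band = select_band(captures)
print(f"selected band across {len(captures)} captures: {band}")
print("GRE wins because the larva's intensity lift is strongest there.")
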