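"""Weighted-mean-phase degradation of a synthetic texture.

Mixes an image's Fourier phases with Hermitian-symmetric uniform noise and
its magnitudes with a set-average magnitude, both weighted by the
signal-to-noise weight w; then normalizes luminance and contrast. Higher w
means more signal: the reconstruction error falls monotonically.
"""

import numpy as np

from emrec.stimuli import (
    assign_sn_class,
    average_magnitude,
    binarize,
    normalize_image,
    wmp_degrade,
)

rng = np.random.default_rng(0)
base = rng.normal(size=(64, 64))
kernel = np.exp(-0.5 * (np.arange(-4, 5) / 2.0) ** 2)
img = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, base)
img = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="same"), 0, img)
img = 128 + 45 * img / img.std()

two_tone = binarize(img, 128)
print(f"binarized image: {np.mean(two_tone == 255):.0%} white pixels at threshold 128")

avg_mag = average_magnitude([img, np.flipud(img), np.fliplr(img)])
print("\n   w   class   relative RMS error vs original")
for w in (0.2, 0.3, 0.4, 0.5, 0.6):
    out = wmp_degrade(img, w, avg_mag, rng_seed=7)
    out = normalize_image(out, target_mean=img.mean(), target_rms=img.std())
    err = np.sqrt(np.mean((out - img) ** 2)) / img.std()
    print(f"  {w:.2f}    {assign_sn_class(w):>2}       {err:.3f}")
print("\nError shrinks as w rises; class 1 covers w in [0.20, 0.24), class 10 ends at 0.60.")
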