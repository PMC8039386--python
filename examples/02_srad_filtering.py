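"""Smooth speckle while keeping a tissue edge with SRAD.

A two-band image (levels 100/200) under 4-look speckle is diffused for
100 iterations; the in-band coefficient of variation collapses while
the band boundary stays within a pixel of its true row.
"""

import numpy as np

import gastrolayer as gl
from gastrolayer.srad import DiffusionParams

bands = np.vstack([np.full((40, 96), 100.0), np.full((40, 96), 200.0)])
noisy = gl.apply_speckle(bands, looks=4, seed=0)

params = DiffusionParams(n_iterations=100, time_step=0.05,
                         homog_window=(4, 30, 4, 92))
filtered = gl.srad_filter(noisy, params)


def in_band_cv(img):
    top, bot = img[6:34], img[46:74]
    return max(top.std() / top.mean(), bot.std() / bot.mean())


edge = int(np.argmax(np.abs(np.diff(filtered.mean(axis=1)))))
print(f"in-band CV before: {in_band_cv(noisy):.3f}   after: {in_band_cv(filtered):.3f}")
print(f"edge located between rows {edge} and {edge + 1}  (truth: 39/40)")
# Homogeneous speckle is treated as noise (c ~ 1, isotropic smoothing);
# the high-ICOV edge gets c ~ 0 and survives the diffusion.
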