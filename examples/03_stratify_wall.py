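"""Recover the five-layer proportion vector of a speckled wall.

Pipeline: wall mask -> ROI crop -> SRAD -> column-wise Sobel edges ->
averaged proportion vector x, compared against the simulated truth.
"""

import numpy as np

import gastrolayer as gl
from gastrolayer.srad import DiffusionParams

truth = gl.generate_phantom(gl.PhantomSpec(wall_thickness=150, speckle_looks=4, seed=3))

roi = gl.mask_to_roi(truth.wall_mask, margin=10)
crop = roi.crop(truth.image)
filtered = gl.srad_filter(
    crop, DiffusionParams(n_iterations=100, homog_window=(0, 5, 0, crop.shape[1]))
)
x = gl.aggregate_columns(filtered, mask=roi.crop(truth.wall_mask))

print("recovered x:", np.round(x, 3).tolist())
print("true      x:", np.round(truth.proportions, 3).tolist())
print(f"max component error: {np.abs(x - truth.proportions).max():.4f}")
# Each component of x is the fraction of total wall thickness occupied
# by one layer (mucosa ... serosa); errors of ~0.01 correspond to about
# one pixel of boundary localisation at this wall thickness.
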