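"""Volumetric PIV on a synthetic bead-stack pair with a known shift.

Renders ~1500 beads (≈8 per interrogation box), shifts them by 0.4 pixel
in x, and measures the displacement field by 3D cross-correlation.  The
printed statistics show sub-pixel accuracy well below a tenth of a pixel.
"""

from dataclasses import replace

import numpy as np

from welltfm.piv import PivConfig, filter_outliers, piv3d
from welltfm.synthetic import BeadField, render_stack

PX, DZ = 0.104, 0.2
rng = np.random.default_rng(0)
beads = BeadField(rng.uniform(0, [20, 20, 8], (1500, 3)))
reference = render_stack(beads, (40, 192, 192), PX, DZ, noise_sd=5.0, seed=1)

shift = 0.4 * PX  # µm
moved = replace(beads, positions=beads.positions + [shift, 0.0, 0.0])
deformed = render_stack(moved, (40, 192, 192), PX, DZ, noise_sd=5.0, seed=2)

field = piv3d(reference, deformed, PivConfig(box_size=(32, 32, 8)))
field = filter_outliers(field)
ux = field.vectors[field.valid, 0]
err_px = np.abs(ux - shift) / PX
print(f"{field.valid.sum()} valid vectors on a {field.grid_shape} grid")
print(f"true shift: {shift:.4f} µm = 0.400 px")
print(f"recovered mean: {ux.mean():.4f} µm = {ux.mean() / PX:.3f} px")
print(f"median |error|: {np.median(err_px):.3f} px; "
      f"{100 * (err_px < 0.1).mean():.1f}% of boxes within 0.1 px")
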