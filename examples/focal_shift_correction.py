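"""Axial focal-shift correction for a refractive-index mismatch.

A glycerin-immersion objective (n₁ = 1.47, NA 1.2) focusing into an
aqueous gel (n₂ = 1.34) moves its focal plane by less than the nominal
stage step: every apparent z must be rescaled before distances are
measured.
"""

import numpy as np

from welltfm import ImageStack, OpticalParams
from welltfm.optics import apply_visser, axial_scale, visser_focal_shift

params = OpticalParams(na=1.2, n_immersion=1.47, n_sample=1.34,
                       z_step_nominal=0.2)
df = visser_focal_shift(params)
print(f"nominal z-step: {params.z_step_nominal:.3f} µm")
print(f"true focal step Δf: {df:.4f} µm  (axial scale {axial_scale(params):.4f})")

stack = ImageStack(np.zeros((58, 8, 8)), pixel_size_xy=0.104, z_step=0.2)
corrected = apply_visser(stack, params)
print(f"a 58-plane stack spans {stack.z_step * 57:.1f} µm nominally, "
      f"but only {corrected.z_step * 57:.1f} µm of physical depth")
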