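"""Geometric bookkeeping for a micro-well: contact area, cell volume, seeding.

A cell filling a closed-bottom cylindrical well touches the gel over the
wall plus the floor.  For the small-well dimensions (radius 5.5 µm, depth
11.5 µm) that area is ≈ 500 µm² — the lever arm that turns a ~180 Pa
outward traction into a ~90 nN net pushing force.
"""

import numpy as np

from welltfm import WellGeometry
from welltfm.metrics import cell_volume, contact_area
from welltfm.piv import particles_per_box

small = WellGeometry(radius=5.5, depth=11.5, gel_height=100.0,
                     fillet_bottom=0.0, fillet_top=0.0)
area = contact_area(small)
print(f"small-well contact area:   {area:7.1f} µm²   (wall + closed bottom)")
print(f"180 Pa over that area:     {180 * area / 1e3:7.1f} nN net pushing force")

small_v = cell_volume(WellGeometry(radius=5.25, depth=11.5, gel_height=100.0))
large_v = cell_volume(WellGeometry(radius=7.5, depth=11.5, gel_height=100.0))
print(f"small-well cell volume:    {small_v:7.0f} µm³ (cylinder approximation)")
print(f"large-well cell volume:    {large_v:7.0f} µm³")

n = particles_per_box(0.0005, (32, 32, 8))
print(f"beads per 32×32×8 box at 0.0005/voxel: {n:.3f}  (≈4: the density "
      "above which volumetric PIV error saturates)")
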