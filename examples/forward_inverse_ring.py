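"""Forward–inverse traction oracle on a coarse well mesh.

Prescribes a 500 Pa inward ring on the well wall, solves the forward
elastic problem, and reconstructs the tractions from the resulting
(noiseless) surface displacements with zero regularization.  The
reconstruction is exact up to numerical round-off because the data are
perfectly consistent with the model.
"""

import numpy as np

from welltfm import MaterialModel, WellGeometry, fem, inverse
from welltfm.pipeline import ring_traction

geometry = WellGeometry(radius=7.5, depth=11.5, gel_height=100.0)
mesh = fem.build_mesh(geometry, target_edge_length=2.5)
print(f"mesh: {mesh.n_nodes} nodes, {len(mesh.tets)} tetrahedra")

truth = fem.TractionField.from_function(
    mesh, ("well_wall", "well_bottom"), ring_traction(geometry, -500.0)
)
op = inverse.InverseOperator(mesh, MaterialModel(youngs_modulus=15000.0))
u = op.forward_displacement(truth)
print(f"peak gel displacement under the ring: {np.linalg.norm(u, axis=1).max():.4f} µm")

measured = inverse.SurfaceDisplacements(
    op.m_nodes, u[op.m_nodes], np.zeros(len(op.m_nodes), bool)
)
result = op.solve(measured, inverse.InverseConfig(regularization_lambda=0.0))
a = truth.areas
rms = np.sqrt(
    (a * ((result.traction.tractions - truth.tractions) ** 2).sum(1)).sum()
    / (a * (truth.tractions**2).sum(1)).sum()
)
print(f"traction RMS reconstruction error: {100 * rms:.2e} %")
print(f"displacement misfit: {result.misfit:.2e} µm²·µm²")
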