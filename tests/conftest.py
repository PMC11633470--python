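"""Shared fixtures: meshes, operators and the synthetic closed loop.

The heavy objects (fine mesh + factorized inverse operator, and the full
synthetic bead-stack loop) are session-scoped so that unit tests and the
acceptance suite share one build each.
"""

from __future__ import annotations

import numpy as np
import pytest

from welltfm import fem, inverse, pipeline
from welltfm.geometry import WellGeometry

# large-well geometry (≈15 µm diameter, 11.5 µm deep, 100 µm gel)
LARGE_WELL = WellGeometry(
    radius=7.5, depth=11.5, gel_height=100.0, lateral_extent=100.0
)


@pytest.fixture(scope="session")
def fine_setup():
    """~10k-node mesh of the large well with a ready inverse operator."""
    mesh = fem.build_mesh(LARGE_WELL, 1.5)
    material = fem.MaterialModel()
    op = inverse.InverseOperator(mesh, material)
    return LARGE_WELL, mesh, material, op


@pytest.fixture(scope="session")
def loop_result():
    """Full synthetic closed loop (render → PIV → inverse), seed 1."""
    return pipeline.run_synthetic_loop(seed=1)


def ring_field(geometry, magnitude=-500.0, half_width=1.0):
    return pipeline.ring_traction(geometry, magnitude, half_width=half_width)


@pytest.fixture(scope="session")
def fine_ring_recovery(fine_setup):
    """Noiseless forward→inverse round trip of a 500 Pa inward wall ring."""
    geometry, mesh, material, op = fine_setup
    truth = fem.TractionField.from_function(
        mesh, ("well_wall", "well_bottom"), ring_field(geometry)
    )
    u = op.forward_displacement(truth)
    measured = inverse.SurfaceDisplacements(
        node_ids=op.m_nodes,
        displacements=u[op.m_nodes],
        extrapolated=np.zeros(len(op.m_nodes), bool),
    )
    result = op.solve(measured, inverse.InverseConfig(0.0))
    return truth, result, u
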