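"""Meshing and the forward elastic problem."""

import numpy as np
import pytest

from welltfm import fem
from welltfm.errors import MeshingError, SolverError
from welltfm.fem import (
    MaterialModel,
    TractionField,
    assemble_stiffness,
    box_mesh,
    build_mesh,
    facet_areas,
    interpolate_nodal_field,
    lumped_node_areas,
    nodal_force_to_traction,
    solve_forward,
    solve_linear,
    traction_to_loads,
)
from welltfm.geometry import WellGeometry
from welltfm.pipeline import ring_traction

SMALL = WellGeometry(radius=5.0, depth=8.0, gel_height=25.0, lateral_extent=30.0)


def analytic_boundary_areas(g: WellGeometry) -> dict:
    """Independent closed-form areas of the filleted solid (Pappus)."""
    R, d, fb, ft = g.radius, g.depth, g.fillet_bottom, g.fillet_top
    L, H = g.lateral_extent, g.gel_height
    return {
        "base": L**2,
        "lateral": 4 * L * H,
        "gel_top": L**2 - np.pi * (R + ft) ** 2,
        "well_wall": 2 * np.pi * R * (d - fb - ft)
        + 2 * np.pi * ft * ((R + ft) * np.pi / 2 - ft),
        "well_bottom": np.pi * (R - fb) ** 2
        + 2 * np.pi * fb * ((R - fb) * np.pi / 2 + fb),
    }


def analytic_cavity_volume(g: WellGeometry) -> float:
    """Filleted-cylinder volume by numerical quadrature of the profile."""
    R, d, fb, ft = g.radius, g.depth, g.fillet_bottom, g.fillet_top
    z = np.linspace(0, d, 4001)
    r = np.full_like(z, R)
    if fb > 0:
        lo = z <= fb
        r[lo] = (R - fb) + np.sqrt(np.maximum(fb**2 - (fb - z[lo]) ** 2, 0))
    if ft > 0:
        hi = z >= d - ft
        r[hi] = (R + ft) - np.sqrt(np.maximum(ft**2 - (z[hi] - (d - ft)) ** 2, 0))
    return float(np.trapezoid(np.pi * r**2, z))


class TestBuildMesh:
    def test_boundary_areas_match_analytic(self, fine_setup):
        geometry, mesh, _, _ = fine_setup
        analytic = analytic_boundary_areas(geometry)
        total_a = sum(analytic.values())
        total_m = sum(
            facet_areas(mesh, f).sum() for f in mesh.surface_groups.values()
        )
        assert total_m == pytest.approx(total_a, rel=0.02)
        for name in ("well_wall", "well_bottom", "gel_top"):
            area = facet_areas(mesh, mesh.surface_groups[name]).sum()
            assert area == pytest.approx(analytic[name], rel=0.02), name

    def test_cavity_volume_matches_analytic(self, fine_setup):
        geometry, mesh, _, _ = fine_setup
        solid = np.abs(mesh.volumes()).sum()
        prism = geometry.lateral_extent**2 * geometry.gel_height
        cavity = prism - solid
        assert cavity == pytest.approx(analytic_cavity_volume(geometry), rel=0.03)

    def test_sharp_cavity_volume(self):
        g = WellGeometry(radius=5.0, depth=8.0, gel_height=20.0,
                         lateral_extent=24.0, fillet_bottom=0.0, fillet_top=0.0)
        mesh = build_mesh(g, 1.2)
        cavity = g.lateral_extent**2 * g.gel_height - np.abs(mesh.volumes()).sum()
        assert cavity == pytest.approx(np.pi * g.radius**2 * g.depth, rel=0.01)

    def test_conforming_and_positively_oriented(self):
        mesh = build_mesh(SMALL, 2.0)
        assert (mesh.volumes() > 0).all()
        faces = np.concatenate(
            [mesh.tets[:, c] for c in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3))]
        )
        _, counts = np.unique(np.sort(faces, axis=1), axis=0, return_counts=True)
        assert set(counts.tolist()) <= {1, 2}
        n_boundary = (counts == 1).sum()
        assert n_boundary == sum(len(f) for f in mesh.surface_groups.values())

    def test_surface_groups_disjoint_cover_boundary(self):
        mesh = build_mesh(SMALL, 2.0)
        keys = [np.sort(f, axis=1) for f in mesh.surface_groups.values()]
        allk = np.concatenate(keys)
        assert len(np.unique(allk, axis=0)) == len(allk)

    def test_too_coarse_edge_rejected(self):
        with pytest.raises(MeshingError):
            build_mesh(SMALL, 3.0)  # >= radius/2


class TestSolveForward:
    def test_zero_traction_zero_displacement(self):
        mesh = build_mesh(SMALL, 2.0)
        mat = MaterialModel()
        ids = mesh.group_nodes("well_wall")
        T = TractionField(
            node_ids=ids,
            tractions=np.zeros((len(ids), 3)),
            areas=lumped_node_areas(mesh, ("well_wall", "well_bottom"))[ids],
        )
        u = solve_forward(mesh, mat, T)
        assert np.abs(u).max() <= 1e-12

    def test_confined_compression_closed_form(self):
        # uniaxial-strain slab: uz(top) = -p·h·(1+ν)(1−2ν) / (E(1−ν))
        mesh = box_mesh(10.0, 10.0, 5.0, 5, 5, 4)
        E, nu, p, h = 15000.0, 0.45, 100.0, 5.0
        mat = MaterialModel(youngs_modulus=E, poisson_ratio=nu)
        K = assemble_stiffness(mesh, mat)
        top = mesh.group_nodes("gel_top")
        T = TractionField(
            node_ids=top,
            tractions=np.tile([0, 0, -p], (len(top), 1)),
            areas=lumped_node_areas(mesh, ("gel_top",))[top],
        )
        loads = traction_to_loads(mesh, T, groups=("gel_top",))
        base = mesh.group_nodes("base")
        lat = mesh.group_nodes("lateral")
        fixed = np.concatenate(
            [
                (3 * base[:, None] + np.arange(3)).ravel(),
                3 * lat, 3 * lat + 1,  # lateral rollers: ux = uy = 0
            ]
        )
        u, _ = solve_linear(K, loads, np.unique(fixed))
        expect = -p * h * (1 + nu) * (1 - 2 * nu) / (E * (1 - nu))
        np.testing.assert_allclose(u[top, 2], expect, rtol=1e-8)

    def test_global_equilibrium(self, fine_setup, fine_ring_recovery):
        geometry, mesh, material, op = fine_setup
        truth, _, u = fine_ring_recovery
        loads = traction_to_loads(mesh, truth)
        r = (op.K @ u.reshape(-1)).reshape(-1, 3) - loads
        base = mesh.group_nodes("base")
        total_reaction = r[base].sum(axis=0)
        total_load = loads.sum(axis=0)
        scale = np.abs(truth.tractions).max() * truth.areas.sum()
        np.testing.assert_allclose(
            total_reaction, -total_load, atol=1e-6 * scale
        )

    def test_linearity(self):
        mesh = build_mesh(SMALL, 2.0)
        mat = MaterialModel()
        K = assemble_stiffness(mesh, mat)
        T1 = TractionField.from_function(
            mesh, ("well_wall", "well_bottom"), ring_traction(SMALL, -200.0)
        )
        T3 = TractionField.from_function(
            mesh, ("well_wall", "well_bottom"), ring_traction(SMALL, -600.0)
        )
        u1 = solve_forward(mesh, mat, T1, K=K)
        u3 = solve_forward(mesh, mat, T3, K=K)
        np.testing.assert_allclose(u3, 3 * u1, atol=1e-10 * np.abs(u1).max())

    def test_patch_test_exact(self):
        # a linear displacement field imposed on the whole boundary is
        # reproduced exactly in the interior (conforming linear elements)
        mesh = build_mesh(SMALL, 1.6)
        K = assemble_stiffness(mesh, MaterialModel())
        A = np.array([[0.01, 0.004, 0.002], [0.001, -0.006, 0.003],
                      [0.002, 0.005, -0.004]])
        u_exact = mesh.nodes @ A.T
        bnodes = np.unique(mesh.boundary_facets())
        fixed = (3 * bnodes[:, None] + np.arange(3)).ravel()
        u, _ = solve_linear(K, np.zeros((mesh.n_nodes, 3)), fixed,
                            u_exact[bnodes].ravel())
        np.testing.assert_allclose(u, u_exact, atol=1e-12)

    def test_mirror_symmetric_load_gives_mirror_symmetric_field(self):
        from scipy.spatial import cKDTree

        mesh = build_mesh(SMALL, 1.2)
        mat = MaterialModel()
        T = TractionField.from_function(
            mesh, ("well_wall", "well_bottom"),
            ring_traction(SMALL, -500.0, half_width=1.5, profile="gaussian"),
        )
        u = solve_forward(mesh, mat, T)
        mirrored = mesh.nodes * [1, -1, 1]
        dist, idx = cKDTree(mesh.nodes).query(mirrored)
        ok = dist < 1e-6  # nodes with an exact mirror partner
        assert ok.all()
        u_m = u[idx[ok]] * [1, -1, 1]
        # the node set is mirror-symmetric but the tetrahedral diagonals are
        # not, so agreement is at discretization accuracy
        rel = np.linalg.norm(u[ok] - u_m) / np.linalg.norm(u[ok])
        assert rel <= 0.15

    def test_singular_without_constraints(self):
        mesh = box_mesh(4, 4, 4, 2, 2, 2)
        K = assemble_stiffness(mesh, MaterialModel())
        with pytest.raises(SolverError):
            solve_linear(K, np.zeros((mesh.n_nodes, 3)), np.array([], dtype=int))

    def test_neo_hookean_matches_linear_at_small_strain(self):
        mesh = build_mesh(SMALL, 2.2)
        lin = MaterialModel(law="linear")
        nh = MaterialModel(law="neo_hookean")
        K = assemble_stiffness(mesh, lin)
        T = TractionField.from_function(
            mesh, ("well_wall", "well_bottom"), ring_traction(SMALL, -50.0)
        )
        u_lin = solve_forward(mesh, lin, T, K=K)
        u_nh = solve_forward(mesh, nh, T, K=K)
        rel = np.linalg.norm(u_nh - u_lin) / np.linalg.norm(u_lin)
        assert rel < 0.01

    def test_mesh_convergence_slow_tier(self):
        # slow tier: the mean radial wall displacement converges as the
        # edge length is halved twice — successive changes shrink by at
        # least half, with the finest increment below 5%
        mat = MaterialModel()
        vals = []
        for h in (2.0, 1.0, 0.5):
            mesh = build_mesh(SMALL, h)
            T = TractionField.from_function(
                mesh, ("well_wall", "well_bottom"),
                ring_traction(SMALL, -500.0, half_width=1.5,
                              profile="gaussian"),
            )
            u = solve_forward(mesh, mat, T)
            ids = mesh.group_nodes("well_wall")
            a = lumped_node_areas(mesh, ("well_wall",))[ids]
            th = np.arctan2(mesh.nodes[ids, 1], mesh.nodes[ids, 0])
            ur = u[ids, 0] * np.cos(th) + u[ids, 1] * np.sin(th)
            vals.append((a * ur).sum() / a.sum())
        c1 = abs(vals[1] - vals[0]) / abs(vals[1])
        c2 = abs(vals[2] - vals[1]) / abs(vals[2])
        assert c2 < 0.5 * c1
        assert c2 < 0.05


class TestTractionConversion:
    def test_force_to_traction_definition(self):
        mesh = box_mesh(6, 6, 3, 3, 3, 2)
        top = mesh.group_nodes("gel_top")
        areas = lumped_node_areas(mesh, ("gel_top",))[top]
        node = top[np.argmax(areas)]
        a = areas.max()
        forces = np.array([[2.0 * a, 0.0, 0.0]])  # pN
        tf = nodal_force_to_traction(
            mesh, np.array([node]), forces, groups=("gel_top",)
        )
        assert tf.tractions[0, 0] == pytest.approx(2.0)  # Pa = pN/µm²

    def test_zero_forces_zero_tractions(self):
        mesh = box_mesh(6, 6, 3, 3, 3, 2)
        top = mesh.group_nodes("gel_top")
        tf = nodal_force_to_traction(
            mesh, top, np.zeros((len(top), 3)), groups=("gel_top",)
        )
        assert not tf.tractions.any()

    def test_total_force_conserved_exactly(self):
        mesh = box_mesh(6, 6, 3, 3, 3, 2)
        top = mesh.group_nodes("gel_top")
        rng = np.random.default_rng(0)
        forces = rng.normal(0, 5, (len(top), 3))
        tf = nodal_force_to_traction(mesh, top, forces, groups=("gel_top",))
        np.testing.assert_allclose(
            tf.total_force(), forces.sum(axis=0), rtol=1e-12
        )

    def test_uniform_pressure_round_trip(self):
        # assemble consistent loads from uniform p, invert via lumped areas
        mesh = box_mesh(10, 10, 4, 5, 5, 2)
        top = mesh.group_nodes("gel_top")
        p = 250.0
        T = TractionField(
            node_ids=top,
            tractions=np.tile([0, 0, p], (len(top), 1)),
            areas=lumped_node_areas(mesh, ("gel_top",))[top],
        )
        loads = traction_to_loads(mesh, T, groups=("gel_top",))
        rec = nodal_force_to_traction(mesh, top, loads[top], groups=("gel_top",))
        np.testing.assert_allclose(rec.tractions[:, 2], p, rtol=0.01)

    def test_off_surface_node_rejected(self):
        mesh = box_mesh(6, 6, 3, 3, 3, 2)
        interior = np.setdiff1d(
            np.arange(mesh.n_nodes), mesh.boundary_facets().ravel()
        )
        with pytest.raises(ValueError):
            nodal_force_to_traction(
                mesh, interior[:1], np.ones((1, 3)), groups=("gel_top",)
            )


class TestInterpolateNodalField:
    def test_affine_field_reproduced(self):
        mesh = build_mesh(SMALL, 2.0)
        A = np.array([[0.1, 0.02, 0.0], [0.0, -0.05, 0.01], [0.03, 0.0, 0.2]])
        b = np.array([1.0, -2.0, 0.5])
        vals = mesh.nodes @ A.T + b
        rng = np.random.default_rng(0)
        # probe points strictly inside the gel, outside the cavity
        pts = rng.uniform(
            [SMALL.radius + 1, -14, SMALL.base_z + 1], [14, 14, SMALL.top_z - 1],
            (50, 3),
        )
        out = interpolate_nodal_field(mesh, vals, pts)
        np.testing.assert_allclose(out, pts @ A.T + b, atol=1e-8)
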