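"""Inverse traction reconstruction and the direct-Dirichlet diagnostic."""

import numpy as np
import pytest

from welltfm import fem, inverse
from welltfm.errors import ConfigError, CoverageError
from welltfm.inverse import (
    InverseConfig,
    SurfaceDisplacements,
    direct_dirichlet_solve,
    interpolate_measured_to_surface,
    misfit,
)
from welltfm.piv import DisplacementField


def _field(points, vectors):
    n = len(points)
    return DisplacementField(
        points=points, vectors=vectors,
        valid=np.ones(n, bool), quality=np.ones(n),
    )


def _traction_on(mesh, tf, group_nodes):
    lut = {n: i for i, n in enumerate(tf.node_ids)}
    rows = [lut[n] for n in group_nodes if n in lut]
    return tf.tractions[rows]


class TestInterpolateMeasuredToSurface:
    def test_constant_field_reproduced(self, loop_result):
        mesh = loop_result["mesh"]
        lo = mesh.nodes.min(axis=0) - 1
        hi = mesh.nodes.max(axis=0) + 1
        g = np.stack(
            np.meshgrid(*[np.linspace(a, b, 8) for a, b in zip(lo, hi)],
                        indexing="ij"), axis=-1,
        ).reshape(-1, 3)
        u0 = np.array([0.2, -0.1, 0.05])
        out = interpolate_measured_to_surface(
            _field(g, np.tile(u0, (len(g), 1))), mesh
        )
        np.testing.assert_allclose(
            out.displacements, np.tile(u0, (len(out.displacements), 1)),
            atol=1e-10,
        )
        assert not out.extrapolated.any()

    def test_affine_field_reproduced(self, loop_result):
        mesh = loop_result["mesh"]
        lo = mesh.nodes.min(axis=0) - 1
        hi = mesh.nodes.max(axis=0) + 1
        g = np.stack(
            np.meshgrid(*[np.linspace(a, b, 10) for a, b in zip(lo, hi)],
                        indexing="ij"), axis=-1,
        ).reshape(-1, 3)
        A = np.array([[0.01, 0.002, 0], [0, -0.005, 0.001], [0.003, 0, 0.02]])
        out = interpolate_measured_to_surface(_field(g, g @ A.T), mesh)
        expect = mesh.nodes[out.node_ids] @ A.T
        scale = np.abs(expect).max()
        np.testing.assert_allclose(out.displacements, expect, atol=1e-6 * scale)

    def test_nodes_outside_hull_flagged(self, loop_result):
        mesh = loop_result["mesh"]
        # samples covering only a thin sub-box: most surface nodes outside
        rng = np.random.default_rng(0)
        g = rng.uniform([10, 10, -5], [20, 20, 0], (200, 3))
        out = interpolate_measured_to_surface(
            _field(g, np.zeros((len(g), 3))), mesh
        )
        assert out.extrapolated.any()
        assert np.isfinite(out.displacements).all()

    def test_too_few_samples(self, loop_result):
        mesh = loop_result["mesh"]
        with pytest.raises(CoverageError):
            interpolate_measured_to_surface(
                _field(np.zeros((3, 3)), np.zeros((3, 3))), mesh
            )


class TestMisfit:
    def test_identical_fields_zero(self):
        u = np.random.default_rng(0).normal(size=(10, 3))
        assert misfit(u, u) == 0.0

    def test_single_node_definition(self):
        a = np.zeros((1, 3))
        b = np.array([[0.1, 0.0, 0.0]])
        assert misfit(a, b, np.ones(1)) == pytest.approx(0.01)

    def test_triangle_inequality_of_rms(self):
        rng = np.random.default_rng(1)
        w = rng.uniform(0.5, 2.0, 20)
        a, b, c = rng.normal(size=(3, 20, 3))
        d_ab = np.sqrt(misfit(a, b, w))
        d_bc = np.sqrt(misfit(b, c, w))
        d_ac = np.sqrt(misfit(a, c, w))
        assert d_ac <= d_ab + d_bc + 1e-12

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            misfit(np.zeros((3, 3)), np.zeros((4, 3)))


class TestSolveInverse:
    def test_noiseless_ring_recovered(self, fine_setup, fine_ring_recovery):
        _, mesh, _, op = fine_setup
        truth, result, _ = fine_ring_recovery
        t_true = truth.tractions
        t_rec = result.traction.tractions
        a = truth.areas
        err = np.sqrt(
            (a * ((t_rec - t_true) ** 2).sum(1)).sum()
            / (a * (t_true**2).sum(1)).sum()
        )
        assert err <= 0.05
        assert result.misfit <= 1e-12

    def test_zero_data_zero_traction(self, loop_result):
        op = loop_result["operator"]
        meas = SurfaceDisplacements(
            op.m_nodes, np.zeros((len(op.m_nodes), 3)),
            np.zeros(len(op.m_nodes), bool),
        )
        res = op.solve(meas, InverseConfig(regularization_lambda=1e-6))
        assert np.abs(res.traction.tractions).max() <= 1e-12
        assert res.misfit <= 1e-20

    def test_gel_top_traction_free_by_construction(self, loop_result):
        op, mesh = loop_result["operator"], loop_result["mesh"]
        top = set(mesh.group_nodes("gel_top").tolist())
        well = set(mesh.group_nodes("well_wall", "well_bottom").tolist())
        claimed = set(loop_result["result"].traction.node_ids.tolist())
        assert claimed <= well
        # rim nodes shared with the top are allowed; strictly-top nodes not
        assert not (claimed - well) & top

    def test_misfit_monotone_in_lambda(self, loop_result):
        op = loop_result["operator"]
        meas = interpolate_measured_to_surface(
            loop_result["displacement_field"], loop_result["mesh"]
        )
        misfits = [
            op.solve(meas, InverseConfig(lam)).misfit
            for lam in (1e-6, 1e-8, 1e-10)
        ]
        assert misfits[0] >= misfits[1] >= misfits[2]

    def test_negative_lambda_rejected(self):
        with pytest.raises(ConfigError):
            InverseConfig(regularization_lambda=-1.0)

    def test_noise_floor_scales_linearly(self, loop_result):
        # zero-signal reconstructions scale linearly with displacement
        # noise SD: code analogue of the empty-well noise characterization
        op = loop_result["operator"]
        sds = np.array([0.005, 0.01, 0.02])
        means = []
        for i, sd in enumerate(sds):
            mags = []
            for seed in (10 + i, 20 + i):
                rng = np.random.default_rng(seed)
                noise = rng.normal(0, sd, (len(op.m_nodes), 3))
                meas = SurfaceDisplacements(
                    op.m_nodes, noise, np.zeros(len(op.m_nodes), bool)
                )
                res = op.solve(meas, InverseConfig(1e-9))
                mags.append(
                    np.linalg.norm(res.traction.tractions, axis=1).mean()
                )
            means.append(np.mean(mags))
        slope = np.polyfit(np.log(sds), np.log(means), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)


class TestDirectDirichlet:
    def test_consistent_data_no_top_artifact(self, loop_result):
        geometry, mesh = loop_result["geometry"], loop_result["mesh"]
        op, truth = loop_result["operator"], loop_result["truth"]
        mat = fem.MaterialModel()
        u = op.forward_displacement(truth)
        ids = op.m_nodes
        clean = SurfaceDisplacements(
            ids, u[ids], np.zeros(len(ids), bool)
        )
        td = direct_dirichlet_solve(mesh, mat, clean, K=op.K)
        top_mag = np.linalg.norm(
            _traction_on(mesh, td, mesh.group_nodes("gel_top")), axis=1
        )
        assert top_mag.mean() < 1.0  # Pa; vanishes for consistent data
        # well-wall tractions match the prescription within discretization
        wall_nodes = mesh.group_nodes("well_wall")
        t_direct = _traction_on(mesh, td, wall_nodes)
        t_true = np.zeros((mesh.n_nodes, 3))
        t_true[truth.node_ids] = truth.tractions
        rms = np.sqrt(((t_direct - t_true[wall_nodes]) ** 2).sum(1).mean())
        assert rms < 0.25 * np.abs(truth.tractions).max()

    def test_noise_leaks_into_top_tractions(self, loop_result):
        mesh, op, truth = (
            loop_result["mesh"], loop_result["operator"], loop_result["truth"]
        )
        mat = fem.MaterialModel()
        u = op.forward_displacement(truth)
        ids = op.m_nodes
        rng = np.random.default_rng(0)
        top_nodes = mesh.group_nodes("gel_top")

        def top_mean(meas):
            td = direct_dirichlet_solve(mesh, mat, meas, K=op.K)
            return np.linalg.norm(
                _traction_on(mesh, td, top_nodes), axis=1
            ).mean()

        clean = top_mean(
            SurfaceDisplacements(ids, u[ids], np.zeros(len(ids), bool))
        )
        noisy = top_mean(
            SurfaceDisplacements(
                ids, u[ids] + rng.normal(0, 0.01, (len(ids), 3)),
                np.zeros(len(ids), bool),
            )
        )
        assert noisy > 3 * clean + 1.0

    def test_zero_data_zero_tractions(self, loop_result):
        mesh, op = loop_result["mesh"], loop_result["operator"]
        mat = fem.MaterialModel()
        ids = op.m_nodes
        td = direct_dirichlet_solve(
            mesh, mat,
            SurfaceDisplacements(ids, np.zeros((len(ids), 3)),
                                 np.zeros(len(ids), bool)),
            K=op.K,
        )
        assert np.abs(td.tractions).max() <= 1e-9
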