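"""Cylindrical decomposition, unfolded maps and profiles."""

import numpy as np
import pytest

from welltfm import fem, unfold
from welltfm.fem import TractionField, build_mesh, lumped_node_areas
from welltfm.geometry import WellGeometry
from welltfm.unfold import (
    TractionProfiles,
    align_profiles,
    circumferential_profile,
    decompose_bottom,
    decompose_wall,
    radial_profile,
    unfold_bottom_map,
    unfold_wall_map,
)

GEOM = WellGeometry(radius=5.0, depth=8.0, gel_height=25.0, lateral_extent=30.0)


@pytest.fixture(scope="module")
def mesh():
    return build_mesh(GEOM, 2.0)


def wall_traction_field(mesh, fn):
    ids = mesh.group_nodes("well_wall", "well_bottom")
    areas = lumped_node_areas(mesh, ("well_wall", "well_bottom"))[ids]
    return TractionField(node_ids=ids, tractions=fn(mesh.nodes[ids]), areas=areas)


class TestDecomposeWall:
    def test_aligned_frame(self, mesh):
        # at θ=0 a +x traction is purely normal (outward)
        tf = wall_traction_field(
            mesh, lambda x: np.tile([100.0, 0, 0], (len(x), 1))
        )
        wc = decompose_wall(tf, mesh, GEOM)
        at0 = np.argmin(np.abs(np.angle(np.exp(1j * wc.theta))))
        assert wc.components[at0, 0] == pytest.approx(100.0, abs=1e-6)
        assert wc.components[at0, 1] == pytest.approx(0.0, abs=1e-6)
        assert wc.components[at0, 2] == pytest.approx(0.0, abs=1e-6)

    def test_rotated_frame(self, mesh):
        # at θ=90° a −y traction is inward (contractile): T_n = −100
        tf = wall_traction_field(
            mesh, lambda x: np.tile([0, -100.0, 0], (len(x), 1))
        )
        wc = decompose_wall(tf, mesh, GEOM)
        at90 = np.argmin(np.abs(wc.theta - np.pi / 2))
        assert abs(wc.theta[at90] - np.pi / 2) < 1e-9  # node exists at 90°
        assert wc.components[at90, 0] == pytest.approx(-100.0, abs=1e-6)
        assert abs(wc.components[at90, 1]) < 1e-9
        assert abs(wc.components[at90, 2]) < 1e-9

    def test_magnitude_conserved(self, mesh):
        rng = np.random.default_rng(0)
        tf = wall_traction_field(
            mesh, lambda x: rng.normal(0, 300, (len(x), 3))
        )
        wc = decompose_wall(tf, mesh, GEOM)
        lut = {n: i for i, n in enumerate(tf.node_ids)}
        orig = tf.tractions[[lut[n] for n in wc.node_ids]]
        np.testing.assert_allclose(
            (wc.components**2).sum(1), (orig**2).sum(1), rtol=1e-10
        )

    def test_round_trip_recomposition(self, mesh):
        rng = np.random.default_rng(1)
        tf = wall_traction_field(
            mesh, lambda x: rng.normal(0, 300, (len(x), 3))
        )
        wc = decompose_wall(tf, mesh, GEOM)
        n_hat = np.column_stack(
            [np.cos(wc.theta), np.sin(wc.theta), np.zeros_like(wc.theta)]
        )
        c_hat = np.column_stack(
            [-np.sin(wc.theta), np.cos(wc.theta), np.zeros_like(wc.theta)]
        )
        z_hat = np.tile([0.0, 0.0, 1.0], (len(wc.theta), 1))
        recomposed = (
            wc.components[:, :1] * n_hat
            + wc.components[:, 1:2] * z_hat
            + wc.components[:, 2:3] * c_hat
        )
        lut = {n: i for i, n in enumerate(tf.node_ids)}
        orig = tf.tractions[[lut[n] for n in wc.node_ids]]
        np.testing.assert_allclose(recomposed, orig, atol=1e-10 * 300)


class TestDecomposeBottom:
    def test_inward_radial_negative(self, mesh):
        # a −x traction at a node on the +x radius pulls toward the center
        tf = wall_traction_field(
            mesh, lambda x: np.tile([-200.0, 0, 0], (len(x), 1))
        )
        bc = decompose_bottom(tf, mesh, GEOM)
        onx = (np.abs(bc.theta) < 1e-9) & (bc.r > 1.0)
        assert onx.any()
        np.testing.assert_allclose(bc.component("T_r")[onx], -200.0, atol=1e-9)

    def test_axis_node_degenerate(self, mesh):
        tf = wall_traction_field(
            mesh, lambda x: np.tile([50.0, 60.0, -70.0], (len(x), 1))
        )
        bc = decompose_bottom(tf, mesh, GEOM)
        center = bc.r < 1e-9
        assert center.sum() == 1
        assert bc.axis_degenerate[center].all()
        assert bc.component("T_r")[center] == 0.0
        assert bc.component("T_c")[center] == 0.0
        assert bc.component("T_n")[center] == pytest.approx(-70.0)


class TestUnfoldWallMap:
    def test_constant_field_gives_constant_map(self, mesh):
        tf = wall_traction_field(mesh, lambda x: np.zeros((len(x), 3)))
        wc = decompose_wall(tf, mesh, GEOM)
        wc.components[:, 0] = 300.0
        m = unfold_wall_map(wc, GEOM, "T_n")
        np.testing.assert_allclose(m.values, 300.0, atol=1e-9)

    def test_excluded_band_removes_top(self, mesh):
        tf = wall_traction_field(mesh, lambda x: np.zeros((len(x), 3)))
        wc = decompose_wall(tf, mesh, GEOM)
        m = unfold_wall_map(wc, GEOM, "T_n", excluded_band=1.0)
        assert m.z.max() == pytest.approx(GEOM.top_z - 1.0)
        assert m.z.min() == pytest.approx(GEOM.bottom_z + GEOM.fillet_bottom)

    def test_linear_in_z_reproduced(self, mesh):
        tf = wall_traction_field(mesh, lambda x: np.zeros((len(x), 3)))
        wc = decompose_wall(tf, mesh, GEOM)
        wc.components[:, 0] = 10.0 * wc.z
        m = unfold_wall_map(wc, GEOM, "T_n")
        expect = 10.0 * m.z
        for col in range(m.values.shape[1]):
            np.testing.assert_allclose(m.values[:, col], expect, rtol=1e-6)

    def test_smooth_azimuthal_field_continuous_across_seam(self, mesh):
        tf = wall_traction_field(mesh, lambda x: np.zeros((len(x), 3)))
        wc = decompose_wall(tf, mesh, GEOM)
        wc.components[:, 0] = 100.0 * np.cos(wc.theta)
        m = unfold_wall_map(wc, GEOM, "T_n", n_theta=120)
        expect = 100.0 * np.cos(np.radians(m.theta_deg))
        assert np.abs(m.values - expect[None, :]).max() < 2.0  # Pa
        assert np.isfinite(m.values).all()

    def test_area_weighted_map_mean_matches_node_mean(self, mesh):
        tf = wall_traction_field(mesh, lambda x: np.zeros((len(x), 3)))
        wc = decompose_wall(tf, mesh, GEOM)
        wc.components[:, 0] = 50.0 + 20.0 * np.sin(wc.z) + 30.0 * np.cos(wc.theta)
        m = unfold_wall_map(wc, GEOM, "T_n", excluded_band=0.0)
        node_mean = (wc.areas * wc.components[:, 0]).sum() / wc.areas.sum()
        assert m.values.mean() == pytest.approx(node_mean, rel=0.03, abs=1.5)

    def test_empty_components_raise(self, mesh):
        tf = wall_traction_field(mesh, lambda x: np.zeros((len(x), 3)))
        wc = decompose_wall(tf, mesh, GEOM)
        wc.theta = wc.theta[:0]
        with pytest.raises(ValueError):
            unfold_wall_map(wc, GEOM, "T_n")


class TestProfiles:
    def _map(self, values, z=None):
        ny, nx = values.shape
        return unfold.UnfoldedMap(
            axis0=np.linspace(0, 360, nx, endpoint=False),
            axis1=np.linspace(-8, 0, ny) if z is None else z,
            values=values, component="T_n",
        )

    def test_uniform_map_profile(self):
        p = circumferential_profile(self._map(np.full((10, 36), 7.0)))
        np.testing.assert_allclose(p.mean, 7.0)
        np.testing.assert_allclose(p.std, 0.0)

    def test_sinusoidal_map_statistics(self):
        theta = np.radians(np.linspace(0, 360, 180, endpoint=False))
        A = 40.0
        vals = np.tile(A * np.sin(theta), (5, 1))
        p = circumferential_profile(self._map(vals))
        np.testing.assert_allclose(p.mean, 0.0, atol=1e-9)
        np.testing.assert_allclose(p.std, A / np.sqrt(2), rtol=0.01)

    def test_single_row_map(self):
        p = circumferential_profile(self._map(np.ones((1, 12)), z=np.array([0.0])))
        assert len(p.abscissa) == 1

    def test_radial_profile_bins(self, mesh):
        tf = wall_traction_field(mesh, lambda x: np.zeros((len(x), 3)))
        bc = decompose_bottom(tf, mesh, GEOM)
        bc.components[:, 1] = 2.0 * bc.r
        p = radial_profile(bc, GEOM, "T_r", bin_width=1.0)
        assert (np.diff(p.abscissa) > 0).all()
        np.testing.assert_allclose(p.mean, 2.0 * p.abscissa, atol=1.0)

    def test_bottom_map_masked_to_disk(self, mesh):
        tf = wall_traction_field(mesh, lambda x: np.zeros((len(x), 3)))
        bc = decompose_bottom(tf, mesh, GEOM)
        bc.components[:, 0] = 5.0
        m = unfold_bottom_map(bc, GEOM, "T_n", n_xy=40)
        XX, YY = np.meshgrid(m.axis0, m.axis1)
        rr = np.hypot(XX, YY)
        assert np.isnan(m.values[rr > GEOM.radius]).all()
        np.testing.assert_allclose(
            m.values[rr <= GEOM.radius * 0.9], 5.0, atol=1e-6
        )


class TestAlignProfiles:
    def _profile(self, z0, z1, n):
        z = np.linspace(z0, z1, n)
        return TractionProfiles(
            component="T_n", abscissa=z, mean=np.ones(n), std=np.zeros(n),
            n=np.full(n, 10),
        )

    def test_depths_11_and_12_aligned_at_bottom(self):
        p11 = self._profile(-11.0, 0.0, 23)
        p12 = self._profile(-12.0, 0.0, 25)
        a11, a12 = align_profiles([p11, p12])
        assert a11.abscissa[0] == 0.0 and a12.abscissa[0] == 0.0
        assert a11.displayed.all()
        # the extra top micron of the deeper profile is not displayed
        hidden = ~a12.displayed
        assert hidden.any()
        assert (a12.abscissa[hidden] > 11.0).all()

    def test_identical_profiles_unchanged(self):
        p = self._profile(-8.0, 0.0, 17)
        (a,) = align_profiles([self._profile(-8.0, 0.0, 17)])
        np.testing.assert_allclose(a.abscissa, p.abscissa + 8.0)
        assert a.displayed.all()

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            align_profiles([])
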