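"""Plane-strain elasticity: oracles, properties, POI sampling."""
import numpy as np
import pytest

from retmech.geometry import UM, make_annulus_mesh, make_rect_mesh
from retmech.hemodynamics import EdgeLoad
from retmech.structure import (BodyLoad, Material, MaterialTable, PoiMetrics,
                               StructureError, SweepPoiMetrics, body_force,
                               sample_pois, solve_elasticity, von_mises)


class TestBodyForce:
    def test_direct_evaluation(self):
        load = BodyLoad(chest_eye_distance=0.2, omega=10.0, direction=[1.0, 0.0])
        f = body_force(load, density=1057.0)
        assert f[0] == pytest.approx(1057 * 0.2 * 100)
        assert f[1] == 0.0

    def test_zero_omega(self):
        load = BodyLoad(chest_eye_distance=0.2, omega=0.0, direction=[0.0, 1.0])
        assert np.all(body_force(load, 1147.0) == 0.0)

    def test_sign_antisymmetry(self):
        d = np.array([0.6, 0.8])
        f_pos = body_force(BodyLoad(0.2, 5.0, d), 1000.0)
        f_neg = body_force(BodyLoad(0.2, -5.0, d), 1000.0)
        np.testing.assert_allclose(f_neg, -f_pos)

    def test_validation(self):
        with pytest.raises(ValueError):
            BodyLoad(chest_eye_distance=-0.1, omega=1.0, direction=[1, 0])
        with pytest.raises(ValueError):
            BodyLoad(chest_eye_distance=0.1, omega=1.0, direction=[1, 1])


class TestVonMises:
    def test_closed_forms(self):
        assert von_mises(5.0, 0, 0, 0) == pytest.approx(5.0)
        assert von_mises(0, 0, 0, 3.0) == pytest.approx(np.sqrt(3) * 3.0)
        assert von_mises(7.0, 7.0, 7.0, 0) == pytest.approx(0.0)


ROLLERS = [
    (lambda x, y: np.abs(y) < 1e-9, "y"),
    (lambda x, y: np.abs(x) < 1e-9, "x"),
]


LAME_A_UM, LAME_B_UM, LAME_P = 100.0, 200.0, 1000.0


@pytest.fixture(scope="module")
def lame_solution(annulus_mesh):
    edges, _ = annulus_mesh.edges_with_tag("interface")
    mids = 0.5 * (annulus_mesh.coords[edges[:, 0]] + annulus_mesh.coords[edges[:, 1]])
    normals = mids / np.linalg.norm(mids, axis=1)[:, None]
    load = EdgeLoad(edges=edges, tractions=LAME_P * normals)
    return solve_elasticity(annulus_mesh, MaterialTable(), traction=load,
                            anchors=ROLLERS)


class TestLameOracle:
    A_UM, B_UM, P = LAME_A_UM, LAME_B_UM, LAME_P

    def test_hoop_stress_at_inner_radius(self, lame_solution):
        a, b = self.A_UM * UM, self.B_UM * UM
        analytic = self.P * (b * b + a * a) / (b * b - a * a)
        st = lame_solution.state_at(np.array([[a * 1.0005, 0.0]]))
        assert st["syy"][0] == pytest.approx(analytic, rel=0.02)

    def test_radial_stress_at_inner_radius(self, lame_solution):
        st = lame_solution.state_at(np.array([[self.A_UM * UM * 1.0005, 0.0]]))
        assert st["sxx"][0] == pytest.approx(-self.P, rel=0.02)


@pytest.fixture(scope="module")
def rect():
    return make_rect_mesh(100.0, 50.0, 10, 5)


@pytest.fixture(scope="module")
def patch_anchors():
    return [(lambda x, y: x < 1e-12, "x"),
            (lambda x, y: (x < 1e-12) & (y < 1e-12), "y")]


class TestElasticityProperties:
    def _tension(self, rect, s):
        edges, _ = rect.edges_with_tag("right")
        return EdgeLoad(edges=edges, tractions=np.tile([s, 0.0], (len(edges), 1)))

    def test_uniform_stress_patch(self, rect, patch_anchors):
        s = 1234.0
        f = solve_elasticity(rect, MaterialTable(), traction=self._tension(rect, s),
                             anchors=patch_anchors)
        pts = np.array([[50, 25], [20, 10], [80, 40]]) * UM
        st = f.state_at(pts)
        np.testing.assert_allclose(st["sxx"], s, rtol=1e-9)
        np.testing.assert_allclose(st["syy"], 0.0, atol=1e-6 * s)
        np.testing.assert_allclose(st["sxy"], 0.0, atol=1e-6 * s)

    def test_zero_load_zero_field(self, rect, patch_anchors):
        f = solve_elasticity(rect, MaterialTable(), traction=None,
                             anchors=patch_anchors)
        assert np.abs(f.u).max() == 0.0
        assert np.abs(f.stress).max() == 0.0

    def test_superposition_doubling(self, rect, patch_anchors):
        f1 = solve_elasticity(rect, MaterialTable(), traction=self._tension(rect, 500.0),
                              anchors=patch_anchors)
        f2 = solve_elasticity(rect, MaterialTable(), traction=self._tension(rect, 1000.0),
                              anchors=patch_anchors)
        np.testing.assert_allclose(f2.stress, 2 * f1.stress, rtol=1e-9, atol=1e-8)

    def test_frame_rotation_by_90_degrees(self):
        """The same slab loaded along x or along y carries the same von
        Mises field at mapped points."""
        mx = make_rect_mesh(100.0, 50.0, 10, 5)
        my = make_rect_mesh(50.0, 100.0, 5, 10)
        ex, _ = mx.edges_with_tag("right")
        ey, _ = my.edges_with_tag("top")
        s = 800.0
        fx = solve_elasticity(mx, MaterialTable(),
                              traction=EdgeLoad(ex, np.tile([s, 0.0], (len(ex), 1))),
                              anchors=[(lambda x, y: x < 1e-12, "x"),
                                       (lambda x, y: (x < 1e-12) & (y < 1e-12), "y")])
        fy = solve_elasticity(my, MaterialTable(),
                              traction=EdgeLoad(ey, np.tile([0.0, s], (len(ey), 1))),
                              anchors=[(lambda x, y: y < 1e-12, "y"),
                                       (lambda x, y: (x < 1e-12) & (y < 1e-12), "x")])
        pts_x = np.array([[30, 20], [70, 35]]) * UM
        pts_y = pts_x[:, ::-1]
        sx = fx.state_at(pts_x)
        sy = fy.state_at(pts_y)
        vmx = von_mises(sx["sxx"], sx["syy"], sx["szz"], sx["sxy"])
        vmy = von_mises(sy["sxx"], sy["syy"], sy["szz"], sy["sxy"])
        np.testing.assert_allclose(vmx, vmy, rtol=1e-8)

    def test_insufficient_anchoring_rejected(self, rect):
        with pytest.raises(StructureError, match="rigid-body"):
            solve_elasticity(rect, MaterialTable(), traction=self._tension(rect, 1.0),
                             anchors=[(lambda x, y: np.zeros_like(x, dtype=bool), "xy")])

    def test_poi_outside_mesh_rejected(self, rect, patch_anchors):
        f = solve_elasticity(rect, MaterialTable(), traction=self._tension(rect, 1.0),
                             anchors=patch_anchors)
        with pytest.raises(StructureError, match="outside"):
            sample_pois(f, np.array([[1.0, 1.0]]))  # metres: far outside


class TestMaterialsAndMetrics:
    def test_material_validation(self):
        with pytest.raises(ValueError):
            Material(density=1000.0, poisson=0.6, youngs=1e5)
        with pytest.raises(ValueError):
            Material(density=1000.0, poisson=0.3, youngs=-1.0)

    def test_printed_material_table(self):
        t = MaterialTable()
        assert (t.retina.density, t.retina.poisson, t.retina.youngs) == (1098.0, 0.49, 90_000.0)
        assert (t.wall.density, t.wall.poisson, t.wall.youngs) == (1147.0, 0.17, 192_000.0)
        assert t.blood_density == 1057.0

    def test_sweep_reduction_max_ge_avg(self):
        steps = [PoiMetrics(np.array([1.0, 2, 3, 4]) * k,
                            np.array([0.1, 0.2, 0.3, 0.4]) * k,
                            np.array([-1e-3, -2e-3, -3e-3, -4e-3]) * k)
                 for k in (0.5, 1.0, 1.5)]
        sw = SweepPoiMetrics.reduce(steps)
        assert (sw.max.von_mises >= sw.avg.von_mises).all()
        assert (sw.max.displacement_um >= sw.avg.displacement_um).all()
        assert (np.abs(sw.max.vol_strain) >= np.abs(sw.avg.vol_strain)).all()
        assert (sw.max.vol_strain < 0).all()   # sign restored after magnitude stats
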