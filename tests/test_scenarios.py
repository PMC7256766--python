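"""Named scenarios, unit conversions, and the coupled pipeline."""
import numpy as np
import pytest
from dataclasses import replace

from retmech.hemodynamics import PortBC
from retmech.scenarios import (AngularMotion, ScenarioError, make_scenario,
                               inlet_velocity_from_flow, mmhg_to_pa,
                               ophthalmic_pressure, run_scenario)
from retmech.structure import SweepPoiMetrics
from retmech.synthetic_data import GeneratorSpec, gen_angular_velocity


class TestConversions:
    @pytest.mark.parametrize("mmhg,pa", [(0.0, 0.0), (63.0, 8399.3), (79.6, 10612.4)])
    def test_mmhg_to_pa(self, mmhg, pa):
        assert mmhg_to_pa(mmhg) == pytest.approx(pa, abs=0.05)

    def test_ophthalmic_ratio(self):
        assert ophthalmic_pressure(117.0) == pytest.approx(79.56)
        assert ophthalmic_pressure(0.0) == 0.0
        assert ophthalmic_pressure(100.0) == pytest.approx(68.0)

    def test_settling_velocity_from_pump_flow(self):
        # 100 µl/min over six fundus arteries through a 120 µm lumen
        v = inlet_velocity_from_flow(100.0, 120.0, n_arteries=6)
        assert v == pytest.approx(2.46e-2, rel=0.005)


class TestScenarioDefaults:
    def test_tbi(self):
        sc = make_scenario("tbi")
        assert sc.inlet.kind == "pressure"
        assert sc.inlet.value == pytest.approx(mmhg_to_pa(79.6))
        assert [sc.outlets[o].value for o in ("o1", "o2", "o3")] == \
            pytest.approx([2.13e-2, 1.77e-2, 1.93e-2])

    def test_settling(self):
        sc = make_scenario("settling")
        assert sc.inlet == PortBC("velocity", 2.46e-2)
        for o in ("o1", "o2", "o3"):
            assert sc.outlets[o].value == pytest.approx(mmhg_to_pa(28.61))

    def test_rh(self):
        sc = make_scenario("rh")
        assert sc.inlet.value == pytest.approx(14.73e-2)
        assert sc.outlets["o1"].value == pytest.approx(mmhg_to_pa(39.46))

    def test_unknown_name(self):
        with pytest.raises(ScenarioError, match="unknown"):
            make_scenario("hypotension")

    def test_motion_validation(self):
        motion = gen_angular_velocity(GeneratorSpec())
        with pytest.raises(ScenarioError, match="must not carry"):
            replace(make_scenario("baseline"), motion=motion)
        with pytest.raises(ScenarioError, match="requires"):
            make_scenario("shaking")


class TestAngularMotion:
    def test_peak_acceleration_invariant(self):
        t = np.linspace(0, 1, 200)
        good = AngularMotion(t, 56.68 * np.sin(2 * np.pi * 3 * t),
                             peak_accel=1068.3, duration=1.0)
        assert good.omega_at(0.0) == 0.0
        with pytest.raises(ValueError, match="deviates"):
            AngularMotion(t, 30.0 * np.sin(2 * np.pi * 3 * t),
                          peak_accel=1068.3, duration=1.0)

    def test_time_monotone(self):
        with pytest.raises(ValueError, match="increasing"):
            AngularMotion(np.array([0.0, 0.0, 1.0]), np.zeros(3), 0.0, 1.0)


@pytest.fixture(scope="module")
def sweep_motion():
    return gen_angular_velocity(GeneratorSpec(shaking_frequency_hz=3.0))


class TestPipeline:
    def test_static_run_deterministic(self, coarse_mesh, default_pois_m):
        r1 = run_scenario(make_scenario("baseline"), coarse_mesh, default_pois_m,
                          keep_fields=False)
        r2 = run_scenario(make_scenario("baseline"), coarse_mesh, default_pois_m,
                          keep_fields=False)
        np.testing.assert_array_equal(r1.metrics.von_mises, r2.metrics.von_mises)
        np.testing.assert_array_equal(r1.metrics.displacement_um,
                                      r2.metrics.displacement_um)

    def test_aht_dominates_tbi_and_sweep_max_ge_avg(self, coarse_mesh,
                                                    default_pois_m, sweep_motion):
        tbi = run_scenario(make_scenario("tbi"), coarse_mesh, default_pois_m,
                           keep_fields=False)
        aht = run_scenario(make_scenario("aht", angular_motion=sweep_motion),
                           coarse_mesh, default_pois_m, n_sweep_steps=21,
                           keep_fields=False)
        assert isinstance(aht.metrics, SweepPoiMetrics)
        m = aht.metrics
        assert (m.max.von_mises >= m.avg.von_mises).all()
        assert (m.max.displacement_um >= m.avg.displacement_um).all()
        # the sweep includes omega = 0, so its maximum cannot fall below
        # the purely hypertensive state at any POI
        assert (m.max.von_mises >= tbi.metrics.von_mises * (1 - 1e-9)).all()

    def test_superposed_sweep_matches_full_resolve(self, coarse_mesh,
                                                   default_pois_m, sweep_motion):
        """The frozen-viscosity superposition engine agrees with per-step
        nonlinear re-solves to well below a percent."""
        kw = dict(n_sweep_steps=5, n_fan=4, keep_fields=False)
        sup = run_scenario(make_scenario("shaking", angular_motion=sweep_motion),
                           coarse_mesh, default_pois_m, sweep_mode="superpose", **kw)
        full = run_scenario(make_scenario("shaking", angular_motion=sweep_motion),
                            coarse_mesh, default_pois_m, sweep_mode="full", **kw)
        np.testing.assert_allclose(sup.metrics.max.von_mises,
                                   full.metrics.max.von_mises, rtol=5e-3)
        np.testing.assert_allclose(sup.metrics.avg.displacement_um,
                                   full.metrics.avg.displacement_um, rtol=5e-3)
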