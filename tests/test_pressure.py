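"""Pressure assembly, omnidirectional integration, and canal pressure drops."""

import numpy as np
import pytest

from cardiopiv.core import PhaseVelocityField
from cardiopiv.pressure import (CanalRegion, PressureField, canal_pressure_drop,
                                nondimensionalize, omnidirectional_integrate,
                                pressure_gradient, solve_pressure)
from cardiopiv.rheology import FluidProperties
from cardiopiv.synthetic import generate_analytic_flow


@pytest.fixture(scope="module")
def poiseuille():
    fld, gt = generate_analytic_flow("poiseuille", h_um=20, length_um=60,
                                     u0_um_s=100, mu_pa_s=3e-3, nx=61, ny=21)
    return fld, gt


class TestGradient:
    def test_zero_velocity_zero_gradient(self):
        u = np.zeros((1, 11, 11))
        fld = PhaseVelocityField(u=u, v=u.copy(), x=np.arange(11.0),
                                 y=np.arange(11.0), times=[0.0])
        gx, gy = pressure_gradient(fld, fluid=FluidProperties())
        assert np.abs(gx).max() == 0 and np.abs(gy).max() == 0

    def test_poiseuille_gradient_is_minus_8mu_u0_over_h2(self, poiseuille):
        fld, gt = poiseuille
        gx, gy = pressure_gradient(fld, fluid=FluidProperties(viscosity_pa_s=3e-3))
        expected = -8 * 3e-3 * 100 / 20.0**2
        interior = gx[0][3:-3, 3:-3]
        assert np.allclose(interior, expected, rtol=1e-6)

    def test_rigid_translation_zero_gradient_in_creeping_mode(self):
        u = np.full((1, 11, 11), 42.0)
        fld = PhaseVelocityField(u=u, v=np.zeros_like(u), x=np.arange(11.0),
                                 y=np.arange(11.0), times=[0.0])
        gx, gy = pressure_gradient(fld, fluid=FluidProperties())
        assert np.abs(gx).max() < 1e-12

    def test_unsteady_term_needs_three_phases(self):
        u = np.zeros((1, 11, 11))
        fld = PhaseVelocityField(u=u, v=u.copy(), x=np.arange(11.0),
                                 y=np.arange(11.0), times=[0.0])
        with pytest.raises(ValueError, match="3 phases"):
            pressure_gradient(fld, fluid=FluidProperties(), include_inertia=True)


class TestIntegration:
    def test_zero_gradient_gives_zero_pressure(self):
        mask = np.ones((10, 14), bool)
        p, res, ok = omnidirectional_integrate(np.zeros((10, 14)), np.zeros((10, 14)),
                                               mask, 1.0, 1.0, (0, 0))
        assert ok and np.abs(p).max() < 1e-12

    def test_constant_gradient_integrated_exactly(self):
        ny, nx = 18, 30
        mask = np.ones((ny, nx), bool)
        gx = np.full((ny, nx), 2.0)
        gy = np.full((ny, nx), -1.0)
        p, res, ok = omnidirectional_integrate(gx, gy, mask, 1.0, 1.0, (0, 0),
                                               tol=1e-12, max_iter=5000)
        xx, yy = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
        assert ok
        assert np.abs(p - (2 * xx - yy)).max() < 1e-8

    def test_reference_node_must_be_inside_mask(self):
        mask = np.zeros((6, 6), bool)
        mask[2:5, 2:5] = True
        with pytest.raises(ValueError, match="reference"):
            omnidirectional_integrate(np.zeros((6, 6)), np.zeros((6, 6)),
                                      mask, 1.0, 1.0, (0, 0))

    def test_poiseuille_end_to_end_drop_within_2pct(self, poiseuille):
        fld, gt = poiseuille
        pf = solve_pressure(fld, FluidProperties(viscosity_pa_s=3e-3),
                            reference_node=(10, 0))
        drop = pf.pressure[0][10, 0] - pf.pressure[0][10, -1]
        assert drop == pytest.approx(gt.extras["pressure_drop_pa"], rel=0.02)
        assert pf.residuals[0] <= 1e-3 and pf.converged[0]
        assert pf.pressure[0][pf.reference_node] == 0.0

    def test_pressure_linear_in_viscosity(self, poiseuille):
        fld, _ = poiseuille
        p1 = solve_pressure(fld, FluidProperties(viscosity_pa_s=3e-3),
                            reference_node=(10, 0))
        p2 = solve_pressure(fld, FluidProperties(viscosity_pa_s=6e-3),
                            reference_node=(10, 0))
        scale = np.abs(p1.pressure).max()
        assert np.abs(p2.pressure - 2 * p1.pressure).max() < 1e-3 * scale


class TestNondimensional:
    def test_definitional_scaling(self):
        p = PressureField(pressure=np.ones((1, 4, 4)), x=np.arange(4.0),
                          y=np.arange(4.0), mask=np.ones((4, 4), bool),
                          reference_node=(0, 0), residuals=np.zeros(1),
                          converged=np.ones(1, bool))
        hr_bpm, mu = 120.0, 5e-3
        nd = nondimensionalize(p, hr_bpm, mu)
        assert nd[0, 0, 0] == pytest.approx(1.0 / ((hr_bpm / 60.0) * mu))

    def test_nondimensional_drop_invariant_under_mu_doubling(self, poiseuille):
        fld, _ = poiseuille
        fld2, _ = generate_analytic_flow("poiseuille", h_um=20, length_um=60,
                                         u0_um_s=100, mu_pa_s=6e-3, nx=61, ny=21)
        out = []
        for f, mu in ((fld, 3e-3), (fld2, 6e-3)):
            pf = solve_pressure(f, FluidProperties(viscosity_pa_s=mu),
                                reference_node=(10, 0))
            nondimensionalize(pf, 120.0, mu)
            out.append(pf.nondim[0][10, 0] - pf.nondim[0][10, -1])
        assert out[1] == pytest.approx(out[0], rel=0.01)

    def test_invalid_parameters_rejected(self):
        p = PressureField(pressure=np.zeros((1, 4, 4)), x=np.arange(4.0),
                          y=np.arange(4.0), mask=np.ones((4, 4), bool),
                          reference_node=(0, 0), residuals=np.zeros(1),
                          converged=np.ones(1, bool))
        with pytest.raises(ValueError):
            nondimensionalize(p, 0.0, 1e-3)


class TestCanalDrop:
    def _pressure_field(self, plane):
        ny, nx = plane.shape
        return PressureField(pressure=plane[None], x=np.arange(nx, dtype=float),
                             y=np.arange(ny, dtype=float),
                             mask=np.ones((ny, nx), bool), reference_node=(0, 0),
                             residuals=np.zeros(1), converged=np.ones(1, bool))

    def test_uniform_pressure_zero_drop(self):
        pf = self._pressure_field(np.full((11, 21), 7.0))
        dp = canal_pressure_drop(pf, CanalRegion("AVC", (3, 5), (17, 5), 1.5))
        assert dp.dp_pa[0] == pytest.approx(0.0)
        assert not dp.retrograde[0]

    def test_probe_swap_negates_series_exactly(self):
        rng = np.random.default_rng(0)
        pf = self._pressure_field(rng.random((11, 21)))
        fwd = canal_pressure_drop(pf, CanalRegion("AVC", (3, 5), (17, 5), 1.5))
        rev = canal_pressure_drop(pf, CanalRegion("AVC", (17, 5), (3, 5), 1.5))
        assert rev.dp_pa[0] == pytest.approx(-fwd.dp_pa[0])

    def test_negative_drop_flagged_retrograde(self):
        plane = np.tile(np.linspace(0, 10, 21), (11, 1))
        pf = self._pressure_field(plane)
        dp = canal_pressure_drop(pf, CanalRegion("AVC", (3, 5), (17, 5), 1.5))
        assert dp.dp_pa[0] < 0 and dp.retrograde[0]

    def test_identical_probes_rejected(self):
        with pytest.raises(ValueError):
            CanalRegion("AVC", (3, 5), (3, 5))

    def test_probe_outside_mask_marks_phase_missing(self):
        pf = self._pressure_field(np.ones((11, 21)))
        pf.mask[:, :6] = False
        dp = canal_pressure_drop(pf, CanalRegion("AVC", (2, 5), (17, 5), 1.0))
        assert dp.missing[0]
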