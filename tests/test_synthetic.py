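"""Phantom generator: analytic flows, particle rendering, beating-heart model."""

import numpy as np
import pytest

from cardiopiv.synthetic import (PhantomSpec, _HeartModel, _stokes_pressure,
                                 generate_analytic_flow, generate_phantom_heart,
                                 render_particle_images, uniform_flow_field)


class TestAnalyticFlows:
    def test_zero_speed_gives_zero_field_and_pressure(self):
        fld, gt = generate_analytic_flow("poiseuille", u0_um_s=0.0)
        assert np.abs(fld.u).max() == 0
        assert np.abs(gt.pressure).max() == 0

    def test_poiseuille_ground_truth_drop(self):
        h, L, u0, mu = 20.0, 60.0, 100.0, 3e-3
        fld, gt = generate_analytic_flow("poiseuille", h_um=h, length_um=L,
                                         u0_um_s=u0, mu_pa_s=mu)
        assert gt.extras["pressure_drop_pa"] == pytest.approx(8 * mu * u0 * L / h**2)
        # pressure field is linear along x with that total drop
        drop = gt.pressure[0][10, 0] - gt.pressure[0][10, -1]
        assert drop == pytest.approx(gt.extras["pressure_drop_pa"])

    def test_couette_uniform_shear(self):
        h, uw = 20.0, 80.0
        fld, gt = generate_analytic_flow("couette", h_um=h, u0_um_s=uw)
        dudy = np.diff(fld.u[0], axis=0) / (fld.y[1] - fld.y[0])
        assert np.allclose(dudy, uw / h)
        assert gt.extras["wall_shear_s"] == pytest.approx(uw / h)

    def test_incompressibility_of_analytic_kinds(self):
        from cardiopiv.fieldops import divergence
        for kind in ("poiseuille", "couette", "translation", "rotation"):
            fld, _ = generate_analytic_flow(kind)
            div = divergence(fld)[0][2:-2, 2:-2]
            scale = max(np.abs(fld.u).max() / 20.0, 1e-12)
            assert np.abs(div).max() < 1e-9 * scale + 1e-12, kind

    def test_bad_parameters(self):
        with pytest.raises(ValueError):
            generate_analytic_flow("warp-drive")
        with pytest.raises(ValueError):
            generate_analytic_flow("poiseuille", h_um=-1.0)


class TestRendering:
    def _spec(self, **kw):
        base = dict(n_cycles=1, period_s=0.02, frame_rate_hz=400,
                    n_particles=50, noise_sigma=0.0, background_amplitude=0.3,
                    dropout_fraction=0.0, turnover_fraction=0.0,
                    margin_px=10, seed=9)
        base.update(kw)
        return PhantomSpec(**base)

    def test_no_particles_no_noise_equals_background(self):
        spec = self._spec(n_particles=0)
        fld = uniform_flow_field((64, 64), 1.0)
        stack = render_particle_images(spec, fld)
        assert (stack.frames == stack.frames[0]).all()

    def test_uniform_field_advects_centers_exactly(self):
        spec = self._spec()
        fld = uniform_flow_field((64, 64), 2.0)
        _, tracks = render_particle_images(spec, fld, return_tracks=True)
        step = tracks[1] - tracks[0]
        assert np.allclose(step[:, 0], 2.0, atol=1e-9)
        assert np.allclose(step[:, 1], 0.0, atol=1e-9)

    def test_same_seed_bit_identical(self):
        spec = self._spec(noise_sigma=0.03)
        fld = uniform_flow_field((64, 64), 1.0)
        s1 = render_particle_images(spec, fld)
        s2 = render_particle_images(spec, fld)
        assert np.array_equal(s1.frames, s2.frames)

    def test_excessive_displacement_warns(self):
        spec = self._spec()
        fld = uniform_flow_field((64, 64), 40.0)
        with pytest.warns(UserWarning, match="displacement"):
            render_particle_images(spec, fld)


class TestPhantomHeart:
    @pytest.fixture(scope="class")
    def small_spec(self):
        return PhantomSpec(ventricle_semiaxes_um=(7.0, 7.0),
                           atrium_semiaxes_um=(6.5, 6.5), canal_width_um=6.0,
                           canal_length_um=5.0, n_cycles=1, period_s=0.1,
                           frame_rate_hz=400, margin_px=30, seed=2)

    def test_amplitude_one_is_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            PhantomSpec(wall_amplitude=1.0)

    def test_canal_wider_than_chamber_rejected(self):
        with pytest.raises(ValueError, match="canal width"):
            PhantomSpec(canal_width_um=12.0,
                        ventricle_semiaxes_um=(10.0, 10.0),
                        atrium_semiaxes_um=(9.0, 9.0))

    def test_zero_amplitude_is_static_with_zero_velocity(self):
        spec = PhantomSpec(ventricle_semiaxes_um=(7.0, 7.0),
                           atrium_semiaxes_um=(6.5, 6.5), canal_width_um=6.0,
                           n_cycles=1, period_s=0.05, wall_amplitude=0.0,
                           noise_sigma=0.0, dropout_fraction=0.0,
                           turnover_fraction=0.0, margin_px=30, seed=3)
        stack, gt = generate_phantom_heart(spec, compute_pressure=False)
        assert (stack.frames == stack.frames[0]).all()
        m = gt.extras["model"]
        u, v = m.velocity(np.array([m.cx_v]), np.array([m.cy]), 0.01)
        assert abs(u[0]) == 0 and abs(v[0]) == 0

    def test_canal_flux_matches_chamber_area_rate(self, small_spec):
        m = _HeartModel(small_spec)
        xm = 0.5 * (m.cx_a + m.aa + m.cx_v - m.av)
        ys = np.linspace(m.cy - m.w / 2, m.cy + m.w / 2, 300)
        for t in (0.013, 0.037, 0.081):
            u, _ = m.velocity(np.full_like(ys, xm), ys, t)
            flux = np.trapezoid(u, ys)
            assert flux == pytest.approx(m.dA_v_dt(t), rel=0.02)

    def test_ground_truth_ef_from_prescribed_geometry(self, small_spec):
        stack, gt = generate_phantom_heart(small_spec, compute_pressure=False)
        a = small_spec.wall_amplitude
        # cylinder volume model: Vol ∝ s³ for isotropic dilation
        expected = 100 * (1 - ((1 - a) / (1 + a)) ** 3)
        assert gt.extras["ef_pct"] == pytest.approx(expected)

    def test_ground_truth_strain_law(self, small_spec):
        stack, gt = generate_phantom_heart(small_spec, compute_pressure=False)
        m = gt.extras["model"]
        t = gt.extras["pair_times_s"]
        lam = m.s_v(t) / (1 - small_spec.wall_amplitude)
        assert np.allclose(gt.extras["strain_pct"], 100 * 0.5 * (lam**2 - 1))

    def test_stokes_pressure_linear_in_viscosity(self, small_spec):
        m = _HeartModel(small_spec)
        shape = (int(np.ceil(m.height_um / 0.25)), int(np.ceil(m.width_um / 0.25)))
        p1, xs, ys = _stokes_pressure(m, 2e-3, 0.013, 0.25, shape, stride=3)
        p2, _, _ = _stokes_pressure(m, 4e-3, 0.013, 0.25, shape, stride=3)
        ok = np.isfinite(p1) & np.isfinite(p2)
        assert np.abs(p2[ok] - 2 * p1[ok]).max() < 1e-6 * np.abs(p1[ok]).max() + 1e-12

    def test_default_recording_conditions(self):
        spec = PhantomSpec()
        assert spec.frame_rate_hz == 400.0
        assert spec.n_cycles == 8
        assert spec.n_frames == 1600          # 4 s at 400 frames/s
        assert spec.pairs_per_cycle == 199
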