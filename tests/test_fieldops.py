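"""Differential operators: accuracy orders, mass-conserving reconstruction,
and wall shear rate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiopiv.core import PhaseVelocityField
from cardiopiv.fieldops import (RegionMask, compact_richardson_derivative,
                                divergence, reconstruct_masked_region,
                                velocity_gradients, wall_shear_rate)
from cardiopiv.strain import WallBoundary


def _field(u, v, dx=1.0):
    ny, nx = u.shape
    return PhaseVelocityField(u=u[None], v=v[None],
                              x=np.arange(nx) * dx, y=np.arange(ny) * dx,
                              times=[0.0])


class TestCompactRichardson:
    def test_constant_field_has_zero_gradient(self):
        f = np.full((1, 8, 8), 3.7)
        d = compact_richardson_derivative(f, 1.0, axis=-1)
        assert np.abs(d).max() < 1e-12

    def test_linear_field_is_exact(self):
        x = np.arange(32) * 0.5
        f = np.broadcast_to(2.5 * x, (1, 8, 32))
        d = compact_richardson_derivative(f, 0.5, axis=-1)
        assert np.abs(d - 2.5).max() < 1e-10

    def test_fourth_order_beats_central_difference_on_sine(self):
        n = 64
        x = np.linspace(0, 2 * np.pi, n)
        h = x[1] - x[0]
        f = np.sin(3 * x)
        truth = 3 * np.cos(3 * x)
        d4 = compact_richardson_derivative(f[None, None], h, axis=-1)[0, 0]
        d2 = np.gradient(f, h)
        err4 = np.abs(d4 - truth)[2:-2].max()
        err2 = np.abs(d2 - truth)[2:-2].max()
        assert err4 < err2 / 10
        assert err4 < 5 * (3 * h) ** 4  # 4th-order bound (loose constant)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            compact_richardson_derivative(np.zeros((4, 8)), 0.0)

    @settings(max_examples=20, deadline=None)
    @given(a=st.floats(-5, 5), b=st.floats(-5, 5))
    def test_gradient_is_linear_operator(self, a, b):
        rng = np.random.default_rng(0)
        f = rng.random((1, 12, 12))
        g = rng.random((1, 12, 12))
        lhs = compact_richardson_derivative(a * f + b * g, 1.0, axis=-1)
        rhs = (a * compact_richardson_derivative(f, 1.0, axis=-1)
               + b * compact_richardson_derivative(g, 1.0, axis=-1))
        assert np.allclose(lhs, rhs, atol=1e-10)


class TestReconstruction:
    def _vortex(self):
        ny, nx = 20, 30
        x = np.arange(nx) * 1.0
        y = np.arange(ny) * 1.0
        xx, yy = np.meshgrid(x, y)
        u = -0.5 * (yy - 10.0)
        v = 0.5 * (xx - 15.0)
        region = np.zeros((ny, nx), bool)
        region[8:13, 12:19] = True
        return _field(u, v), u, v, region

    def test_empty_mask_returns_field_unchanged(self):
        fld, u, v, _ = self._vortex()
        out = reconstruct_masked_region(fld, RegionMask(np.zeros_like(fld.mask[0])))
        assert np.array_equal(out.u, fld.u)

    def test_vortex_strip_recovered_within_5pct_rms(self):
        fld, u, v, region = self._vortex()
        corrupted = fld.copy()
        corrupted.u[0][region] = 99.0
        corrupted.v[0][region] = -99.0
        rec = reconstruct_masked_region(corrupted, RegionMask(region))
        err = np.sqrt(np.mean((rec.u[0][region] - u[region]) ** 2
                              + (rec.v[0][region] - v[region]) ** 2))
        rms = np.sqrt(np.mean(u[region] ** 2 + v[region] ** 2))
        assert err / rms < 0.05

    def test_reconstructed_interior_divergence_vanishes(self):
        fld, _, _, region = self._vortex()
        corrupted = fld.copy()
        corrupted.u[0][region] = 123.0
        rec = reconstruct_masked_region(corrupted, RegionMask(region))
        div = divergence(rec)[0]
        interior = region.copy()
        for ax, sh in ((0, 1), (0, -1), (1, 1), (1, -1)):
            interior &= np.roll(region, sh, axis=ax)
        assert np.abs(div[interior]).max() < 1e-8

    def test_reconstruction_is_idempotent(self):
        fld, _, _, region = self._vortex()
        corrupted = fld.copy()
        corrupted.u[0][region] = 99.0
        once = reconstruct_masked_region(corrupted, RegionMask(region))
        twice = reconstruct_masked_region(once, RegionMask(region))
        assert np.allclose(once.u, twice.u, atol=1e-9)

    def test_invalid_donor_ring_raises_with_location(self):
        fld, _, _, region = self._vortex()
        bad = fld.copy()
        bad.mask[0, 7, 13] = False  # a ring node
        with pytest.raises(ValueError, match="donor ring"):
            reconstruct_masked_region(bad, RegionMask(region))


class TestWallShear:
    def _channel_boundary(self, h, n=40):
        top = np.column_stack([np.linspace(5, 55, n), np.full(n, h)])
        bot = np.column_stack([np.linspace(5, 55, n), np.zeros(n)])
        pts = np.vstack([top, bot])
        nrm = np.vstack([np.tile([0.0, 1.0], (n, 1)), np.tile([0.0, -1.0], (n, 1))])

        class B:
            def points(self, p):
                return pts

            def normals(self, p):
                return nrm

        return B()

    def test_rigid_translation_has_zero_shear(self):
        u = np.full((21, 31), 40.0)
        fld = PhaseVelocityField(u=u[None], v=np.zeros_like(u)[None],
                                 x=np.linspace(0, 60, 31), y=np.linspace(0, 20, 21),
                                 times=[0.0])
        res = wall_shear_rate(fld, self._channel_boundary(20.0))
        assert res["cycle_peak"] < 1e-9

    def test_couette_shear_equals_uw_over_h(self):
        h, uw = 20.0, 100.0
        x = np.linspace(0, 60, 31)
        y = np.linspace(0, h, 21)
        xx, yy = np.meshgrid(x, y)
        fld = PhaseVelocityField(u=(uw * yy / h)[None], v=np.zeros((1, 21, 31)),
                                 x=x, y=y, times=[0.0])
        res = wall_shear_rate(fld, self._channel_boundary(h))
        assert res["cycle_peak"] == pytest.approx(uw / h, rel=1e-9)

    def test_poiseuille_wall_shear_is_4u0_over_h(self):
        h, u0 = 20.0, 100.0
        x = np.linspace(0, 60, 31)
        y = np.linspace(0, h, 21)
        xx, yy = np.meshgrid(x, y)
        u = 4 * u0 * yy * (h - yy) / h**2
        fld = PhaseVelocityField(u=u[None], v=np.zeros((1, 21, 31)), x=x, y=y,
                                 times=[0.0])
        res = wall_shear_rate(fld, self._channel_boundary(h))
        assert res["cycle_peak"] == pytest.approx(4 * u0 / h, rel=1e-6)

    def test_shear_invariant_under_uniform_velocity_offset(self):
        h, u0 = 20.0, 100.0
        x = np.linspace(0, 60, 31)
        y = np.linspace(0, h, 21)
        xx, yy = np.meshgrid(x, y)
        u = 4 * u0 * yy * (h - yy) / h**2
        f1 = PhaseVelocityField(u=u[None], v=np.zeros((1, 21, 31)), x=x, y=y,
                                times=[0.0])
        f2 = PhaseVelocityField(u=(u + 37.0)[None], v=np.full((1, 21, 31), -12.0),
                                x=x, y=y, times=[0.0])
        b = self._channel_boundary(h)
        r1 = wall_shear_rate(f1, b)
        r2 = wall_shear_rate(f2, b)
        assert r1["cycle_peak"] == pytest.approx(r2["cycle_peak"], rel=1e-9)


def test_wall_boundary_normals_point_outward():
    th = np.linspace(0, 2 * np.pi, 80, endpoint=False)
    pts = np.column_stack([10 + 5 * np.cos(th), 10 + 5 * np.sin(th)])
    wb = WallBoundary(contours=[pts])
    nrm = wb.normals(0)
    radial = pts - [10, 10]
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    assert np.mean(np.einsum("ij,ij->i", nrm, radial)) > 0.99
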