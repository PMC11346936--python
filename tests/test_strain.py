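"""Wall segmentation, deformation accumulation, and Green–Lagrange strain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiopiv.core import PhaseVelocityField
from cardiopiv.strain import (DeformationField, WallBoundary,
                              accumulate_deformation, green_lagrange,
                              peak_wall_strain, segment_wall)


def _grid_field(u, v, x, y, times):
    return PhaseVelocityField(u=u, v=v, x=x, y=y, times=times)


class TestSegmentation:
    def test_zero_field_raises(self):
        u = np.zeros((1, 32, 32))
        fld = _grid_field(u, u.copy(), np.arange(32.0), np.arange(32.0), [0.0])
        with pytest.raises(ValueError, match="segmentation failed"):
            segment_wall(fld)

    def test_annulus_wall_recovered_within_2px(self):
        n = 160
        x = np.arange(n, dtype=float)
        y = np.arange(n, dtype=float)
        xx, yy = np.meshgrid(x, y)
        cx = cy = 80.0
        r = np.hypot(xx - cx, yy - cy)
        r0, r1 = 35.0, 60.0
        edge = 1.5  # thin shear layer at both walls, as PIV fields show
        prof = np.clip(np.minimum((r - r0) / edge, (r1 - r) / edge), 0, 1)
        tx = -(yy - cy) / np.maximum(r, 1e-9)
        ty = (xx - cx) / np.maximum(r, 1e-9)
        fld = _grid_field((50 * prof * tx)[None], (50 * prof * ty)[None], x, y, [0.0])
        wb = segment_wall(fld)
        pts = wb.contours[0]
        dev = np.abs(np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) - r1)
        assert dev.max() < 2.0
        assert len(pts) > 50

    def test_scale_invariance_of_the_mask(self):
        rng = np.random.default_rng(3)
        n = 96
        x = np.arange(n, dtype=float)
        xx, yy = np.meshgrid(x, x)
        blob = np.exp(-((xx - 48) ** 2 + (yy - 48) ** 2) / (2 * 15**2))
        u = (blob * (yy - 48) + 0.01 * rng.random((n, n)))[None]
        v = (-blob * (xx - 48))[None]
        f1 = _grid_field(u, v, x, x, [0.0])
        f2 = _grid_field(10 * u, 10 * v, x, x, [0.0])
        m1 = segment_wall(f1).masks[0]
        m2 = segment_wall(f2).masks[0]
        assert np.array_equal(m1, m2)


class TestDeformation:
    def test_static_field_keeps_identity(self):
        n, ny, nx = 6, 15, 15
        u = np.zeros((n, ny, nx))
        fld = _grid_field(u, u.copy(), np.arange(nx, dtype=float),
                          np.arange(ny, dtype=float), np.arange(n, dtype=float))
        dfm = accumulate_deformation(fld, reference_phase=0)
        ident = np.broadcast_to(np.eye(2), dfm.F.shape)
        assert np.abs(dfm.F - ident).max() < 1e-12
        assert dfm.cycle_drift_um < 1e-12

    def test_uniform_exponential_stretch_recovers_lambda(self):
        lam, T, n = 1.2, 1.0, 40
        ny = nx = 21
        x = np.linspace(-10, 10, nx)
        y = np.linspace(-10, 10, ny)
        xx, yy = np.meshgrid(x, y)
        k = np.log(lam) / T
        u = np.broadcast_to(k * xx, (n, ny, nx)).copy()
        fld = _grid_field(u, np.zeros_like(u), x, y, np.arange(n) * (T / n))
        dfm = accumulate_deformation(fld, reference_phase=0)
        lam_end = np.exp(k * (n - 1) * (T / n))
        assert dfm.F[n - 1, 10, 10, 0, 0] == pytest.approx(lam_end, rel=0.01)

    def test_solid_body_rotation_keeps_f_orthogonal(self):
        n = 60
        ny = nx = 31
        x = np.linspace(-10, 10, nx)
        y = np.linspace(-10, 10, ny)
        xx, yy = np.meshgrid(x, y)
        om = 2 * np.pi / n
        u = np.broadcast_to(-om * yy, (n, ny, nx)).copy()
        v = np.broadcast_to(om * xx, (n, ny, nx)).copy()
        fld = _grid_field(u, v, x, y, np.arange(n, dtype=float))
        dfm = accumulate_deformation(fld, reference_phase=0)
        F = dfm.F[n // 2, 15, 15]
        assert np.abs(F.T @ F - np.eye(2)).max() < 0.01

    def test_instantaneous_variant_returns_velocity_gradients(self):
        n, ny, nx = 4, 11, 11
        x = np.arange(nx, dtype=float)
        xx, _ = np.meshgrid(x, np.arange(ny, dtype=float))
        u = np.broadcast_to(0.5 * xx, (n, ny, nx)).copy()
        fld = _grid_field(u, np.zeros_like(u), x, np.arange(ny, dtype=float),
                          np.arange(n, dtype=float))
        dfm = accumulate_deformation(fld, reference_phase=0, instantaneous=True)
        assert dfm.F[0, 5, 5, 0, 0] == pytest.approx(0.5)


class TestGreenLagrange:
    def _wrap(self, F):
        n = F.shape[0]
        return DeformationField(F=F, valid=np.ones(F.shape[:3], bool),
                                reference_phase=0, x=np.arange(F.shape[2], dtype=float),
                                y=np.arange(F.shape[1], dtype=float))

    def test_identity_gives_zero_strain(self):
        F = np.broadcast_to(np.eye(2), (1, 4, 4, 2, 2)).copy()
        E = green_lagrange(self._wrap(F))
        assert np.abs(E.E).max() == 0

    @settings(max_examples=25, deadline=None)
    @given(theta=st.floats(-np.pi, np.pi))
    def test_pure_rotation_has_zero_strain(self, theta):
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        F = np.broadcast_to(R, (1, 3, 3, 2, 2)).copy()
        E = green_lagrange(self._wrap(F))
        assert np.abs(E.E).max() < 1e-6

    def test_uniaxial_stretch_exx(self):
        F = np.broadcast_to(np.diag([1.2, 1.0]), (1, 3, 3, 2, 2)).copy()
        E = green_lagrange(self._wrap(F))
        assert E.E[0, 1, 1, 0, 0] == pytest.approx(0.22)
        assert E.principal_pct[0, 1, 1] == pytest.approx(22.0)

    @settings(max_examples=25, deadline=None)
    @given(theta=st.floats(-np.pi, np.pi), lam=st.floats(0.8, 1.5))
    def test_objectivity_under_superposed_rotation(self, theta, lam):
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        F0 = np.diag([lam, 1.0 / lam])
        for F in (F0, R @ F0):
            Ff = np.broadcast_to(F, (1, 1, 1, 2, 2)).copy()
            E = green_lagrange(self._wrap(Ff))
            expected = 0.5 * (F0.T @ F0 - np.eye(2))
            assert np.allclose(E.E[0, 0, 0], expected, atol=1e-9)


class TestPeakWallStrain:
    def _strain_field(self, boundary_vals):
        ny = nx = 9
        grid = np.zeros((1, ny, nx))
        # place known values along the mid row; boundary samples there
        grid[0, 4, 2:7] = boundary_vals
        from cardiopiv.strain import StrainField
        return StrainField(E=np.zeros((1, ny, nx, 2, 2)), principal_pct=grid,
                           valid=np.ones((1, ny, nx), bool), reference_phase=0,
                           x=np.arange(nx, dtype=float), y=np.arange(ny, dtype=float))

    def test_top_three_average(self):
        sf = self._strain_field([1.0, 2.0, 3.0, 4.0, 5.0])
        pts = np.column_stack([np.arange(2.0, 7.0), np.full(5, 4.0)])
        series = peak_wall_strain(sf, WallBoundary(contours=[pts]))
        assert series.values_pct[0] == pytest.approx(4.0)  # mean of {3,4,5}

    def test_uniform_boundary_strain_returns_that_value(self):
        sf = self._strain_field([2.5] * 5)
        pts = np.column_stack([np.arange(2.0, 7.0), np.full(5, 4.0)])
        series = peak_wall_strain(sf, WallBoundary(contours=[pts]))
        assert series.values_pct[0] == pytest.approx(2.5)

    def test_too_few_valid_points_marks_phase_missing(self):
        sf = self._strain_field([1.0, 2.0, 3.0, 4.0, 5.0])
        sf.valid[:] = False
        pts = np.column_stack([np.arange(2.0, 7.0), np.full(5, 4.0)])
        series = peak_wall_strain(sf, WallBoundary(contours=[pts]))
        assert series.missing[0]
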