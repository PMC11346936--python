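"""PIV engine: POD background removal, correlation displacement recovery,
and universal outlier validation."""

import numpy as np
import pytest

from cardiopiv.core import ImageStack, PhaseVelocityField
from cardiopiv.piv import (DEFAULT_PASSES, PassSchedule, ensemble_piv,
                           pod_background_removal, validate_vectors)
from cardiopiv.synthetic import PhantomSpec, render_particle_images, uniform_flow_field

from conftest import make_blob_stack


class TestPOD:
    def test_identical_frames_reduce_to_numerical_zero(self):
        f0 = np.random.default_rng(0).random((32, 32))
        stack = ImageStack(frames=np.repeat(f0[None], 5, axis=0),
                           pixel_size_um=0.25, frame_rate_hz=400)
        out = pod_background_removal(stack)
        assert (out.frames**2).sum() < 1e-10 * (stack.frames**2).sum()

    def test_all_zero_stack_is_degenerate(self):
        stack = ImageStack(frames=np.zeros((5, 16, 16)),
                           pixel_size_um=0.25, frame_rate_hz=400)
        with pytest.raises(ValueError, match="degenerate"):
            pod_background_removal(stack)

    def test_two_frames_not_enough(self):
        stack = ImageStack(frames=np.random.default_rng(0).random((2, 16, 16)),
                           pixel_size_um=0.25, frame_rate_hz=400)
        with pytest.raises(ValueError):
            pod_background_removal(stack)

    def test_static_background_variance_reduced_over_90pct(self):
        stack = make_blob_stack(40, seed=5, n_frames=30)
        clean = pod_background_removal(stack)
        # oracle: rank-1 background from a direct SVD of the snapshot matrix
        snaps = stack.frames.reshape(30, -1).astype(float)
        u_m, s, vt = np.linalg.svd(snaps, full_matrices=False)
        bg_oracle = (u_m[:, :1] * s[:1]) @ vt[:1]
        bg_var_before = float(stack.frames.astype(float).mean(axis=0).var())
        bg_var_after = float(clean.frames.mean(axis=0).var())
        assert bg_var_after < 0.1 * bg_var_before
        # the discarded leading subspace matches the oracle's background
        resid = snaps - bg_oracle
        assert (clean.frames.reshape(30, -1).var(axis=0).mean()
                <= 1.05 * resid.var(axis=0).mean())

    def test_output_shape_and_zero_temporal_mean(self):
        stack = make_blob_stack(30, seed=2, n_frames=20)
        clean = pod_background_removal(stack)
        assert clean.frames.shape == stack.frames.shape
        scale = np.abs(stack.frames.astype(float)).max()
        assert np.abs(clean.frames.mean(axis=0)).max() < 0.05 * scale


class TestEnsemblePIV:
    def test_default_schedule_matches_processing_protocol(self):
        sched = PassSchedule()
        assert sched.passes == [(96, 48, 0.50), (64, 32, 0.50), (64, 32, 0.75)]
        assert sched.min_iterations == 3 and sched.max_iterations == 6
        assert DEFAULT_PASSES[-1] == (64, 32, 0.75)

    def test_identical_image_pair_gives_zero_displacement(self):
        stack = make_blob_stack(60, seed=3, n_frames=2, noise=0.0)
        stack = ImageStack(frames=np.repeat(stack.frames[:1], 2, axis=0),
                           pixel_size_um=0.25, frame_rate_hz=400)
        fld = ensemble_piv(stack, PassSchedule(passes=[(48, 24, 0.5)]),
                           cycle_period_frames=2)
        px = fld.u / (0.25 * 400)
        assert np.abs(px[fld.mask]).max() < 1e-6

    def test_final_grid_spacing_follows_resolution_and_overlap(self):
        stack = make_blob_stack(60, seed=3, n_frames=2)
        sched = PassSchedule(passes=[(32, 16, 0.75)])
        fld = ensemble_piv(stack, sched, cycle_period_frames=2)
        assert fld.x[1] - fld.x[0] == pytest.approx(16 * 0.25 * 0.25)  # px→μm

    def test_window_larger_than_image_is_config_error(self):
        stack = make_blob_stack(10, seed=1, n_frames=2, size=48)
        with pytest.raises(ValueError, match="larger than image"):
            ensemble_piv(stack, PassSchedule(passes=[(96, 48, 0.5)]),
                         cycle_period_frames=2)

    def test_phase_average_invariant_to_cycle_rotation(self):
        spec = PhantomSpec(n_cycles=6, period_s=0.01, frame_rate_hz=400,
                           n_particles=200, noise_sigma=0.0,
                           background_amplitude=0.0, dropout_fraction=0.0,
                           turnover_fraction=0.0, margin_px=10, seed=4)
        fld_in = uniform_flow_field((96, 96), (1.5, -0.5, -1.5, 0.5))
        stack = render_particle_images(spec, fld_in)
        f1 = ensemble_piv(stack, PassSchedule(passes=[(32, 16, 0.5)]),
                          cycle_period_frames=4)
        rolled = ImageStack(frames=np.roll(stack.frames, -4, axis=0),
                            pixel_size_um=0.25, frame_rate_hz=400)
        f2 = ensemble_piv(rolled, PassSchedule(passes=[(32, 16, 0.5)]),
                          cycle_period_frames=4)
        both = f1.mask & f2.mask
        # interior nodes; last cycle of the rolled stack wraps, so compare medians
        d = np.abs(f1.u - f2.u)[both]
        assert np.median(d) < 0.05 * (0.25 * 400)


class TestValidation:
    def _uniform(self, val=10.0):
        u = np.full((1, 9, 9), val)
        return PhaseVelocityField(u=u, v=np.zeros_like(u),
                                  x=np.arange(9.0), y=np.arange(9.0), times=[0.0])

    def test_uniform_field_has_no_outliers(self):
        out = validate_vectors(self._uniform())
        assert not out.replaced.any()

    def test_single_spike_is_flagged_and_replaced_by_median(self):
        fld = self._uniform()
        fld.u[0, 4, 4] = 100.0  # 10x the neighborhood median
        out = validate_vectors(fld, threshold=2.0, neighborhood=3)
        assert out.replaced[0, 4, 4]
        assert out.u[0, 4, 4] == pytest.approx(10.0)

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            validate_vectors(self._uniform(), neighborhood=4)
        with pytest.raises(ValueError):
            validate_vectors(self._uniform(), threshold=0.0)

    def test_tiny_field_skipped_with_warning(self):
        u = np.full((1, 2, 2), 1.0)
        fld = PhaseVelocityField(u=u, v=u.copy(), x=np.arange(2.0),
                                 y=np.arange(2.0), times=[0.0])
        with pytest.warns(UserWarning, match="neighborhood"):
            validate_vectors(fld)
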