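"""Shared fixtures: analytic flows, rendered tracer stacks, and one
session-scoped end-to-end phantom run reused by the acceptance checks."""

import warnings

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
hyp_settings.load_profile("deterministic")

from cardiopiv.core import ImageStack
from cardiopiv.pipeline import PipelineConfig, run_pipeline
from cardiopiv.synthetic import (PhantomSpec, _HeartModel, _background,
                                 _quantize, _render_blobs,
                                 generate_phantom_heart)

warnings.filterwarnings("ignore", category=UserWarning)


def make_blob_stack(n_blobs, seed=0, n_frames=40, size=96, noise=0.01,
                    bg_amp=0.3, sigma=1.2, peak=0.6):
    """Frames with independently re-seeded blobs (decorrelated tracers)."""
    rng = np.random.default_rng(seed)
    bg = _background((size, size), bg_amp, rng)
    frames = np.empty((n_frames, size, size), dtype=np.uint16)
    for k in range(n_frames):
        f = bg.copy()
        _render_blobs(f, rng.uniform(0, size, n_blobs),
                      rng.uniform(0, size, n_blobs), peak, sigma)
        f = f + rng.normal(0, noise, (size, size))
        frames[k] = _quantize(f)
    return ImageStack(frames=frames, pixel_size_um=0.25, frame_rate_hz=400.0)


@pytest.fixture(scope="session")
def e2e_phantom():
    """Scaled-down beating-heart phantom (4 cycles of 80 frames) + truth."""
    spec = PhantomSpec(n_cycles=4, period_s=0.2, frame_rate_hz=400,
                       noise_sigma=0.02, seed=11)
    model = _HeartModel(spec)
    stack, gt = generate_phantom_heart(spec, compute_pressure=True)
    return spec, model, stack, gt


@pytest.fixture(scope="session")
def e2e_run(e2e_phantom, tmp_path_factory):
    """Full pipeline run on the phantom (the expensive end-to-end fixture)."""
    spec, m, stack, gt = e2e_phantom
    cfg = PipelineConfig(
        passes=[(32, 16, 0.5), (24, 12, 0.5)],
        avc_upstream_um=(m.cx_a, m.cy),
        avc_downstream_um=(m.cx_v, m.cy),
        probe_radius_um=3.0,
        canal_strip_um=(m.cx_a + m.aa, m.cx_v - m.av,
                        m.cy - m.w / 2, m.cy + m.w / 2),
        reference_locus_um=(m.cx_v + m.av, m.cy),
        ventricle_roi_um=(m.cx_v - m.av, m.width_um, 0.0, m.height_um),
        inlet_diameter_um=spec.canal_width_um,
        cycle_period_frames=spec.frames_per_cycle,
        outdir=str(tmp_path_factory.mktemp("e2e_out")),
        seed=11,
    )
    manifest, results = run_pipeline(cfg, stack=stack)
    return cfg, manifest, results
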