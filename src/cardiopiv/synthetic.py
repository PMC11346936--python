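"""Synthetic phantoms with full ground truth.

Real recordings of beating embryonic hearts are rarely archived, so every
stage of the pipeline is exercised against phantoms instead: analytic
creeping-flow fields with closed-form pressure and shear, and a rendered
two-chamber "beating heart" whose red-blood-corpuscle-like tracer patterns
are advected by a prescribed pulsatile field through an atrium-canal-ventricle
geometry with prescribed periodic wall motion.

The phantom's chamber interiors move with an affine dilation law, so the
walls are material points of the prescribed scaling and the ground-truth
wall strain is closed-form.  The canal carries a parabolic profile whose flux
equals the rate of change of the ventricle area (2D incompressibility at the
canal).  Ground-truth pressure is obtained by solving the Stokes
pressure-Poisson problem numerically on the phantom grid — an oracle
independent of the production pressure integrator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse import linalg as splinalg

from .core import ImageStack, PhaseVelocityField

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_analytic_flow",
    "render_particle_images",
    "generate_phantom_heart",
    "uniform_flow_field",
]

UINT16_FULL_SCALE = 52000  # headroom below 2^16 for noise excursions


# --------------------------------------------------------------------------
# specifications and ground truth containers
# --------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parameters of a rendered phantom recording.

    Defaults mirror the imaging conditions the pipeline targets: 400 frames/s
    for 4 s (8 cardiac cycles of 0.5 s, i.e. 199 image pairs per cycle at a
    heart rate of 120 bpm), 0.25 μm/px (40x preset), an atrioventricular-canal
    width inside the 6–10 μm range, and tracer seeding dense enough to put
    roughly 10–15 blob patterns in a 48×48 px interrogation window.
    """

    geometry: str = "two-chamber"  # "two-chamber" | "channel"
    ventricle_semiaxes_um: tuple[float, float] = (10.5, 10.5)
    atrium_semiaxes_um: tuple[float, float] = (9.5, 9.5)
    canal_width_um: float = 9.0
    canal_length_um: float = 6.0
    wall_amplitude: float = 0.06  # fractional semi-axis excursion
    swirl_rad_s: float = 0.0  # optional solid-body vortex (strain-free for circular chambers)
    period_s: float = 0.5
    n_cycles: int = 8
    frame_rate_hz: float = 400.0
    pixel_size_um: float = 0.25
    n_particles: int = 0  # 0 → auto from seeding density
    particle_sigma_px: float = 1.2  # Gaussian blob scale (radius ~2-3 px)
    particle_peak: float = 0.6
    background_amplitude: float = 0.30
    noise_sigma: float = 0.02
    dropout_fraction: float = 0.02
    turnover_fraction: float = 0.05  # per-frame out-of-plane tracer exchange
    rbc_volume_um3: float = 60.0
    depth_of_focus_um: float = 15.0
    margin_px: int = 80  # flow-free surround, as in whole-embryo framing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_s <= 0:
            raise ValueError("period must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.n_particles < 0 or self.n_cycles < 1:
            raise ValueError("counts must be non-negative")
        if self.wall_amplitude >= 1:
            raise ValueError("wall-motion amplitude >= 1 self-intersects the wall")
        if self.canal_width_um >= min(self.ventricle_semiaxes_um[1],
                                      self.atrium_semiaxes_um[1]):
            raise ValueError("canal width must be smaller than the chamber minor axis")

    @property
    def frames_per_cycle(self) -> int:
        return int(round(self.period_s * self.frame_rate_hz))

    @property
    def n_frames(self) -> int:
        return self.n_cycles * self.frames_per_cycle

    @property
    def pairs_per_cycle(self) -> int:
        return self.frames_per_cycle - 1


@dataclass
class GroundTruth:
    """Oracle quantities attached to a phantom.

    Pressure is stored with the same zero-reference-node convention as the
    production solver: P = 0 at the reference node each phase.
    """

    period_s: float
    velocity_fn: Optional[Callable] = None  # (x_um, y_um, t_s) -> (u, v) μm/s
    lumen_fn: Optional[Callable] = None     # (x_um, y_um, t_s) -> bool
    pressure: Optional[np.ndarray] = None   # (n_sampled_phases, ny, nx), Pa
    pressure_x_um: Optional[np.ndarray] = None
    pressure_y_um: Optional[np.ndarray] = None
    pressure_times_s: Optional[np.ndarray] = None
    wall_contours: Optional[list] = None    # per phase, (n_pts, 2) μm
    ht_pct: Optional[float] = None
    mu_pa_s: Optional[float] = None
    extras: dict = dc_field(default_factory=dict)


# --------------------------------------------------------------------------
# analytic flows
# --------------------------------------------------------------------------

_ANALYTIC_KINDS = ("poiseuille", "couette", "pulsatile_poiseuille",
                   "translation", "rotation")


def generate_analytic_flow(
    kind: str,
    *,
    h_um: float = 20.0,
    length_um: float = 60.0,
    u0_um_s: float = 100.0,
    mu_pa_s: float = 3e-3,
    nx: int = 61,
    ny: int = 21,
    hr_bpm: float = 120.0,
    n_phases: int = 1,
    omega_s: float = 1.0,
) -> tuple[PhaseVelocityField, GroundTruth]:
    """Closed-form creeping-flow fields sampled on a stated grid.

    ``poiseuille``: channel of height ``h_um`` along y, flow along x with
    centerline speed ``u0_um_s``; ground-truth pressure drops by
    8·μ·U0·L/h² over the channel length.  ``couette``: linear profile with
    wall speed ``u0_um_s`` (uniform shear U0/h).  ``pulsatile_poiseuille``
    modulates the Poiseuille amplitude sinusoidally at ``hr_bpm``.
    ``translation`` and ``rotation`` are rigid motions (zero pressure
    gradient in the creeping regime).
    """
    if kind not in _ANALYTIC_KINDS:
        raise ValueError(f"unknown analytic flow kind {kind!r}; choose from {_ANALYTIC_KINDS}")
    if h_um <= 0 or mu_pa_s <= 0 or length_um <= 0:
        raise ValueError("channel height, length and viscosity must be positive")
    if u0_um_s < 0:
        raise ValueError("speed scale must be non-negative")
    if nx < 2 or ny < 2:
        raise ValueError("grid must have at least 2 nodes per axis")

    x = np.linspace(0.0, length_um, nx)
    y = np.linspace(0.0, h_um, ny)
    xx, yy = np.meshgrid(x, y)
    period = 60.0 / hr_bpm
    if kind == "pulsatile_poiseuille":
        times = (np.arange(n_phases) + 0.5) / n_phases * period
        amp = np.sin(2 * np.pi * times / period)
    else:
        n_phases = max(1, n_phases)
        times = (np.arange(n_phases) + 0.5) / n_phases * period
        amp = np.ones(n_phases)

    u = np.zeros((n_phases, ny, nx))
    v = np.zeros_like(u)
    pressure = np.zeros_like(u)
    extras: dict = {"kind": kind, "h_um": h_um, "length_um": length_um,
                    "u0_um_s": u0_um_s, "mu_pa_s": mu_pa_s}

    if kind in ("poiseuille", "pulsatile_poiseuille"):
        profile = 4.0 * u0_um_s * yy * (h_um - yy) / h_um**2
        dpdx = -8.0 * mu_pa_s * u0_um_s / h_um**2  # Pa/μm
        for p in range(n_phases):
            u[p] = amp[p] * profile
            pressure[p] = amp[p] * dpdx * (xx - x[0])
        extras["dp_dx_pa_um"] = dpdx
        extras["pressure_drop_pa"] = -dpdx * length_um
        extras["wall_shear_s"] = 4.0 * u0_um_s / h_um
    elif kind == "couette":
        u[:] = u0_um_s * yy / h_um
        extras["wall_shear_s"] = u0_um_s / h_um
        extras["dp_dx_pa_um"] = 0.0
    elif kind == "translation":
        u[:] = u0_um_s
        extras["wall_shear_s"] = 0.0
    elif kind == "rotation":
        cx, cy = x.mean(), y.mean()
        u[:] = -omega_s * (yy - cy)
        v[:] = omega_s * (xx - cx)
        extras["wall_shear_s"] = 0.0

    fld = PhaseVelocityField(u=u, v=v, x=x, y=y, times=times, n_cycles=1)
    gt = GroundTruth(
        period_s=period,
        velocity_fn=None,
        pressure=pressure,
        pressure_x_um=x,
        pressure_y_um=y,
        pressure_times_s=times,
        mu_pa_s=mu_pa_s,
        extras=extras,
    )
    return fld, gt


def uniform_flow_field(
    shape_px: tuple[int, int],
    u_px_frame,
    v_px_frame=0.0,
    pixel_size_um: float = 0.25,
    frame_rate_hz: float = 400.0,
) -> PhaseVelocityField:
    """Spatially uniform field from per-frame pixel displacements (test helper).

    Scalars give a steady field; sequences give one phase per entry (e.g.
    ``(+d, -d)`` oscillates tracers with zero net drift across cycles).
    """
    ny, nx = shape_px
    scale = pixel_size_um * frame_rate_hz  # px/frame -> μm/s
    u_vals = np.atleast_1d(np.asarray(u_px_frame, dtype=float))
    v_vals = np.broadcast_to(np.atleast_1d(np.asarray(v_px_frame, dtype=float)),
                             u_vals.shape)
    n_phases = u_vals.size
    u = np.broadcast_to((u_vals * scale)[:, None, None], (n_phases, ny, nx)).copy()
    v = np.broadcast_to((v_vals * scale)[:, None, None], (n_phases, ny, nx)).copy()
    x = np.arange(nx) * pixel_size_um
    y = np.arange(ny) * pixel_size_um
    times = (np.arange(n_phases) + 0.5) / frame_rate_hz
    return PhaseVelocityField(u=u, v=v, x=x, y=y, times=times,
                              pixel_size_um=pixel_size_um)


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _background(shape: tuple[int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Static bright background with smooth artifacts (what POD must remove)."""
    ny, nx = shape
    coarse = ndimage.gaussian_filter(rng.standard_normal((ny, nx)), 8.0)
    fine = ndimage.gaussian_filter(rng.standard_normal((ny, nx)), 2.5)
    pat = 0.75 * coarse / (np.abs(coarse).max() + 1e-12) + 0.25 * fine / (np.abs(fine).max() + 1e-12)
    return amplitude * (0.5 + 0.5 * pat)


def _render_blobs(frame: np.ndarray, cx: np.ndarray, cy: np.ndarray,
                  peak: float, sigma: float) -> None:
    """Accumulate Gaussian-profile blobs at continuous centers (in place)."""
    ny, nx = frame.shape
    r = max(2, int(np.ceil(4 * sigma)))
    for xc, yc in zip(cx, cy):
        j0, i0 = int(np.floor(xc)) - r, int(np.floor(yc)) - r
        j1, i1 = j0 + 2 * r + 1, i0 + 2 * r + 1
        if j1 < 0 or i1 < 0 or j0 >= nx or i0 >= ny:
            continue
        jj0, ii0 = max(j0, 0), max(i0, 0)
        jj1, ii1 = min(j1, nx), min(i1, ny)
        ys = np.arange(ii0, ii1)
        xs = np.arange(jj0, jj1)
        gx = np.exp(-((xs - xc) ** 2) / (2 * sigma**2))
        gy = np.exp(-((ys - yc) ** 2) / (2 * sigma**2))
        frame[ii0:ii1, jj0:jj1] += peak * gy[:, None] * gx[None, :]


def _quantize(frames_f: np.ndarray) -> np.ndarray:
    return np.clip(frames_f * UINT16_FULL_SCALE, 0, 65535).astype(np.uint16)


def render_particle_images(
    spec: PhantomSpec,
    field: PhaseVelocityField,
    return_tracks: bool = False,
):
    """Render a tracer-seeded image sequence advected by ``field``.

    Blobs are seeded uniformly over the field domain, advected between frames
    by the local velocity (sub-pixel displacements rendered via continuous
    blob centers), then a static background pattern and per-pixel Gaussian
    noise are added.  The sequence spans ``spec.n_frames`` frames; the field's
    phases repeat with the stated period.
    """
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size_um
    nx_px = int(round(field.x[-1] / px)) + 1
    ny_px = int(round(field.y[-1] / px)) + 1
    shape = (ny_px, nx_px)
    n_frames = spec.n_frames
    fpc = spec.frames_per_cycle
    dt = 1.0 / spec.frame_rate_hz

    max_speed = float(field.speed.max())
    disp = max_speed * dt / px
    if disp > 16:
        warnings.warn(
            f"per-frame displacement {disp:.1f} px exceeds half the smallest "
            "PIV window; correlation will fail by design",
            stacklevel=2,
        )

    from .fieldops import sample_bilinear

    def vel_px(xs, ys, frame_idx):
        phase = int((frame_idx % fpc) * field.n_phases / fpc)
        u = sample_bilinear(field.u[phase], field.x, field.y, xs * px, ys * px)
        v = sample_bilinear(field.v[phase], field.x, field.y, xs * px, ys * px)
        return u * dt / px, v * dt / px

    m = spec.margin_px
    n_part = spec.n_particles
    pos0 = np.column_stack([
        rng.uniform(m, nx_px - m, n_part),
        rng.uniform(m, ny_px - m, n_part),
    ]) if n_part else np.empty((0, 2))
    tracks = np.empty((n_frames, n_part, 2))
    pos = pos0.astype(float).copy()
    for k in range(n_frames):
        tracks[k] = pos
        if k + 1 < n_frames:
            if spec.turnover_fraction > 0 and n_part:
                # out-of-plane tracer exchange: replaced tracers re-enter
                # at fresh positions
                swap = rng.random(n_part) < spec.turnover_fraction
                if swap.any():
                    pos[swap] = np.column_stack([
                        rng.uniform(m, nx_px - m, int(swap.sum())),
                        rng.uniform(m, ny_px - m, int(swap.sum())),
                    ])
            u1, v1 = vel_px(pos[:, 0], pos[:, 1], k)
            mid = pos + 0.5 * np.column_stack([u1, v1])
            u2, v2 = vel_px(mid[:, 0], mid[:, 1], k)
            pos = pos + np.column_stack([u2, v2])
    visible = rng.random((n_frames, len(pos0))) >= spec.dropout_fraction
    if len(pos0):
        visible[0] = True

    bg = _background(shape, spec.background_amplitude, rng)
    frames = np.empty((n_frames, *shape), dtype=np.uint16)
    for k in range(n_frames):
        f = bg.copy()
        vis = visible[k]
        _render_blobs(f, tracks[k, vis, 0], tracks[k, vis, 1],
                      spec.particle_peak, spec.particle_sigma_px)
        if spec.noise_sigma > 0:
            f = f + rng.normal(0.0, spec.noise_sigma, shape)
        frames[k] = _quantize(f)
    stack = ImageStack(frames=frames, pixel_size_um=px,
                       frame_rate_hz=spec.frame_rate_hz)
    if return_tracks:
        return stack, tracks
    return stack


# --------------------------------------------------------------------------
# two-chamber beating-heart phantom
# --------------------------------------------------------------------------

def _smoothstep(x: np.ndarray) -> np.ndarray:
    t = np.clip(x, 0.0, 1.0)
    return t * t * (3 - 2 * t)


class _HeartModel:
    """Prescribed geometry + kinematics of the two-chamber phantom (units μm)."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        av, bv = spec.ventricle_semiaxes_um
        aa, ba = spec.atrium_semiaxes_um
        self.av, self.bv, self.aa, self.ba = av, bv, aa, ba
        self.amp = spec.wall_amplitude
        # antiphase atrium amplitude balancing the ventricle area change
        self.amp_a = self.amp * (av * bv) / (aa * ba)
        self.T = spec.period_s
        m = spec.margin_px * spec.pixel_size_um
        grow = 1.0 + self.amp
        self.cy = m + max(bv, ba) * grow
        self.cx_a = m + aa * grow
        self.cx_v = self.cx_a + aa + spec.canal_length_um + av
        self.width_um = self.cx_v + av * grow + m
        self.height_um = 2 * self.cy
        self.w = spec.canal_width_um
        # blend region: smooth transition over the canal length
        self.x_blend0 = self.cx_a + aa - 0.25 * spec.canal_length_um
        self.x_blend1 = self.cx_v - av + 0.25 * spec.canal_length_um

    # -- kinematic laws ---------------------------------------------------
    def s_v(self, t):
        return 1.0 + self.amp * np.sin(2 * np.pi * t / self.T)

    def sdot_v(self, t):
        return self.amp * (2 * np.pi / self.T) * np.cos(2 * np.pi * t / self.T)

    def s_a(self, t):
        return 1.0 - self.amp_a * np.sin(2 * np.pi * t / self.T)

    def sdot_a(self, t):
        return -self.amp_a * (2 * np.pi / self.T) * np.cos(2 * np.pi * t / self.T)

    def ventricle_area(self, t):
        return np.pi * self.av * self.bv * self.s_v(t) ** 2

    def dA_v_dt(self, t):
        return 2 * np.pi * self.av * self.bv * self.s_v(t) * self.sdot_v(t)

    def canal_u0(self, t):
        """Centerline canal speed (μm/s); flux (2/3)·u0·w = dA_v/dt."""
        return 1.5 * self.dA_v_dt(t) / self.w

    # -- region indicators -------------------------------------------------
    def in_ventricle(self, x, y, t):
        s = self.s_v(t)
        return ((x - self.cx_v) / (self.av * s)) ** 2 + ((y - self.cy) / (self.bv * s)) ** 2 <= 1.0

    def in_atrium(self, x, y, t):
        s = self.s_a(t)
        return ((x - self.cx_a) / (self.aa * s)) ** 2 + ((y - self.cy) / (self.ba * s)) ** 2 <= 1.0

    def in_canal_strip(self, x, y):
        return (np.abs(y - self.cy) <= self.w / 2) & (x >= self.cx_a) & (x <= self.cx_v)

    def lumen(self, x, y, t):
        return self.in_ventricle(x, y, t) | self.in_atrium(x, y, t) | self.in_canal_strip(x, y)

    # -- velocity field ----------------------------------------------------
    def velocity(self, x, y, t):
        """Prescribed velocity (μm/s) at positions (μm) and time t (s)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        sv, sa = self.s_v(t), self.s_a(t)
        rv = self.sdot_v(t) / sv
        ra = self.sdot_a(t) / sa
        om = self.spec.swirl_rad_s
        # dilation (follows the prescribed wall law) + strain-free solid-body
        # swirl emulating the intracardiac vortex; for circular chambers the
        # combined material map is s(t)·R(ωt), so E depends on s(t) alone
        u_v = rv * (x - self.cx_v) - om * (y - self.cy)
        v_v = rv * (y - self.cy) + om * (x - self.cx_v)
        u_a = ra * (x - self.cx_a) - om * (y - self.cy)
        v_a = ra * (y - self.cy) + om * (x - self.cx_a)
        eta = np.clip(2 * (y - self.cy) / self.w, -1, 1)
        u_c = self.canal_u0(t) * (1 - eta**2)
        # partition of unity along x across the canal mouths
        t_a = _smoothstep((x - (self.x_blend0 - 2.0)) / 4.0)   # 0 in atrium, 1 past mouth
        t_v = _smoothstep((x - (self.x_blend1 - 2.0)) / 4.0)   # 0 before mouth, 1 in ventricle
        w_a = 1 - t_a
        w_c = t_a * (1 - t_v)
        w_v = t_v
        in_can = self.in_canal_strip(x, y)
        in_ven = self.in_ventricle(x, y, t)
        in_atr = self.in_atrium(x, y, t)
        lum = in_can | in_ven | in_atr
        u = w_a * u_a + w_c * np.where(in_can, u_c, 0.0) + w_v * u_v
        v = w_a * v_a + w_v * v_v
        u = np.where(lum, u, 0.0)
        v = np.where(lum, v, 0.0)
        return u, v

    def ventricle_contour(self, t, n_pts: int = 200):
        th = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
        s = self.s_v(t)
        return np.column_stack([
            self.cx_v + self.av * s * np.cos(th),
            self.cy + self.bv * s * np.sin(th),
        ])


def _stokes_pressure(model: _HeartModel, mu: float, t: float,
                     h_um: float, shape_px: tuple[int, int],
                     stride: int = 2) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve the Stokes pressure-Poisson problem on the phantom grid.

    ∇²P = ∇·(μ∇²u) with Neumann data μ(∇²u)·n on the lumen boundary and
    P = 0 at the reference node (rightmost ventricle-boundary node, the
    phantom's 'ventricle outflow').  Sparse 5-point discretization.
    """
    ny_px, nx_px = shape_px
    xs = np.arange(0, nx_px, stride) * h_um
    ys = np.arange(0, ny_px, stride) * h_um
    hx = xs[1] - xs[0]
    xx, yy = np.meshgrid(xs, ys)
    lum = model.lumen(xx, yy, t)
    lum = ndimage.binary_erosion(lum, iterations=1)
    u, v = model.velocity(xx, yy, t)

    def lap(f):
        out = np.zeros_like(f)
        out[1:-1, 1:-1] = (
            f[1:-1, 2:] + f[1:-1, :-2] + f[2:, 1:-1] + f[:-2, 1:-1] - 4 * f[1:-1, 1:-1]
        ) / hx**2
        return out

    gx = mu * lap(u)
    gy = mu * lap(v)

    idx = -np.ones(lum.shape, dtype=int)
    nodes = np.argwhere(lum)
    idx[lum] = np.arange(len(nodes))
    n = len(nodes)
    rows_l, cols_l, vals_l = [], [], []
    diag = np.zeros(n)
    b = np.zeros(n)
    # interior faces only: Neumann wall fluxes cancel between the two sides
    # of the discrete divergence theorem, leaving the interior-face sums
    for di, dj, g in ((0, 1, gx), (0, -1, gx), (1, 0, gy), (-1, 0, gy)):
        nb = np.roll(np.roll(lum, -di, axis=0), -dj, axis=1)
        if di > 0:
            nb[-1, :] = False
        if di < 0:
            nb[0, :] = False
        if dj > 0:
            nb[:, -1] = False
        if dj < 0:
            nb[:, 0] = False
        pair = lum & nb
        src = idx[pair]
        tgt = np.roll(np.roll(idx, -di, axis=0), -dj, axis=1)[pair]
        g_nb = np.roll(np.roll(g, -di, axis=0), -dj, axis=1)
        rows_l.append(src)
        cols_l.append(tgt)
        vals_l.append(np.ones(src.size))
        np.add.at(diag, src, -1.0)
        np.add.at(b, src, (di + dj) * 0.5 * (g[pair] + g_nb[pair]) * hx)
    rows = np.concatenate(rows_l + [np.arange(n)])
    cols = np.concatenate(cols_l + [np.arange(n)])
    vals = np.concatenate(vals_l + [diag])
    # anchor: rightmost lumen node on the ventricle midline ('outflow' node)
    ref_candidates = nodes[np.abs(ys[nodes[:, 0]] - model.cy) < 2 * hx]
    ref_node = ref_candidates[np.argmax(xs[ref_candidates[:, 1]])]
    ref_k = idx[ref_node[0], ref_node[1]]
    keep = rows != ref_k
    rows = np.append(rows[keep], ref_k)
    cols = np.append(cols[keep], ref_k)
    vals = np.append(vals[keep], 1.0)
    b[ref_k] = 0.0
    a_mat = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    p_vec = splinalg.spsolve(a_mat, b)
    p_grid = np.zeros(lum.shape)
    p_grid[lum] = p_vec
    p_grid[~lum] = np.nan
    return p_grid, xs, ys


def generate_phantom_heart(
    spec: PhantomSpec,
    compute_pressure: bool = True,
    pressure_stride_px: int = 2,
    max_pressure_phases: int = 100,
) -> tuple[ImageStack, GroundTruth]:
    """Render the two-chamber beating-heart phantom and its ground truth.

    The ventricle dilates by ``s_v(t) = 1 + a·sin(2πt/T)`` and the atrium
    contracts in antiphase; the connecting canal carries a parabolic profile
    whose flux equals the ventricle's area rate (2D incompressibility).
    Ground truth includes the prescribed velocity field (as a callable), the
    Stokes-solved pressure at sampled phases, per-phase wall contours, the
    seeded hematocrit, and closed-form ejection fraction and strain laws.
    """
    if spec.geometry != "two-chamber":
        raise ValueError("generate_phantom_heart requires the two-chamber geometry")
    model = _HeartModel(spec)
    px = spec.pixel_size_um
    nx_px = int(np.ceil(model.width_um / px))
    ny_px = int(np.ceil(model.height_um / px))
    shape = (ny_px, nx_px)
    rng = np.random.default_rng(spec.seed)
    fpc = spec.frames_per_cycle
    dt = 1.0 / spec.frame_rate_hz
    n_frames = spec.n_frames

    # --- seeding: uniform in the lumen at t = 0 --------------------------
    lumen_area_um2 = (
        np.pi * model.av * model.bv + np.pi * model.aa * model.ba
        + spec.canal_width_um * spec.canal_length_um
    )
    n_part = spec.n_particles
    if n_part == 0:
        # protocol seeding density: ~12 patterns per 48x48 px window
        density_per_px2 = 12.0 / 48.0**2
        n_part = int(round(density_per_px2 * lumen_area_um2 / px**2))
    pos = []
    while len(pos) < n_part:
        cand_x = rng.uniform(0, model.width_um, 4 * n_part)
        cand_y = rng.uniform(0, model.height_um, 4 * n_part)
        ok = model.lumen(cand_x, cand_y, 0.0)
        pos.extend(np.column_stack([cand_x[ok], cand_y[ok]])[: n_part - len(pos)])
    pos0_px = np.asarray(pos) / px

    def vel_px(xs, ys, frame_idx):
        t = frame_idx * dt
        u, v = model.velocity(xs * px, ys * px, t)
        return u * dt / px, v * dt / px

    def sample_lumen(count, t):
        out = []
        while len(out) < count:
            cx = rng.uniform(0, model.width_um, 4 * count + 8)
            cyc = rng.uniform(0, model.height_um, 4 * count + 8)
            ok = model.lumen(cx, cyc, t)
            out.extend(np.column_stack([cx[ok], cyc[ok]])[: count - len(out)])
        return np.asarray(out) / px

    # advection with out-of-plane turnover: a fraction of tracers is swapped
    # for fresh ones each frame, emulating tracer exchange across the focal slab
    tracks = np.empty((n_frames, n_part, 2))
    pos = pos0_px.copy()
    for k in range(n_frames):
        tracks[k] = pos
        if k + 1 < n_frames:
            if spec.turnover_fraction > 0 and n_part:
                swap = rng.random(n_part) < spec.turnover_fraction
                if swap.any():
                    pos[swap] = sample_lumen(int(swap.sum()), k * dt)
            u1, v1 = vel_px(pos[:, 0], pos[:, 1], k)
            midp = pos + 0.5 * np.column_stack([u1, v1])
            u2, v2 = vel_px(midp[:, 0], midp[:, 1], k)
            pos = pos + np.column_stack([u2, v2])
    visible = rng.random((n_frames, n_part)) >= spec.dropout_fraction

    bg = _background(shape, spec.background_amplitude, rng)
    frames = np.empty((n_frames, *shape), dtype=np.uint16)
    static = spec.wall_amplitude == 0
    for k in range(n_frames):
        f = bg.copy()
        vis = visible[k]
        _render_blobs(f, tracks[k, vis, 0], tracks[k, vis, 1],
                      spec.particle_peak, spec.particle_sigma_px)
        if spec.noise_sigma > 0:
            f = f + rng.normal(0.0, spec.noise_sigma, shape)
        frames[k] = _quantize(f)
    stack = ImageStack(frames=frames, pixel_size_um=px,
                       frame_rate_hz=spec.frame_rate_hz)

    # --- ground truth ------------------------------------------------------
    pair_times = (np.arange(fpc - 1) + 0.5) * dt  # mid-pair times, one cycle
    ht = 100.0 * spec.rbc_volume_um3 * n_part / (lumen_area_um2 * spec.depth_of_focus_um)
    # viscosity from the rheology model at the phantom's own Ht and peak shear
    from .rheology import RheologyModel, walburn_schneck_viscosity

    u0_max = float(np.max(np.abs(model.canal_u0(pair_times)))) if not static else 0.0
    gamma_peak = 4.0 * u0_max / model.w if u0_max > 0 else 1.0
    mu = walburn_schneck_viscosity(ht, gamma_peak, RheologyModel())

    pressure = None
    p_x = p_y = p_t = None
    dp_avc = None
    if compute_pressure and not static:
        stride_ph = max(1, int(np.ceil((fpc - 1) / max_pressure_phases)))
        sel = np.arange(0, fpc - 1, stride_ph)
        p_t = pair_times[sel]
        planes = []
        for t in p_t:
            plane, p_x, p_y = _stokes_pressure(model, mu, t, px, shape,
                                               stride=pressure_stride_px)
            planes.append(plane)
        pressure = np.asarray(planes)
        # probe series: disc-averaged chamber pressures (atrium minus ventricle)
        dp_avc = np.array([
            _disc_mean(planes[i], p_x, p_y, model.cx_a, model.cy, 3.0)
            - _disc_mean(planes[i], p_x, p_y, model.cx_v, model.cy, 3.0)
            for i in range(len(planes))
        ])

    contours = [model.ventricle_contour(t) for t in pair_times]
    s_ref = 1.0 - spec.wall_amplitude  # end of ventricle systole: minimum scale
    lam = model.s_v(pair_times) / s_ref
    strain_pct = 100.0 * 0.5 * (lam**2 - 1.0)
    ef = 100.0 * (1.0 - ((1 - spec.wall_amplitude) / (1 + spec.wall_amplitude)) ** 3)

    gt = GroundTruth(
        period_s=spec.period_s,
        velocity_fn=model.velocity,
        lumen_fn=model.lumen,
        pressure=pressure,
        pressure_x_um=p_x,
        pressure_y_um=p_y,
        pressure_times_s=p_t,
        wall_contours=contours,
        ht_pct=ht,
        mu_pa_s=mu,
        extras={
            "model": model,
            "hr_bpm": 60.0 / spec.period_s,
            "ef_pct": ef,
            "strain_pct": strain_pct,
            "pair_times_s": pair_times,
            "dp_avc_pa": dp_avc,
            "gamma_peak_s": gamma_peak,
            "n_particles": n_part,
            "tracks_px": tracks,
            "canal_u0_um_s": model.canal_u0(pair_times),
        },
    )
    return stack, gt


def _disc_mean(plane: np.ndarray, xs: np.ndarray, ys: np.ndarray,
               cx: float, cy: float, r_um: float) -> float:
    xx, yy = np.meshgrid(xs, ys)
    sel = ((xx - cx) ** 2 + (yy - cy) ** 2 <= r_um**2) & np.isfinite(plane)
    return float(plane[sel].mean())
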