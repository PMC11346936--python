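"""Phase-resolved relative pressure from velocity fields.

The pressure gradient is assembled from the rearranged incompressible
Navier–Stokes equation  ∇P = −ρ(∂u/∂t + u·∇u) + μ∇²u.  For embryonic-heart
flow both Re and Wo are ≪ 1, so the creeping-flow mode (viscous term only)
is the default; the full unsteady form sits behind ``include_inertia``.

Integration uses an omnidirectional multi-path scheme: the gradient is
integrated with the second-order trapezoidal rule along parallel-ray families
in eight grid orientations (axes and diagonals), ray-origin values are
refreshed from the previous iterate, and the per-node average is iterated
until the normalized pressure residual converges below 1e-3.  Pressure is
relative, with P := 0 at a fixed reference node on the boundary, and is also
reported non-dimensionalized by heart rate × dynamic viscosity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .core import GradientField, PhaseVelocityField
from .fieldops import laplacian, velocity_gradients
from .rheology import FluidProperties

__all__ = [
    "PressureField",
    "CanalRegion",
    "PressureDropSeries",
    "pressure_gradient",
    "omnidirectional_integrate",
    "nondimensionalize",
    "canal_pressure_drop",
]

#: ρ[kg/m³]·(μm/s²) → Pa/μm
_INERTIA_TO_PA_PER_UM = 1e-12

_DIRECTIONS = [(0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1)]


@dataclass
class PressureField:
    """Relative pressure on the velocity grid (Pa), P = 0 at the reference node."""

    pressure: np.ndarray               # (n_phases, ny, nx), Pa; 0 outside mask
    x: np.ndarray
    y: np.ndarray
    mask: np.ndarray                   # (ny, nx) or (n_phases, ny, nx)
    reference_node: tuple[int, int]
    residuals: np.ndarray
    converged: np.ndarray
    n_orientations: int = 8
    nondim: Optional[np.ndarray] = None   # P / (HR·μ)
    hr_bpm: Optional[float] = None
    mu_pa_s: Optional[float] = None

    @property
    def n_phases(self) -> int:
        return self.pressure.shape[0]

    def mask_at(self, phase: int) -> np.ndarray:
        return self.mask if self.mask.ndim == 2 else self.mask[phase]


@dataclass
class CanalRegion:
    """Probe pair bracketing a canal (AVC or OFT).

    ΔP is measured as upstream minus downstream over small averaging discs;
    the positive sign is the forward-flow direction.
    """

    label: str
    upstream_um: tuple[float, float]
    downstream_um: tuple[float, float]
    radius_um: float = 2.0

    def __post_init__(self) -> None:
        if tuple(self.upstream_um) == tuple(self.downstream_um):
            raise ValueError("upstream and downstream probes must differ")


@dataclass
class PressureDropSeries:
    """Per-phase pressure drop across a canal region."""

    label: str
    times_s: np.ndarray
    dp_pa: np.ndarray
    dp_nondim: Optional[np.ndarray]
    missing: np.ndarray
    retrograde: np.ndarray = dc_field(init=False)
    peak_pa: float = dc_field(init=False)
    peak_phase: int = dc_field(init=False)

    def __post_init__(self) -> None:
        self.retrograde = np.nan_to_num(self.dp_pa) < 0
        valid = ~self.missing
        if valid.any():
            k = int(np.nanargmax(np.abs(np.where(valid, self.dp_pa, np.nan))))
            self.peak_pa = float(self.dp_pa[k])
            self.peak_phase = k
        else:
            self.peak_pa = np.nan
            self.peak_phase = -1


# --------------------------------------------------------------------------
# gradient assembly
# --------------------------------------------------------------------------

def pressure_gradient(
    field: PhaseVelocityField,
    grads: Optional[GradientField] = None,
    fluid: FluidProperties = FluidProperties(),
    include_inertia: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble ∇P (Pa/μm) per node from the phase-averaged velocity field.

    Creeping-flow default keeps only μ∇²u; with ``include_inertia`` the
    unsteady and convective terms −ρ(∂u/∂t + u·∇u) are added (central
    difference in phase-time, cyclic).
    """
    lap_u, lap_v = laplacian(field)
    mu = fluid.viscosity_pa_s
    gx = mu * lap_u
    gy = mu * lap_v
    if include_inertia:
        if field.n_phases < 3:
            raise ValueError("the unsteady term needs at least 3 phases")
        if grads is None:
            grads = velocity_gradients(field)
        dt = field.dt_s
        dudt = (np.roll(field.u, -1, axis=0) - np.roll(field.u, 1, axis=0)) / (2 * dt)
        dvdt = (np.roll(field.v, -1, axis=0) - np.roll(field.v, 1, axis=0)) / (2 * dt)
        conv_u = field.u * grads.du_dx + field.v * grads.du_dy
        conv_v = field.u * grads.dv_dx + field.v * grads.dv_dy
        rho = fluid.density_kg_m3
        gx = gx - rho * (dudt + conv_u) * _INERTIA_TO_PA_PER_UM
        gy = gy - rho * (dvdt + conv_v) * _INERTIA_TO_PA_PER_UM
    return gx, gy


# --------------------------------------------------------------------------
# omnidirectional multi-path integration
# --------------------------------------------------------------------------

def _ray_runs(mask: np.ndarray, di: int, dj: int):
    """Mask-connected runs of grid nodes along parallel rays in direction (di, dj).

    Returns flat node indices in traversal order plus, per element, the flat
    position and node index of its run start.
    """
    ny, nx = mask.shape
    order: list[int] = []
    seg_start_pos: list[int] = []
    seg_start_node: list[int] = []

    if di == 0:
        starts = [(i, 0 if dj > 0 else nx - 1) for i in range(ny)]
    elif dj == 0:
        starts = [(0 if di > 0 else ny - 1, j) for j in range(nx)]
    else:
        i0 = 0 if di > 0 else ny - 1
        j0 = 0 if dj > 0 else nx - 1
        starts = [(i0, j) for j in range(nx)] + [(i, j0) for i in range(ny) if i != i0]

    for si, sj in starts:
        i, j = si, sj
        cur_start_pos = cur_start_node = None
        while 0 <= i < ny and 0 <= j < nx:
            if mask[i, j]:
                flat = i * nx + j
                if cur_start_pos is None:
                    cur_start_pos = len(order)
                    cur_start_node = flat
                order.append(flat)
                seg_start_pos.append(cur_start_pos)
                seg_start_node.append(cur_start_node)
            else:
                cur_start_pos = cur_start_node = None
            i += di
            j += dj
    return (np.asarray(order, dtype=int),
            np.asarray(seg_start_pos, dtype=int),
            np.asarray(seg_start_node, dtype=int))


def _precompute_paths(mask: np.ndarray, dx: float, dy: float):
    paths = []
    for di, dj in _DIRECTIONS:
        order, spos, snode = _ray_runs(mask, di, dj)
        paths.append({"order": order, "spos": spos, "snode": snode,
                      "step": (dj * dx, di * dy)})
    return paths


def omnidirectional_integrate(
    gx: np.ndarray,
    gy: np.ndarray,
    mask: np.ndarray,
    dx: float,
    dy: float,
    reference_node: tuple[int, int],
    tol: float = 1e-3,
    max_iter: int = 400,
) -> tuple[np.ndarray, float, bool]:
    """Integrate one phase's ∇P over the mask; returns (P, residual, converged).

    Trapezoidal line integrals along 8 ray orientations are averaged per node;
    ray-origin values are refreshed from the previous iterate until the
    residual (max per-node change normalized by the field range) meets
    ``tol``.  P is anchored to zero at ``reference_node``.
    """
    ny, nx = mask.shape
    if not mask[reference_node]:
        raise ValueError("reference node must lie inside the mask")
    paths = _precompute_paths(mask, dx, dy)
    gxf = gx.ravel()
    gyf = gy.ravel()
    for p in paths:
        order = p["order"]
        if order.size == 0:
            p["inc"] = np.zeros(0)
            continue
        sx, sy = p["step"]
        prev = np.empty_like(order)
        prev[1:] = order[:-1]
        prev[0] = order[0]
        inc = 0.5 * ((gxf[order] + gxf[prev]) * sx + (gyf[order] + gyf[prev]) * sy)
        inc[p["spos"] == np.arange(order.size)] = 0.0
        p["inc"] = inc
        p["cum"] = np.cumsum(inc)

    ref_flat = reference_node[0] * nx + reference_node[1]
    p_flat = np.zeros(ny * nx)
    n_mask = int(mask.sum())
    count = np.zeros(ny * nx)
    for p in paths:
        np.add.at(count, p["order"], 1.0)
    count[count == 0] = 1.0

    residual = np.inf
    converged = False
    for _ in range(max_iter):
        acc = np.zeros(ny * nx)
        for p in paths:
            order = p["order"]
            if order.size == 0:
                continue
            vals = p_flat[p["snode"]] + p["cum"] - p["cum"][p["spos"]] + p["inc"][p["spos"]]
            np.add.at(acc, order, vals)
        p_new = acc / count
        p_new -= p_new[ref_flat]
        scale = np.ptp(p_new[mask.ravel()]) if n_mask > 1 else 1.0
        residual = float(np.max(np.abs(p_new - p_flat)[mask.ravel()]) / (scale + 1e-300))
        p_flat = p_new
        if residual <= tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"pressure integration did not reach residual {tol:g} "
                      f"(achieved {residual:.2e})", stacklevel=2)
    out = np.zeros((ny, nx))
    out.ravel()[mask.ravel()] = p_flat[mask.ravel()]
    return out, residual, converged


def solve_pressure(
    field: PhaseVelocityField,
    fluid: FluidProperties,
    reference_node: tuple[int, int] | None = None,
    include_inertia: bool = False,
    mask: Optional[np.ndarray] = None,
    tol: float = 1e-3,
    max_iter: int = 400,
) -> PressureField:
    """Convenience driver: assemble ∇P and integrate every phase."""
    gx, gy = pressure_gradient(field, fluid=fluid, include_inertia=include_inertia)
    if mask is None:
        mask = field.mask.all(axis=0)
    if reference_node is None:
        ii, jj = np.argwhere(mask)[0]
        reference_node = (int(ii), int(jj))
    planes, residuals, conv = [], [], []
    for p in range(field.n_phases):
        plane, res, ok = omnidirectional_integrate(
            gx[p], gy[p], mask, field.dx_um, field.dy_um, reference_node,
            tol=tol, max_iter=max_iter,
        )
        planes.append(plane)
        residuals.append(res)
        conv.append(ok)
    return PressureField(
        pressure=np.asarray(planes),
        x=field.x,
        y=field.y,
        mask=mask,
        reference_node=tuple(reference_node),
        residuals=np.asarray(residuals),
        converged=np.asarray(conv),
    )


def nondimensionalize(p_field: PressureField, hr_bpm: float, mu_pa_s: float) -> np.ndarray:
    """P / (HR·μ) with HR converted to s⁻¹; stored on the field and returned."""
    if hr_bpm <= 0 or mu_pa_s <= 0:
        raise ValueError("heart rate and viscosity must be positive")
    hr_hz = hr_bpm / 60.0
    nondim = p_field.pressure / (hr_hz * mu_pa_s)
    p_field.nondim = nondim
    p_field.hr_bpm = hr_bpm
    p_field.mu_pa_s = mu_pa_s
    return nondim


def canal_pressure_drop(
    p_field: PressureField,
    region: CanalRegion,
    times_s: Optional[np.ndarray] = None,
) -> PressureDropSeries:
    """ΔP(phase) = P(upstream) − P(downstream), disc-averaged.

    Negative values are permitted and flagged as retrograde.  Phases where a
    probe disc leaves the valid mask are marked missing, never interpolated.
    """
    xx, yy = np.meshgrid(p_field.x, p_field.y)
    r2 = region.radius_um**2
    up = (xx - region.upstream_um[0]) ** 2 + (yy - region.upstream_um[1]) ** 2 <= r2
    dn = (xx - region.downstream_um[0]) ** 2 + (yy - region.downstream_um[1]) ** 2 <= r2
    if not up.any() or not dn.any():
        # fall back to the nearest single node
        def nearest(locus):
            d2 = (xx - locus[0]) ** 2 + (yy - locus[1]) ** 2
            m = np.zeros_like(d2, dtype=bool)
            m.ravel()[np.argmin(d2)] = True
            return m
        up = up if up.any() else nearest(region.upstream_um)
        dn = dn if dn.any() else nearest(region.downstream_um)
    n = p_field.n_phases
    dp = np.full(n, np.nan)
    dp_nd = np.full(n, np.nan) if p_field.nondim is not None else None
    missing = np.ones(n, dtype=bool)
    for p in range(n):
        m = p_field.mask_at(p)
        u_sel = up & m
        d_sel = dn & m
        if not u_sel.any() or not d_sel.any():
            continue
        dp[p] = p_field.pressure[p][u_sel].mean() - p_field.pressure[p][d_sel].mean()
        if dp_nd is not None:
            dp_nd[p] = p_field.nondim[p][u_sel].mean() - p_field.nondim[p][d_sel].mean()
        missing[p] = False
    if times_s is None:
        times_s = np.arange(n, dtype=float)
    return PressureDropSeries(
        label=region.label, times_s=times_s, dp_pa=dp, dp_nondim=dp_nd, missing=missing,
    )
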