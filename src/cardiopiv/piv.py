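"""Ensemble phase-correlation micro-PIV engine.

Velocity fields are recovered from brightfield sequences in four stages:

1. **POD background removal** — a singular-value decomposition of the image
   time series; the leading modes carry the (dominant) static background and
   are discarded, retaining the non-dominant modes that represent the moving
   red-blood-corpuscle patterns.
2. **Multi-pass cross-correlation with iterative window deformation** — a
   coarse-to-fine pass schedule (default 96/48 at 50%, 64/32 at 50%, 64/32 at
   75% overlap); within each pass both frames of a pair are symmetrically
   deformed by ± half the predictor field and re-correlated until the
   displacement update falls below 0.1 px (min 3 / max 6 iterations), with
   Blackman apodization of the interrogation windows.
3. **Ensemble phase averaging** — correlation planes from the same cardiac
   phase of every recorded cycle are averaged before peak detection, raising
   the correlation signal-to-noise ratio.
4. **Subpixel peak fit and validation** — three-point Gaussian estimator
   (parabolic / integer fallback), universal normalized-median outlier test
   between passes, and a final-pass 3×3 vector median filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .core import ImageStack, PhaseVelocityField

__all__ = [
    "PassSchedule",
    "pod_background_removal",
    "ensemble_piv",
    "validate_vectors",
    "correlation_peak_ratio",
    "ensemble_correlation_plane",
]


DEFAULT_PASSES = [(96, 48, 0.50), (64, 32, 0.50), (64, 32, 0.75)]


@dataclass
class PassSchedule:
    """Ordered (window size, window resolution, overlap) passes plus bounds."""

    passes: list = dc_field(default_factory=lambda: [tuple(p) for p in DEFAULT_PASSES])
    min_iterations: int = 3
    max_iterations: int = 6
    apodization: str = "blackman"
    convergence_px: float = 0.1

    def __post_init__(self) -> None:
        for win, res, ov in self.passes:
            if res > win:
                raise ValueError("window_resolution must not exceed window size")
            if not 0 <= ov < 1:
                raise ValueError("overlap must lie in [0, 1)")
        if self.min_iterations > self.max_iterations:
            raise ValueError("min iterations must not exceed max iterations")

    def grid_spacing_px(self, pass_index: int = -1) -> float:
        win, res, ov = self.passes[pass_index]
        return res * (1.0 - ov)


# --------------------------------------------------------------------------
# POD background removal
# --------------------------------------------------------------------------

def pod_background_removal(
    stack: ImageStack,
    energy_cutoff: float = 0.90,
    n_modes: int | None = None,
) -> ImageStack:
    """Strip the dominant (background) modes from an image time series.

    The stack is reshaped to a snapshot matrix and decomposed by SVD; the
    smallest number of leading modes whose cumulative energy reaches
    ``energy_cutoff`` is discarded (or exactly ``n_modes`` when given), and
    frames are reconstructed from the trailing modes.  In brightfield
    sequences the static background dominates the energy, so the retained
    fluctuation modes are the moving tracer patterns.
    """
    if stack.n_frames < 3:
        raise ValueError("POD needs at least 3 frames")
    if not 0 < energy_cutoff < 1:
        raise ValueError("energy_cutoff must lie in (0, 1)")
    t, ny, nx = stack.frames.shape
    snaps = stack.frames.reshape(t, ny * nx).astype(float)
    total = float((snaps**2).sum())
    if total <= 0:
        raise ValueError(
            "degenerate decomposition: the stack carries no energy; "
            "check the input images (all-zero frames?)"
        )
    u_m, s, vt = np.linalg.svd(snaps, full_matrices=False)
    energy = s**2
    frac = np.cumsum(energy) / energy.sum()
    if n_modes is None:
        k = int(np.searchsorted(frac, energy_cutoff) + 1)
    else:
        k = int(n_modes)
    k = min(max(k, 1), len(s))
    recon = (u_m[:, k:] * s[k:]) @ vt[k:]
    return ImageStack(
        frames=recon.reshape(t, ny, nx),
        pixel_size_um=stack.pixel_size_um,
        frame_rate_hz=stack.frame_rate_hz,
        magnification=stack.magnification,
    )


# --------------------------------------------------------------------------
# correlation primitives
# --------------------------------------------------------------------------

def _apodization_window(win: int, name: str) -> np.ndarray:
    if name == "blackman":
        w1 = np.blackman(win)
    elif name in (None, "none", "rect"):
        w1 = np.ones(win)
    else:
        raise ValueError(f"unknown apodization window {name!r}")
    return np.outer(w1, w1)


def _node_grid(shape: tuple[int, int], win: int, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = shape
    margin = win // 2
    if win > min(ny, nx):
        raise ValueError(f"window {win} px larger than image {shape}")
    xs = np.arange(margin, nx - margin + 1, spacing)
    ys = np.arange(margin, ny - margin + 1, spacing)
    return xs.astype(float), ys.astype(float)


def _extract_windows(img: np.ndarray, xs: np.ndarray, ys: np.ndarray, win: int) -> np.ndarray:
    """(n_nodes, win, win) windows centered on the grid xs × ys."""
    jj, ii = np.meshgrid(np.asarray(xs), np.asarray(ys))
    return _extract_windows_flat(img, jj.ravel(), ii.ravel(), win)


def _extract_windows_flat(img: np.ndarray, cx: np.ndarray, cy: np.ndarray, win: int) -> np.ndarray:
    """(n, win, win) windows centered on flat center lists."""
    view = np.lib.stride_tricks.sliding_window_view(img, (win, win))
    tl_x = np.clip(np.round(cx).astype(int) - win // 2, 0, img.shape[1] - win)
    tl_y = np.clip(np.round(cy).astype(int) - win // 2, 0, img.shape[0] - win)
    return view[tl_y, tl_x].astype(float)


def _correlate(batch1: np.ndarray, batch2: np.ndarray, apod: np.ndarray) -> np.ndarray:
    """Zero-padded FFT cross-correlation planes, zero lag at the center."""
    win = batch1.shape[-1]
    pad = 2 * win
    a = (batch1 - batch1.mean(axis=(-2, -1), keepdims=True)) * apod
    b = (batch2 - batch2.mean(axis=(-2, -1), keepdims=True)) * apod
    fa = np.fft.rfft2(a, s=(pad, pad))
    fb = np.fft.rfft2(b, s=(pad, pad))
    corr = np.fft.irfft2(np.conj(fa) * fb, s=(pad, pad))
    return np.fft.fftshift(corr, axes=(-2, -1))


def _subpixel_peaks(corr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized peak location per plane with 3-point Gaussian estimator.

    Returns (dx, dy, quality_flag); flag 0 = Gaussian fit, 1 = parabolic
    fallback, 2 = integer peak, 3 = invalid (flat plane).  Ties between equal
    peaks are broken toward the smaller displacement magnitude.
    """
    n, py, px = corr.shape
    cy, cx = py // 2, px // 2
    interior = corr.copy()
    interior[:, 0, :] = -np.inf
    interior[:, -1, :] = -np.inf
    interior[:, :, 0] = -np.inf
    interior[:, :, -1] = -np.inf
    flat = interior.reshape(n, -1)
    peak_val = flat.max(axis=1)
    # tie-break toward smaller displacement: penalize radius by a tiny amount
    yy, xx = np.mgrid[0:py, 0:px]
    r2 = ((yy - cy) ** 2 + (xx - cx) ** 2).ravel()
    is_peak = flat >= (peak_val[:, None] - 1e-12 * np.abs(peak_val[:, None]) - 1e-300)
    big = np.where(is_peak, r2[None, :], np.inf)
    arg = big.argmin(axis=1)
    iy, ix = np.unravel_index(arg, (py, px))

    idx = np.arange(n)
    c0 = corr[idx, iy, ix]
    cxm = corr[idx, iy, ix - 1]
    cxp = corr[idx, iy, ix + 1]
    cym = corr[idx, iy - 1, ix]
    cyp = corr[idx, iy + 1, ix]

    flag = np.zeros(n, dtype=np.int8)
    invalid = ~np.isfinite(c0) | (np.abs(c0) <= 1e-300) | (np.ptp(flat, axis=1) <= 0)
    flag[invalid] = 3

    def one_axis(cm, c0v, cp):
        ok_g = (cm > 0) & (c0v > 0) & (cp > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            lm, l0, lp = np.log(np.where(ok_g, cm, 1)), np.log(np.where(ok_g, c0v, 1)), np.log(np.where(ok_g, cp, 1))
            den_g = lm - 2 * l0 + lp
            gauss = 0.5 * (lm - lp) / den_g
            den_p = cm - 2 * c0v + cp
            para = 0.5 * (cm - cp) / den_p
        gauss = np.where(ok_g & (den_g < 0) & np.isfinite(gauss), gauss, np.nan)
        para = np.where((den_p < 0) & np.isfinite(para), para, np.nan)
        sub = np.where(np.isfinite(gauss), gauss, np.where(np.isfinite(para), para, 0.0))
        used = np.where(np.isfinite(gauss), 0, np.where(np.isfinite(para), 1, 2)).astype(np.int8)
        sub = np.clip(sub, -1, 1)
        return sub, used

    sub_x, used_x = one_axis(cxm, c0, cxp)
    sub_y, used_y = one_axis(cym, c0, cyp)
    flag = np.where(invalid, 3, np.maximum(used_x, used_y)).astype(np.int8)
    dx = np.where(invalid, 0.0, ix - cx + sub_x)
    dy = np.where(invalid, 0.0, iy - cy + sub_y)
    return dx, dy, flag


def correlation_peak_ratio(plane: np.ndarray, exclusion: int = 2) -> float:
    """Primary-to-secondary peak ratio of one correlation plane."""
    p = plane.copy()
    p[0, :] = p[-1, :] = -np.inf
    p[:, 0] = p[:, -1] = -np.inf
    iy, ix = np.unravel_index(np.argmax(p), p.shape)
    primary = p[iy, ix]
    y0, y1 = max(iy - exclusion, 0), min(iy + exclusion + 1, p.shape[0])
    x0, x1 = max(ix - exclusion, 0), min(ix + exclusion + 1, p.shape[1])
    p[y0:y1, x0:x1] = -np.inf
    secondary = p.max()
    if not np.isfinite(secondary) or secondary <= 0:
        return np.inf
    return float(primary / secondary)


# --------------------------------------------------------------------------
# outlier validation
# --------------------------------------------------------------------------

def _normalized_median_outliers(
    u: np.ndarray, v: np.ndarray, threshold: float, neighborhood: int, eps: float
) -> np.ndarray:
    """Universal (normalized-median) outlier mask for one phase."""
    k = neighborhood
    footprint = np.ones((k, k), bool)
    footprint[k // 2, k // 2] = False
    out = np.zeros(u.shape, dtype=bool)
    for comp in (u, v):
        med = ndimage.median_filter(comp, footprint=footprint, mode="nearest")
        resid = np.abs(comp - med)
        med_resid = ndimage.median_filter(resid, footprint=footprint, mode="nearest")
        out |= resid / (med_resid + eps) > threshold
    return out


def validate_vectors(
    field: PhaseVelocityField,
    threshold: float = 2.0,
    neighborhood: int = 3,
    eps: float | None = None,
    final_median_filter: bool = False,
) -> PhaseVelocityField:
    """Universal outlier detection with neighborhood-median replacement.

    A vector whose normalized fluctuation against the neighborhood (default
    3×3) median exceeds ``threshold`` (default 2) is flagged and replaced by
    that median.  With ``final_median_filter`` a 3×3 vector median filter is
    additionally applied, as done on the last correlation pass.  Replaced
    vectors are recorded in the ``replaced`` mask.
    """
    if neighborhood % 2 == 0 or neighborhood < 3:
        raise ValueError("neighborhood must be odd and >= 3")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min(field.u.shape[1:]) < neighborhood:
        warnings.warn("field smaller than the validation neighborhood; skipped",
                      stacklevel=2)
        return field.copy()
    out = field.copy()
    if eps is None:
        scale = np.median(np.abs(field.u[field.mask])) + np.median(np.abs(field.v[field.mask]))
        eps = max(0.02 * scale, 1e-12)
    replaced = np.zeros(field.u.shape, dtype=bool)
    k = neighborhood
    footprint = np.ones((k, k), bool)
    footprint[k // 2, k // 2] = False
    for p in range(field.n_phases):
        bad = _normalized_median_outliers(out.u[p], out.v[p], threshold, k, eps)
        bad &= field.mask[p]
        if bad.any():
            med_u = ndimage.median_filter(out.u[p], footprint=footprint, mode="nearest")
            med_v = ndimage.median_filter(out.v[p], footprint=footprint, mode="nearest")
            out.u[p][bad] = med_u[bad]
            out.v[p][bad] = med_v[bad]
            replaced[p] = bad
        if final_median_filter:
            out.u[p] = ndimage.median_filter(out.u[p], size=3, mode="nearest")
            out.v[p] = ndimage.median_filter(out.v[p], size=3, mode="nearest")
    out.replaced = replaced
    return out


# --------------------------------------------------------------------------
# ensemble PIV driver
# --------------------------------------------------------------------------

def _signal_mask(frames: np.ndarray) -> np.ndarray:
    """Pixels carrying tracer fluctuation signal (True) vs background noise.

    The temporal fluctuation amplitude is strongly bimodal when part of the
    frame is flow-free (noise-level only); in that case an Otsu split
    separates the classes.  When no clear separation exists (whole-frame
    flow) everything is kept.
    """
    var = frames.var(axis=0)
    noise = np.percentile(var, 5)  # flow-free pixels carry sensor noise only
    excess = ndimage.gaussian_filter(np.clip(var - noise, 0, None), 6.0)
    top = np.percentile(excess, 99)
    if top <= 3.0 * noise:  # no tracer fluctuation anywhere above the floor
        return np.ones(var.shape, dtype=bool)
    mask = excess > 0.05 * top
    if mask.mean() > 0.9:
        return np.ones(var.shape, dtype=bool)
    return mask


def _node_signal_valid(signal: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                       core: int, min_fraction: float = 0.3) -> np.ndarray:
    """Node validity: enough signal pixels inside the window-resolution core."""
    frac = np.empty((len(ys), len(xs)))
    h = core // 2
    ny, nx = signal.shape
    for i, yc in enumerate(np.round(ys).astype(int)):
        for j, xc in enumerate(np.round(xs).astype(int)):
            frac[i, j] = signal[max(yc - h, 0): yc + h, max(xc - h, 0): xc + h].mean()
    return frac >= min_fraction


def _phase_pairs(n_frames: int, period: float, n_phases: int) -> list[list[tuple[int, int]]]:
    """Frame-index pairs per phase, one entry per cycle (nearest-phase binning)."""
    pairs: list[list[tuple[int, int]]] = [[] for _ in range(n_phases)]
    n_cycles = int(np.floor(n_frames / period))
    for c in range(max(n_cycles, 1)):
        base = int(round(c * period))
        for p in range(n_phases):
            a = base + p
            if a + 1 < n_frames:
                pairs[p].append((a, a + 1))
    return [ps for ps in pairs]


def _dense_map(xs: np.ndarray, ys: np.ndarray, grid: np.ndarray,
               shape: tuple[int, int]) -> np.ndarray:
    """Bilinear interpolation of node values onto the full pixel raster."""
    ny, nx = shape
    gx = np.clip((np.arange(nx) - xs[0]) / max(xs[1] - xs[0], 1e-9), 0, len(xs) - 1.000001) \
        if len(xs) > 1 else np.zeros(nx)
    gy = np.clip((np.arange(ny) - ys[0]) / max(ys[1] - ys[0], 1e-9), 0, len(ys) - 1.000001) \
        if len(ys) > 1 else np.zeros(ny)
    j0 = np.floor(gx).astype(int)
    i0 = np.floor(gy).astype(int)
    tx = (gx - j0)[None, :]
    ty = (gy - i0)[:, None]
    g = grid
    return (
        g[np.ix_(i0, j0)] * (1 - tx) * (1 - ty)
        + g[np.ix_(i0, j0 + (len(xs) > 1))] * tx * (1 - ty)
        + g[np.ix_(i0 + (len(ys) > 1), j0)] * (1 - tx) * ty
        + g[np.ix_(i0 + (len(ys) > 1), j0 + (len(xs) > 1))] * tx * ty
    )


def ensemble_correlation_plane(
    frames: np.ndarray,
    pairs: list[tuple[int, int]],
    node_xy: tuple[float, float],
    win: int = 32,
    apodization: str = "blackman",
) -> np.ndarray:
    """Average correlation plane of one window over the given frame pairs."""
    apod = _apodization_window(win, apodization)
    xs = np.array([node_xy[0]], dtype=float)
    ys = np.array([node_xy[1]], dtype=float)
    acc = None
    for a, b in pairs:
        w1 = _extract_windows(frames[a].astype(float), xs, ys, win)
        w2 = _extract_windows(frames[b].astype(float), xs, ys, win)
        c = _correlate(w1, w2, apod)[0]
        acc = c if acc is None else acc + c
    return acc / len(pairs)


def ensemble_piv(
    stack: ImageStack,
    schedule: PassSchedule | None = None,
    cycle_period_frames: float | None = None,
) -> PhaseVelocityField:
    """Phase-resolved ensemble-correlation PIV.

    Windows from the same phase of every cycle are cross-correlated pairwise
    and their correlation planes averaged before subpixel peak detection.
    Passes run coarse to fine with symmetric iterative window deformation;
    displacements are converted to μm/s via pixel size × frame rate.
    """
    schedule = schedule or PassSchedule()
    if cycle_period_frames is None:
        cycle_period_frames = stack.n_frames  # single 'cycle': instantaneous mode
    if cycle_period_frames < 2:
        raise ValueError("cycle period must span at least 2 frames")
    if stack.n_frames < 2 * cycle_period_frames:
        warnings.warn("fewer than two cycles available; ensemble reduces to a "
                      "single-cycle estimate", stacklevel=2)
    frames = stack.frames.astype(float)
    shape = frames.shape[1:]
    n_phases = int(np.ceil(cycle_period_frames)) - 1
    phase_pairs = _phase_pairs(stack.n_frames, float(cycle_period_frames), n_phases)
    n_cycles = max(len(phase_pairs[0]), 1)
    signal = _signal_mask(frames)

    xs = ys = None
    disp_u = disp_v = None  # (n_phases, ny, nx) in px/frame
    flags = None

    for p_idx, (win, res, overlap) in enumerate(schedule.passes):
        spacing = res * (1.0 - overlap)
        new_xs, new_ys = _node_grid(shape, win, spacing)
        apod = _apodization_window(win, schedule.apodization)
        if disp_u is None:
            disp_u = np.zeros((n_phases, len(new_ys), len(new_xs)))
            disp_v = np.zeros_like(disp_u)
        else:
            disp_u = _regrid(xs, ys, disp_u, new_xs, new_ys)
            disp_v = _regrid(xs, ys, disp_v, new_xs, new_ys)
        xs, ys = new_xs, new_ys
        flags = np.zeros(disp_u.shape, dtype=np.int8)
        node_ok = _node_signal_valid(signal, xs, ys, core=res)
        disp_u[:, ~node_ok] = 0.0
        disp_v[:, ~node_ok] = 0.0

        phase_done = np.zeros(n_phases, dtype=bool)
        for it in range(schedule.max_iterations):
            max_update = 0.0
            for ph in range(n_phases):
                pairs = phase_pairs[ph]
                if not pairs or (phase_done[ph] and it + 1 >= schedule.min_iterations):
                    continue
                has_pred = np.any(disp_u[ph]) or np.any(disp_v[ph])
                if has_pred:
                    du_map = _dense_map(xs, ys, disp_u[ph], shape)
                    dv_map = _dense_map(xs, ys, disp_v[ph], shape)
                    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
                    c1 = [yy - 0.5 * dv_map, xx - 0.5 * du_map]
                    c2 = [yy + 0.5 * dv_map, xx + 0.5 * du_map]
                jj, ii = np.meshgrid(xs, ys)
                sel = node_ok.ravel()
                if not sel.any():
                    phase_done[ph] = True
                    continue
                cxs = jj.ravel()[sel]
                cys = ii.ravel()[sel]
                acc = None
                for a, b in pairs:
                    f1, f2 = frames[a], frames[b]
                    if has_pred:
                        f1 = ndimage.map_coordinates(f1, c1, order=1, mode="nearest")
                        f2 = ndimage.map_coordinates(f2, c2, order=1, mode="nearest")
                    w1 = _extract_windows_flat(f1, cxs, cys, win)
                    w2 = _extract_windows_flat(f2, cxs, cys, win)
                    c = _correlate(w1, w2, apod)
                    acc = c if acc is None else acc + c
                acc /= len(pairs)
                sdx, sdy, sfl = _subpixel_peaks(acc)
                ddx = np.zeros(node_ok.size)
                ddy = np.zeros(node_ok.size)
                flf = np.full(node_ok.size, 3, dtype=np.int8)
                ddx[sel] = sdx
                ddy[sel] = sdy
                flf[sel] = sfl
                ddx = ddx.reshape(len(ys), len(xs))
                ddy = ddy.reshape(len(ys), len(xs))
                fl = flf.reshape(len(ys), len(xs))
                ok = (fl < 3) & node_ok
                disp_u[ph][ok] += ddx[ok]
                disp_v[ph][ok] += ddy[ok]
                fl[~node_ok] = 3
                # quarter-window rule: larger displacements are unreliable
                over = np.hypot(disp_u[ph], disp_v[ph]) > win / 4.0
                disp_u[ph][over] = 0.0
                disp_v[ph][over] = 0.0
                fl[over] = 3
                flags[ph] = fl
                if ok.any():
                    upd = float(np.max(np.hypot(ddx[ok], ddy[ok])))
                    phase_done[ph] = upd < schedule.convergence_px
                    max_update = max(max_update, upd)
                else:
                    phase_done[ph] = True
            if it + 1 >= schedule.min_iterations and max_update < schedule.convergence_px:
                break

        # validation between passes (final-pass run adds the median filter)
        is_final = p_idx == len(schedule.passes) - 1
        disp_u[:, ~node_ok] = 0.0
        disp_v[:, ~node_ok] = 0.0
        tmp = PhaseVelocityField(
            u=disp_u, v=disp_v, x=xs, y=ys,
            times=np.arange(n_phases, dtype=float),
            mask=flags < 3,
        )
        tmp = validate_vectors(tmp, threshold=2.0, neighborhood=3, eps=0.1,
                               final_median_filter=is_final)
        disp_u, disp_v = tmp.u, tmp.v
        disp_u[:, ~node_ok] = 0.0
        disp_v[:, ~node_ok] = 0.0
        replaced = tmp.replaced & (flags < 3)

    scale = stack.pixel_size_um * stack.frame_rate_hz  # px/frame -> μm/s
    times = (np.arange(n_phases) + 0.5) / stack.frame_rate_hz
    return PhaseVelocityField(
        u=disp_u * scale,
        v=disp_v * scale,
        x=xs * stack.pixel_size_um,
        y=ys * stack.pixel_size_um,
        times=times,
        mask=flags < 3,
        pixel_size_um=stack.pixel_size_um,
        n_cycles=n_cycles,
        replaced=replaced,
    )


def _regrid(xs, ys, grid, new_xs, new_ys):
    """Linear interpolation of per-phase node grids onto a new node grid."""
    out = np.empty((grid.shape[0], len(new_ys), len(new_xs)))
    fx = np.interp(new_xs, xs, np.arange(len(xs)))
    fy = np.interp(new_ys, ys, np.arange(len(ys)))
    j0 = np.minimum(np.floor(fx).astype(int), len(xs) - 2) if len(xs) > 1 else np.zeros(len(new_xs), int)
    i0 = np.minimum(np.floor(fy).astype(int), len(ys) - 2) if len(ys) > 1 else np.zeros(len(new_ys), int)
    tx = (fx - j0)[None, :] if len(xs) > 1 else np.zeros((1, len(new_xs)))
    ty = (fy - i0)[:, None] if len(ys) > 1 else np.zeros((len(new_ys), 1))
    for p in range(grid.shape[0]):
        g = grid[p]
        j1 = j0 + (len(xs) > 1)
        i1 = i0 + (len(ys) > 1)
        out[p] = (
            g[np.ix_(i0, j0)] * (1 - tx) * (1 - ty)
            + g[np.ix_(i0, j1)] * tx * (1 - ty)
            + g[np.ix_(i1, j0)] * (1 - tx) * ty
            + g[np.ix_(i1, j1)] * tx * ty
        )
    return out
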