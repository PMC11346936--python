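"""Hematocrit estimation and Walburn–Schneck blood viscosity.

Teleost blood viscosity is ill-defined, so it is modelled as a function of
hematocrit (Ht, % by volume) and the peak wall shear rate recorded in a
heart cycle via the empirical Walburn–Schneck correlation

    μ = C1 · exp(C2·Ht) · exp(C4·TPMA/Ht²) · γ^(−C3·Ht)

with Ht in percent, γ in 1/s and TPMA (total protein minus albumin) in g/L,
which makes the C4·TPMA/Ht² exponent dimensionless.  The C1 prefactor is
poise-consistent in the original correlation; ``PA_S_PER_POISE`` converts the
result to Pa·s.

Hematocrit is estimated non-invasively from the image sequence itself: the
count of red-blood-corpuscle patterns in a ventricle crop follows from the
time-averaged autocorrelation plane, whose central-peak mass is an integer
multiple of the single-particle correlation mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .core import ImageStack

__all__ = [
    "RheologyModel",
    "FluidProperties",
    "PA_S_PER_POISE",
    "count_rbc_patterns",
    "hematocrit",
    "walburn_schneck_viscosity",
]

#: Conversion from poise (the unit system of the Walburn–Schneck constants)
#: to SI dynamic viscosity.
PA_S_PER_POISE = 0.1


@dataclass(frozen=True)
class RheologyModel:
    """Walburn–Schneck constants (original correlation units)."""

    c1: float = 0.00797
    c2: float = 0.0608
    c3: float = 0.00499
    c4_l_per_g: float = 14.59
    tpma_mg_ml: float = 45.0


@dataclass(frozen=True)
class FluidProperties:
    """Bulk blood properties used by the pressure and similarity numbers."""

    density_kg_m3: float = 1025.0
    viscosity_pa_s: float = 4e-3

    def __post_init__(self) -> None:
        if self.density_kg_m3 <= 0 or self.viscosity_pa_s <= 0:
            raise ValueError("density and viscosity must be positive")


# --------------------------------------------------------------------------
# RBC pattern counting via image autocorrelation
# --------------------------------------------------------------------------

def _mean_autocorrelation(frames: np.ndarray) -> np.ndarray:
    """Average spatial autocorrelation of temporally mean-subtracted frames."""
    f = frames.astype(float)
    f = f - f.mean(axis=0, keepdims=True)  # strip the static background
    f = f - f.mean(axis=(1, 2), keepdims=True)
    spec = np.abs(np.fft.rfft2(f, axes=(1, 2))) ** 2
    acf = np.fft.irfft2(spec, s=frames.shape[1:], axes=(1, 2))
    return np.fft.fftshift(acf.mean(axis=0))


def count_rbc_patterns(
    stack: ImageStack,
    crop: tuple[slice, slice] | None = None,
    noise_guard: float = 1e-6,
) -> float:
    """Estimate the RBC-pattern count inside a crop from the mean autocorrelation.

    A field of N identical non-overlapping Gaussian blobs of amplitude ``a``
    and scale ``σ`` has an autocorrelation central peak of height
    ``N·a²·π·σ²`` and width ``σ·√2``.  The peak height and width are fit from
    the measured average autocorrelation; the blob amplitude is estimated
    robustly from the per-frame maxima of the background-subtracted frames,
    which pins down the single-particle correlation mass and hence N.
    """
    frames = stack.frames if crop is None else stack.frames[(slice(None), *crop)]
    if frames.shape[0] < 10:
        raise ValueError("need at least 10 frames for a stable average autocorrelation")
    frames = frames.astype(float)
    scale = max(frames.max(), 1.0)
    frames = frames / scale

    resid = frames - frames.mean(axis=0, keepdims=True)
    if float(resid.std()) <= noise_guard:
        raise ValueError("featureless crop: no particle signal above the noise floor")

    acf = _mean_autocorrelation(frames)
    ny, nx = acf.shape
    cy, cx = ny // 2, nx // 2
    half = min(8, cy - 1, cx - 1)
    patch = acf[cy - half: cy + half + 1, cx - half: cx + half + 1]
    yy, xx = np.mgrid[-half: half + 1, -half: half + 1]
    rr = np.hypot(xx, yy)

    # exclude the zero-lag pixel (it carries the additive-noise delta)
    sel = (rr > 0.5) & (rr <= half)
    r = rr[sel]
    z = patch[sel]
    if z.max() <= 0:
        raise ValueError("featureless crop: autocorrelation peak indistinguishable from noise")

    def peak_model(rv, height, s2, base):
        return height * np.exp(-(rv**2) / s2) + base

    try:
        (height, s2, _base), _ = optimize.curve_fit(
            peak_model, r, z, p0=(float(z.max()), 4.0, 0.0),
            bounds=([0, 0.2, -np.inf], [np.inf, (2 * half) ** 2, np.inf]),
            maxfev=2000,
        )
    except RuntimeError as exc:  # pragma: no cover
        raise ValueError("autocorrelation peak fit failed (featureless crop?)") from exc
    # a genuine particle peak must stand clear of the autocorrelation floor
    floor = np.std(patch[rr > 0.75 * half])
    if height < 5.0 * floor:
        raise ValueError("featureless crop: autocorrelation peak "
                         "indistinguishable from the noise floor")
    sigma_p = np.sqrt(s2 / 4.0)  # peak width σ√2 → particle σ

    # particle amplitude: median height of detected blob maxima, corrected for
    # sub-pixel sampling attenuation and for the subtracted mean blob coverage
    amp0 = _particle_amplitude(resid, sigma_p)
    if amp0 <= noise_guard:
        raise ValueError("featureless crop: no particle signal above the noise floor")
    area_px = frames.shape[1] * frames.shape[2]
    amp = amp0
    n_rbc = height / (amp**2 * np.pi * sigma_p**2)
    for _ in range(3):  # fixed point: coverage depends on the count itself
        coverage = n_rbc * amp * 2 * np.pi * sigma_p**2 / area_px
        amp = amp0 + coverage / _attenuation(sigma_p)
        n_rbc = height / (amp**2 * np.pi * sigma_p**2)
    return float(n_rbc)


def _attenuation(sigma_p: float) -> float:
    """Expected peak attenuation for a pixel-sampled Gaussian blob."""
    from scipy.special import erf

    att_1d = sigma_p * np.sqrt(2 * np.pi) * erf(0.5 / (sigma_p * np.sqrt(2)))
    return float(att_1d**2)


def _particle_amplitude(resid: np.ndarray, sigma_p: float) -> float:
    """Median local-maximum height of background-subtracted frames.

    The median over detected blob peaks is robust against occasional blob
    overlap; the expected attenuation of a Gaussian peak sampled at a pixel
    center offset uniform in [-½, ½)² is divided out.
    """
    amps = []
    step = max(1, resid.shape[0] // 10)
    for f in resid[::step]:
        mx = ndimage.maximum_filter(f, size=5)
        peaks = (f == mx) & (f > 0.3 * f.max())
        if peaks.any():
            amps.append(np.median(f[peaks]))
    if not amps:
        return 0.0
    return float(np.median(amps) / _attenuation(sigma_p))


def hematocrit(
    n_rbc: float,
    rbc_volume_um3: float,
    crop_area_um2: float,
    depth_of_focus_um: float,
) -> float:
    """Hematocrit (% by volume): 100 · V_rbc · N_rbc / (crop area × depth of focus)."""
    if rbc_volume_um3 <= 0 or crop_area_um2 <= 0 or depth_of_focus_um <= 0:
        raise ValueError("volumes must be positive")
    if n_rbc < 0:
        raise ValueError("pattern count cannot be negative")
    ht = 100.0 * rbc_volume_um3 * n_rbc / (crop_area_um2 * depth_of_focus_um)
    if ht > 100.0:
        warnings.warn(f"hematocrit {ht:.1f}% exceeds 100%; check V_rbc / depth of focus",
                      stacklevel=2)
    return ht


def walburn_schneck_viscosity(
    ht_pct: float,
    gamma_s: float,
    model: RheologyModel = RheologyModel(),
) -> float:
    """Dynamic viscosity (Pa·s) from the Walburn–Schneck correlation.

    ``ht_pct`` is hematocrit in percent; ``gamma_s`` is the peak shear rate
    over the cycle in 1/s.  TPMA is converted from mg/mL to g/L so that the
    C4·TPMA/Ht² exponent is dimensionless; the poise-valued result is
    converted to Pa·s through :data:`PA_S_PER_POISE`.
    """
    if ht_pct <= 0:
        raise ValueError("the correlation is singular at Ht = 0; Ht must be positive")
    if gamma_s <= 0:
        raise ValueError("shear rate must be positive")
    tpma_g_l = model.tpma_mg_ml  # mg/mL == g/L numerically
    mu_poise = (
        model.c1
        * np.exp(model.c2 * ht_pct)
        * np.exp(model.c4_l_per_g * tpma_g_l / ht_pct**2)
        * gamma_s ** (-model.c3 * ht_pct)
    )
    return float(mu_poise * PA_S_PER_POISE)
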