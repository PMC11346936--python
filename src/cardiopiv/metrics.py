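"""Whole-heart functional metrics.

Heart rate comes from the Fourier transform of an instantaneous velocity
waveform; Reynolds and Womersley numbers from the atrial inlet diameter,
blood density and the shear-dependent viscosity; ejection fraction from a
cylindrical ventricle volume model Vol = (π/4)·L·D1·D2 with D2 = D1 (depth
unresolved in a planar measurement).

Endocardial Work (EW) is the area under the ΔP_AVC–strain curve over the
diastolic (ventricle-filling) window, evaluated with the trapezoidal rule.
Because ΔP across the atrioventricular canal is defined only while the canal
is open, the curve is an open path, not a closed loop; EW carries the unit
Pa-% (pressure × percent strain).  EW separates the developmental stages of
the embryonic heart: linear heart tube below 100 Pa-%, looped chambers below
300 Pa-%, fully formed chambers above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .rheology import FluidProperties

__all__ = [
    "HeartGeometry",
    "PressureStrainLoop",
    "CardiacSummary",
    "heart_rate",
    "reynolds_womersley",
    "ejection_fraction",
    "endocardial_work",
    "classify_stage",
    "pairs_per_cycle",
]

#: EW stage cuts (Pa-%); boundary values map to the higher stage
STAGE_LINEAR_MAX = 100.0
STAGE_LOOPED_MAX = 300.0


@dataclass
class HeartGeometry:
    """Ventricle geometry under the cylinder model (lengths in μm).

    ``area_um2`` follows the reported convention A = π·L·D1; the volume is
    Vol = (π/4)·L·D1·D2 with D2 = D1 when the depth is unobserved.
    """

    length_um: float
    d1_um: float
    d2_um: float | None = None
    inlet_diameter_um: float | None = None

    def __post_init__(self) -> None:
        if self.d2_um is None:
            self.d2_um = self.d1_um
        if self.length_um <= 0 or self.d1_um <= 0 or self.d2_um <= 0:
            raise ValueError("geometry lengths must be positive")

    @property
    def area_um2(self) -> float:
        return np.pi * self.length_um * self.d1_um

    @property
    def volume_um3(self) -> float:
        return (np.pi / 4.0) * self.length_um * self.d1_um * self.d2_um


@dataclass
class PressureStrainLoop:
    """Time-ordered (strain %, ΔP Pa) samples over the diastolic window."""

    strain_pct: np.ndarray
    dp_pa: np.ndarray
    times_s: np.ndarray | None = None
    open_loop: bool = True

    def __post_init__(self) -> None:
        self.strain_pct = np.asarray(self.strain_pct, dtype=float)
        self.dp_pa = np.asarray(self.dp_pa, dtype=float)
        if self.strain_pct.shape != self.dp_pa.shape:
            raise ValueError("strain and ΔP series must share a shape")


@dataclass
class CardiacSummary:
    """One row of whole-heart metrics."""

    hr_bpm: float
    re: float
    wo: float
    ef_pct: float
    ew_pa_pct: float
    stage: str
    area_um2: float = np.nan
    peak_dp_avc_pa: float = np.nan
    peak_dp_oft_pa: float = np.nan
    peak_strain_pct: float = np.nan
    extras: dict = dc_field(default_factory=dict)


def pairs_per_cycle(duration_s: float, frame_rate_hz: float, n_cycles: int) -> int:
    """Consecutive image pairs available per cycle for phase averaging."""
    frames_per_cycle = int(round(duration_s * frame_rate_hz / n_cycles))
    return frames_per_cycle - 1


def heart_rate(
    series: np.ndarray,
    sample_rate_hz: float,
    band_bpm: tuple[float, float] | None = None,
) -> tuple[float, float, float]:
    """Heart rate from the Fourier transform of a velocity waveform.

    Returns ``(hr_bpm, period_frames, spectral_resolution_bpm)``.  The
    dominant nonzero spectral frequency sets HR; the period in frames feeds
    the phase binning of the ensemble correlation.  ``band_bpm`` optionally
    restricts the search to a physiological band.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 4:
        raise ValueError("waveform too short for a spectral estimate")
    detr = series - series.mean()
    if np.allclose(detr, 0):
        raise ValueError("flat waveform: no spectral peak above the noise floor")
    spec = np.abs(np.fft.rfft(detr * np.hanning(series.size)))
    freqs = np.fft.rfftfreq(series.size, d=1.0 / sample_rate_hz)
    spec[0] = 0.0
    if band_bpm is not None:
        lo, hi = band_bpm
        spec[(freqs < lo / 60.0) | (freqs > hi / 60.0)] = 0.0
    k = int(np.argmax(spec))
    if spec[k] <= 0:
        raise ValueError("flat waveform: no spectral peak above the noise floor")
    # parabolic interpolation of the log-magnitude peak
    f0 = freqs[k]
    if 1 <= k < spec.size - 1 and spec[k - 1] > 0 and spec[k + 1] > 0:
        lm, l0, lp = np.log(spec[k - 1]), np.log(spec[k]), np.log(spec[k + 1])
        den = lm - 2 * l0 + lp
        if den < 0:
            f0 = freqs[k] + 0.5 * (lm - lp) / den * (freqs[1] - freqs[0])
    hr_bpm = 60.0 * f0
    period_frames = sample_rate_hz / f0
    resolution_bpm = 60.0 * sample_rate_hz / series.size
    return float(hr_bpm), float(period_frames), float(resolution_bpm)


def reynolds_womersley(
    inlet_diameter_um: float,
    velocity_um_s: float,
    fluid: FluidProperties,
    hr_bpm: float,
) -> tuple[float, float]:
    """Re = ρVd/μ and Wo = d·√(ρω/μ) with ω = 2π·HR/60 (SI conversions internal)."""
    if inlet_diameter_um <= 0:
        raise ValueError("inlet diameter must be positive")
    if velocity_um_s < 0:
        raise ValueError("characteristic velocity cannot be negative")
    if hr_bpm <= 0:
        raise ValueError("heart rate must be positive")
    d_m = inlet_diameter_um * 1e-6
    v_m = velocity_um_s * 1e-6
    rho = fluid.density_kg_m3
    mu = fluid.viscosity_pa_s
    re = rho * v_m * d_m / mu
    omega = 2 * np.pi * hr_bpm / 60.0
    wo = d_m * np.sqrt(rho * omega / mu)
    return float(re), float(wo)


def ejection_fraction(diastole: HeartGeometry, systole: HeartGeometry) -> float:
    """EF (%) = 100 × (Vol_dias − Vol_sys)/Vol_dias under the cylinder model."""
    vd = diastole.volume_um3
    vs = systole.volume_um3
    if vd <= 0:
        raise ValueError("diastolic volume must be positive")
    if vs > vd:
        warnings.warn("systolic volume exceeds diastolic volume; EF is negative",
                      stacklevel=2)
    return float(100.0 * (vd - vs) / vd)


def endocardial_work(loop: PressureStrainLoop) -> float:
    """EW (Pa-%): trapezoidal integral of ΔP with respect to strain.

    Samples must be time-ordered; non-monotone strain is allowed (the path
    integral may reduce the net area).  The sign convention is positive for
    rising pressure-drop with rising strain during filling.
    """
    if loop.strain_pct.size < 2:
        raise ValueError("EW needs at least two (strain, ΔP) samples")
    ok = np.isfinite(loop.strain_pct) & np.isfinite(loop.dp_pa)
    s = loop.strain_pct[ok]
    p = loop.dp_pa[ok]
    if s.size < 2:
        raise ValueError("EW needs at least two finite samples")
    return float(np.trapezoid(p, s))


def classify_stage(ew_pa_pct: float) -> str:
    """Developmental stage from EW: linear < 100 ≤ looped < 300 ≤ formed (Pa-%)."""
    if not np.isfinite(ew_pa_pct):
        raise ValueError("EW must be finite")
    if ew_pa_pct < 0:
        warnings.warn("negative EW cannot be classified", stacklevel=2)
        return "unclassified"
    if ew_pa_pct < STAGE_LINEAR_MAX:
        return "linear"
    if ew_pa_pct < STAGE_LOOPED_MAX:
        return "looped"
    return "formed"
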