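"""Core data containers shared across the pipeline.

Coordinate convention (used everywhere in the package): images are row-major
with the origin at the top-left corner; ``x`` increases rightward along
columns, ``y`` increases downward along rows; pixel indices are 0-based.
Vector-grid nodes sit at interrogation-window centers.  Velocities are stored
in μm/s, lengths in μm, time in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["ImageStack", "PhaseVelocityField", "GradientField"]


@dataclass
class ImageStack:
    """Time-ordered grayscale frames plus acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, ny, nx)
        Intensity frames (any float/integer dtype).
    pixel_size_um : float
        Effective pixel size in μm/px (0.16 for the 60x preset, 0.25 for 40x).
    frame_rate_hz : float
        Acquisition rate in frames per second.
    magnification : str, optional
        Objective tag, e.g. ``"40x"`` or ``"60x"``.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_rate_hz: float
    magnification: Optional[str] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, ny, nx) array")
        if self.frames.shape[0] < 2:
            raise ValueError("an image stack needs at least 2 frames")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]

    @property
    def dt_s(self) -> float:
        return 1.0 / self.frame_rate_hz


@dataclass
class PhaseVelocityField:
    """Phase-resolved 2D velocity field on a regular grid.

    ``u``/``v`` are the x/y velocity components in μm/s with shape
    (n_phases, ny, nx).  ``x``/``y`` hold the node coordinates in μm.
    ``mask`` marks nodes carrying a valid measurement; invalid nodes hold
    finite placeholder values (never NaN) so that downstream array math stays
    well-defined.
    """

    u: np.ndarray
    v: np.ndarray
    x: np.ndarray
    y: np.ndarray
    times: np.ndarray
    mask: Optional[np.ndarray] = None
    pixel_size_um: Optional[float] = None
    n_cycles: int = 1
    replaced: Optional[np.ndarray] = None  # outlier-replaced vectors (validation)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.ndim == 2:
            self.u = self.u[None]
            self.v = self.v[None]
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        if self.mask is None:
            self.mask = np.ones(self.u.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.ndim == 2:
                self.mask = np.broadcast_to(self.mask[None], self.u.shape).copy()
        if self.u.shape != self.v.shape or self.u.shape != self.mask.shape:
            raise ValueError("u, v and mask must share one shape")
        if self.u.shape[1:] != (self.y.size, self.x.size):
            raise ValueError("grid coordinates inconsistent with field shape")
        if not (np.isfinite(self.u[self.mask]).all() and np.isfinite(self.v[self.mask]).all()):
            raise ValueError("velocities must be finite where mask is true")

    @property
    def n_phases(self) -> int:
        return self.u.shape[0]

    @property
    def dx_um(self) -> float:
        return float(self.x[1] - self.x[0]) if self.x.size > 1 else 1.0

    @property
    def dy_um(self) -> float:
        return float(self.y[1] - self.y[0]) if self.y.size > 1 else 1.0

    @property
    def dt_s(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 1.0

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def copy(self) -> "PhaseVelocityField":
        return replace(
            self,
            u=self.u.copy(),
            v=self.v.copy(),
            mask=self.mask.copy(),
            replaced=None if self.replaced is None else self.replaced.copy(),
        )


@dataclass
class GradientField:
    """Velocity-gradient tensor components on the source grid (units 1/s)."""

    du_dx: np.ndarray
    du_dy: np.ndarray
    dv_dx: np.ndarray
    dv_dy: np.ndarray
    x: np.ndarray = field(default=None)  # type: ignore[assignment]
    y: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def magnitude(self) -> np.ndarray:
        """Frobenius norm of the gradient tensor per node."""
        return np.sqrt(
            self.du_dx**2 + self.du_dy**2 + self.dv_dx**2 + self.dv_dy**2
        )
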