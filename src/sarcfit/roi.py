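"""ROI extraction, orientation correction, sensitivity maps and time traces.

Coordinate convention: pixel centres at integer coordinates, row-major,
0-based.  A :class:`Roi` is a rectangle of ``height`` image lines of
``width`` samples each, centred at real-valued ``(row, col)`` and rotated by
``angle_deg`` about its centre; the unit vector along a ROI line is
``(sin a, cos a)`` in (row, col), so ``angle_deg = 0`` aligns ROI lines with
image rows and positive angles tilt them toward increasing row index.

Striations form a quasi-periodic lattice of lines; cutting a P-periodic
lattice at angle ``a`` yields an apparent period ``P / cos(a - a0)`` where
``a0`` is the lattice orientation.  :func:`orientation_scan` fits that model
over a sweep of ROI angles (linearised on reciprocals, which is exact) to
recover ``a0`` and the corrected period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .similarity import estimate_period

__all__ = [
    "Roi",
    "RoiBoundsError",
    "OrientationFitError",
    "OrientationScanResult",
    "SarcomereTrace",
    "extract_roi",
    "orientation_scan",
    "sensitivity_map",
    "trace_timeseries",
    "rate_3pt",
    "px_to_um",
]

#: pixel size of the reference transmission-microscopy setup (um / px)
DEFAULT_PIXEL_SIZE_UM = 0.411
#: frame interval of the reference 200 Hz acquisition (s)
DEFAULT_FRAME_INTERVAL_S = 0.005


class RoiBoundsError(ValueError):
    """The (rotated) ROI footprint extends outside the source image."""


class OrientationFitError(RuntimeError):
    """Too few valid angle samples to fit the orientation model."""


@dataclass
class Roi:
    """A possibly rotated rectangular region of interest."""

    center: tuple[float, float]       # (row, col), pixel coordinates
    height: int                       # number of lines
    width: int                        # samples per line
    angle_deg: float = 0.0            # rotation about the centre

    def __post_init__(self):
        if self.width < 4:
            raise ValueError(f"ROI width must be >= 4, got {self.width}")
        if self.height < 1:
            raise ValueError(f"ROI height must be >= 1, got {self.height}")

    def with_angle(self, angle_deg: float) -> "Roi":
        return Roi(self.center, self.height, self.width, angle_deg)

    def footprint_margins(self) -> tuple[float, float]:
        """Max |row| / |col| offset of any sample from the centre."""
        a = math.radians(self.angle_deg)
        hr = (self.height - 1) / 2.0
        hc = (self.width - 1) / 2.0
        dr = abs(hc * math.sin(a)) + abs(hr * math.cos(a))
        dc = abs(hc * math.cos(a)) + abs(hr * math.sin(a))
        return dr, dc


def extract_roi(image, roi: Roi) -> np.ndarray:
    """Resample a rotated ROI onto its own grid by bilinear interpolation.

    Returns a ``(height, width)`` array whose rows are the ROI lines.  With
    ``angle_deg = 0`` and integral coordinates this is an exact sub-block
    copy.  Raises :class:`RoiBoundsError` if any sample falls outside the
    image.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    a = math.radians(roi.angle_deg)
    dr = np.arange(roi.height, dtype=float) - (roi.height - 1) / 2.0
    dc = np.arange(roi.width, dtype=float) - (roi.width - 1) / 2.0
    DR, DC = np.meshgrid(dr, dc, indexing="ij")
    rows = roi.center[0] + DC * math.sin(a) + DR * math.cos(a)
    cols = roi.center[1] + DC * math.cos(a) - DR * math.sin(a)
    tol = 1e-9
    if (rows.min() < -tol or cols.min() < -tol
            or rows.max() > img.shape[0] - 1 + tol
            or cols.max() > img.shape[1] - 1 + tol):
        raise RoiBoundsError(
            f"ROI footprint rows [{rows.min():.2f}, {rows.max():.2f}], "
            f"cols [{cols.min():.2f}, {cols.max():.2f}] exceeds image "
            f"shape {img.shape}"
        )
    return map_coordinates(img, [rows.clip(0, img.shape[0] - 1),
                                 cols.clip(0, img.shape[1] - 1)], order=1)


@dataclass
class OrientationScanResult:
    """Angle sweep of period estimates plus the fitted lattice orientation."""

    angles_deg: np.ndarray
    period_px: np.ndarray             # NaN where the estimate was invalid
    valid: np.ndarray
    alpha0_deg: float                 # fitted lattice orientation
    corrected_period_px: float        # model amplitude 1/sqrt(a^2+b^2)
    period_at_zero_corrected_px: float   # SL(angle nearest 0) * cos(alpha0)

    @property
    def correction_factor(self) -> float:
        return math.cos(math.radians(self.alpha0_deg))


def orientation_scan(image, roi: Roi, angles_deg, recenter: int = 0,
                     **estimator_options) -> OrientationScanResult:
    """Estimate the period over a sweep of ROI angles and fit P/cos(a - a0).

    The fit is linear least squares on reciprocals,
    ``1/SL_j = a cos(angle_j) + b sin(angle_j)``, which is exactly
    equivalent to the cosine model; ``alpha0 = atan2(b, a)`` and the
    corrected period is ``1 / sqrt(a^2 + b^2)``.  Invalid angles are
    excluded; at least 3 valid samples spanning >= 4 degrees are required.

    With ``recenter = n`` the scan is repeated ``n`` times with the angle
    grid shifted to be symmetric about the previously fitted ``alpha0``.
    The subpixel interpolation bias of the estimator varies smoothly with
    the apparent period; over an angle window that is asymmetric about the
    lattice orientation its odd component tilts the reciprocal fit, and a
    symmetric window cancels it.
    """
    base = np.asarray(angles_deg, dtype=float)
    result = _orientation_scan_once(image, roi, base, estimator_options)
    for _ in range(recenter):
        shifted = result.alpha0_deg + (base - base.mean())
        result = _orientation_scan_once(image, roi, shifted, estimator_options)
    return result


def _orientation_scan_once(image, roi, angles, estimator_options
                           ) -> OrientationScanResult:
    periods = np.full(angles.size, np.nan)
    for i, ang in enumerate(angles):
        est = estimate_period(extract_roi(image, roi.with_angle(ang)),
                              **estimator_options)
        if est.valid:
            periods[i] = est.period_px
    valid = np.isfinite(periods)
    if valid.sum() < 3 or np.ptp(angles[valid]) < 4.0:
        raise OrientationFitError(
            f"orientation fit needs >= 3 valid angles spanning >= 4 deg, "
            f"got {int(valid.sum())} over {np.ptp(angles[valid]) if valid.any() else 0:.2f} deg"
        )
    rad = np.radians(angles[valid])
    A = np.column_stack([np.cos(rad), np.sin(rad)])
    coef, *_ = np.linalg.lstsq(A, 1.0 / periods[valid], rcond=None)
    a, b = coef
    alpha0 = math.degrees(math.atan2(b, a))
    corrected = 1.0 / math.hypot(a, b)
    i0 = int(np.argmin(np.abs(angles[valid])))
    sl0 = periods[valid][i0] * math.cos(math.radians(alpha0))
    return OrientationScanResult(angles, periods, valid, alpha0, corrected,
                                 float(sl0))


def sensitivity_map(image, roi_height: int, roi_width: int, stride: int = 1,
                    angle_deg: float = 0.0, pixel_size_um: float | None = None,
                    **estimator_options) -> tuple[np.ndarray, np.ndarray]:
    """Period estimate as a function of ROI centre position.

    Evaluates the estimator on a ROI of fixed size centred at every
    ``stride``-th pixel where the footprint fits.  Returns an image-shaped
    map (NaN where not evaluated or invalid) and a boolean validity mask.
    Values are in px, or in um when ``pixel_size_um`` is given.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    probe = Roi((0.0, 0.0), roi_height, roi_width, angle_deg)
    mr, mc = probe.footprint_margins()
    r_lo, r_hi = int(math.ceil(mr)), int(math.floor(img.shape[0] - 1 - mr))
    c_lo, c_hi = int(math.ceil(mc)), int(math.floor(img.shape[1] - 1 - mc))
    if r_hi < r_lo or c_hi < c_lo:
        raise ValueError(
            f"ROI {roi_height}x{roi_width} at {angle_deg} deg does not fit "
            f"inside image of shape {img.shape}"
        )
    sl_map = np.full(img.shape, np.nan)
    for r in range(r_lo, r_hi + 1, stride):
        for c in range(c_lo, c_hi + 1, stride):
            patch = extract_roi(img, Roi((float(r), float(c)), roi_height,
                                         roi_width, angle_deg))
            est = estimate_period(patch, **estimator_options)
            if est.valid:
                sl = est.period_px
                if pixel_size_um is not None:
                    sl = px_to_um(sl, pixel_size_um)
                sl_map[r, c] = sl
    return sl_map, np.isfinite(sl_map)


@dataclass
class SarcomereTrace:
    """Per-frame mean sarcomere length and shortening rate."""

    times_s: np.ndarray
    sl_px: np.ndarray                 # NaN where invalid
    sl_um: np.ndarray
    rate_um_s: np.ndarray
    valid: np.ndarray
    contrast: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    method: str = "finite"

    def __len__(self) -> int:
        return self.times_s.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time_s": self.times_s,
            "sl_px": self.sl_px,
            "sl_um": self.sl_um,
            "rate_um_s": self.rate_um_s,
            "valid": self.valid,
            "contrast": self.contrast,
        })


def trace_timeseries(stack, roi: Roi, method: str = "finite",
                     pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                     frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
                     **estimator_options) -> SarcomereTrace:
    """Track the mean sarcomere length through an image stack on a fixed ROI.

    Each frame is estimated independently (the ROI does not move); invalid
    frames are reported as NaN, never interpolated.  The shortening rate is
    the 3-point finite difference of the um-converted trace.
    """
    frames = np.asarray(stack, dtype=float)
    if frames.ndim != 3:
        raise ValueError(f"expected a (frames, H, W) stack, got {frames.shape}")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be positive")
    n = frames.shape[0]
    sl_px = np.full(n, np.nan)
    contrast = np.zeros(n)
    for i in range(n):
        est = estimate_period(extract_roi(frames[i], roi), method=method,
                              **estimator_options)
        if est.valid:
            sl_px[i] = est.period_px
            contrast[i] = est.contrast
    valid = np.isfinite(sl_px)
    sl_um = sl_px * pixel_size_um
    rate = rate_3pt(sl_um, frame_interval_s)
    times = np.arange(n) * frame_interval_s
    return SarcomereTrace(times, sl_px, sl_um, rate, valid, contrast,
                          pixel_size_um, frame_interval_s, method)


def rate_3pt(sl, dt: float) -> np.ndarray:
    """3-point finite-difference rate of a sampled sequence.

    Interior points use the central difference ``(sl[j+1] - sl[j-1])/(2 dt)``
    (exact for quadratics); the endpoints use one-sided two-point
    differences so the output has the input length.  A NaN (invalid) sample
    invalidates its own rate and every rate that uses it; invalid frames
    are never interpolated over.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    y = np.asarray(sl, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    r = np.empty_like(y)
    r[1:-1] = (y[2:] - y[:-2]) / (2.0 * dt)
    r[0] = (y[1] - y[0]) / dt
    r[-1] = (y[-1] - y[-2]) / dt
    r[~np.isfinite(y)] = np.nan
    return r


def px_to_um(period_px: float, pixel_size_um: float) -> float:
    """Convert a period in pixels to micrometres."""
    if period_px < 0 or pixel_size_um < 0:
        raise ValueError("period and pixel size must be non-negative")
    return period_px * pixel_size_um
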