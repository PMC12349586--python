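"""Phase extraction, ROI time series, calibration and resolution metrics.

The quad-channel estimator

    cos(delta_phi) = (I0 - I90) / (2 sqrt(I45 I135))

is exact on noise-free forward data and cancels any common multiplicative
factor on the four channels (laser-power fluctuation).  Phase maps are the
principal-branch arccos, so values live in [0, pi]; the instrument's
operating range keeps the true phase difference on a single monotone branch
and no unwrapping is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import PolFrame, PolVideo

__all__ = [
    "PhaseImage",
    "PhaseSeries",
    "CalibrationFit",
    "cos_delta_phi",
    "phase_image",
    "roi_series",
    "fit_sensitivity",
    "resolution",
    "smoothing_filter",
    "plateau_windows",
]


@dataclass
class PhaseImage:
    """Per-pixel phase-difference map in radians, range [0, pi].

    ``clamp_mask`` marks pixels where |cos| exceeded 1 before clamping
    (inevitable near the branch ends under noise); ``invalid_mask`` marks
    zero-denominator pixels, which carry NaN in ``values``.
    """

    values: np.ndarray
    clamp_mask: np.ndarray
    invalid_mask: np.ndarray

    @property
    def clamp_fraction(self) -> float:
        return float(np.mean(self.clamp_mask))


@dataclass
class PhaseSeries:
    """Mean-ROI phase versus time.  ``roi`` is (r0, c0, r1, c1), 0-based half-open."""

    t: np.ndarray
    phi: np.ndarray
    roi: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.t.shape != self.phi.shape:
            raise ValueError("t and phi must have the same shape")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    def sd(self) -> float:
        """Temporal standard deviation of the phase (sample SD)."""
        return float(np.std(self.phi, ddof=1))


@dataclass
class CalibrationFit:
    """Linear phase-vs-refractive-index calibration."""

    sensitivity: float  # rad / RIU
    intercept: float  # rad
    r_squared: float


def cos_delta_phi(frame: PolFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (cos map clamped to [-1, 1], clamp mask, invalid mask)."""
    i0, i45, i90, i135 = frame.data
    prod = i45 * i135
    invalid = prod <= 0
    denom = 2.0 * np.sqrt(np.where(invalid, 1.0, prod))
    raw = (i0 - i90) / denom
    clamp = (np.abs(raw) > 1.0) & ~invalid
    cos = np.clip(raw, -1.0, 1.0)
    cos = np.where(invalid, np.nan, cos)
    return cos, clamp, invalid


def phase_image(frame: PolFrame) -> PhaseImage:
    """Principal-branch phase map arccos(cos_delta_phi) in [0, pi]."""
    cos, clamp, invalid = cos_delta_phi(frame)
    with np.errstate(invalid="ignore"):
        values = np.arccos(cos)
    return PhaseImage(values=values, clamp_mask=clamp, invalid_mask=invalid)


def _check_roi(roi, shape):
    r0, c0, r1, c1 = roi
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise ValueError(f"roi {roi} empty or out of bounds for shape {shape}")
    return r0, c0, r1, c1


def roi_series(video: PolVideo, roi: tuple[int, int, int, int]) -> PhaseSeries:
    """Mean-ROI phase per frame: per-pixel phase first, then spatial mean.

    Averaging phase (not intensity) matches the phase-image-then-curve
    workflow; invalid pixels are excluded from the mean.
    """
    r0, c0, r1, c1 = _check_roi(roi, video.shape)
    phi = np.empty(video.n_frames)
    for i in range(video.n_frames):
        img = phase_image(video.frame(i))
        phi[i] = np.nanmean(img.values[r0:r1, c0:c1])
    return PhaseSeries(t=video.t, phi=phi, roi=(r0, c0, r1, c1))


def roi_series_intensity_first(video: PolVideo, roi: tuple[int, int, int, int]) -> PhaseSeries:
    """Alternative ROI statistic: average the four intensities over the ROI
    first, then extract a single phase per frame.  Provided for comparison."""
    r0, c0, r1, c1 = _check_roi(roi, video.shape)
    means = video.data[:, :, r0:r1, c0:c1].mean(axis=(2, 3))  # (T, 4)
    phi = np.empty(video.n_frames)
    for i in range(video.n_frames):
        img = phase_image(PolFrame(means[i].reshape(4, 1, 1)))
        phi[i] = img.values[0, 0]
    return PhaseSeries(t=video.t, phi=phi, roi=(r0, c0, r1, c1))


def fit_sensitivity(phases, ris) -> CalibrationFit:
    """Ordinary least squares of plateau phase (rad) against refractive index.

    ``phases`` and ``ris`` are matched per-plateau values; at least two
    distinct refractive indices are required, and a two-point fit warns that
    R^2 = 1 by construction.
    """
    phases = np.asarray(phases, dtype=float)
    ris = np.asarray(ris, dtype=float)
    if phases.shape != ris.shape or phases.ndim != 1:
        raise ValueError("phases and ris must be matched 1-D arrays")
    if np.ptp(ris) == 0 or ris.size < 2:
        raise ValueError("need at least two distinct refractive indices")
    if ris.size == 2:
        warnings.warn("two-point calibration: R^2 = 1 by construction", stacklevel=2)
    res = stats.linregress(ris, phases)
    return CalibrationFit(
        sensitivity=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def resolution(sd_phase: float, fit: CalibrationFit | float) -> float:
    """Refractive-index resolution: 3 sigma of the phase noise over the
    sensitivity, in RIU.  ``fit`` may be a CalibrationFit or a bare
    sensitivity in rad/RIU."""
    s = fit.sensitivity if isinstance(fit, CalibrationFit) else float(fit)
    if s <= 0:
        raise ValueError("sensitivity must be positive")
    if sd_phase < 0:
        raise ValueError("sd_phase must be >= 0")
    return 3.0 * sd_phase / s


def smoothing_filter(series: PhaseSeries, window: int) -> PhaseSeries:
    """Centered moving average with truncated windows at the edges."""
    if window < 1:
        raise ValueError("window must be >= 1")
    n = series.phi.size
    if window > n:
        raise ValueError(f"window {window} longer than series ({n} samples)")
    if window == 1:
        return PhaseSeries(t=series.t.copy(), phi=series.phi.copy(), roi=series.roi)
    half_lo = (window - 1) // 2
    half_hi = window // 2
    csum = np.concatenate(([0.0], np.cumsum(series.phi)))
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, n)
    phi = (csum[hi] - csum[lo]) / (hi - lo)
    return PhaseSeries(t=series.t.copy(), phi=phi, roi=series.roi)


def plateau_windows(segments, frame_rate: float, frac: float = 0.6):
    """Frame-index windows covering the central ``frac`` of each protocol
    segment (transitions excluded).  ``segments`` is a list of
    (duration_s, value); returns [(i0, i1, value), ...] half-open."""
    if not (0 < frac <= 1):
        raise ValueError("frac must be in (0, 1]")
    out = []
    t0 = 0.0
    for duration, value in segments:
        margin = duration * (1 - frac) / 2
        i0 = int(np.ceil((t0 + margin) * frame_rate))
        i1 = int(np.floor((t0 + duration - margin) * frame_rate)) + 1
        out.append((i0, max(i1, i0 + 1), value))
        t0 += duration
    return out
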