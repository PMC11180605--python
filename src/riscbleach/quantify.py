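"""Image-analysis pipeline for reduced-photobleaching quantification.

Extracts per-ROI photobleaching kinetics from time-lapse stacks
(background subtraction, normalization to the first frame), forms RP
ratios as areas under paired with/without-NIR decay curves, and performs
ratiometric (green/red) temperature calibration and mapping.

Conventions: pixel coordinates are 0-based (row, column); the time axis
comes first; multi-plane stacks are ordered TZYX.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .photophysics import BleachingTrace, RPResult

__all__ = [
    "ImageStack",
    "ROISet",
    "TemperatureCalibration",
    "extract_traces",
    "select_rois_by_initial_intensity",
    "compute_rp_from_traces",
    "fit_temperature_calibration",
    "temperature_map",
]

log = logging.getLogger(__name__)


@dataclass
class ImageStack:
    """Time-lapse (optionally multi-plane) pixel data with geometry.

    Attributes
    ----------
    pixels : ndarray
        Non-negative counts, axes T,Y,X or T,Z,Y,X.
    frame_interval : float
        Seconds between frames (constant).
    pixel_size : float
        Micrometres per pixel.
    z_step : float or None
        Micrometres between focal planes, for TZYX stacks.
    vis_disc, nir_disc : (row, col, diameter_px) or None
        Centre and diameter of the visible / NIR illumination discs in
        pixel coordinates; None means uniform (vis) or absent (NIR).
    """

    pixels: np.ndarray
    frame_interval: float
    pixel_size: float = 1.0
    z_step: float | None = None
    vis_disc: tuple[float, float, float] | None = None
    nir_disc: tuple[float, float, float] | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim not in (3, 4):
            raise ValueError("pixels must be TYX or TZYX")
        if px.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if np.any(px < 0):
            raise ValueError("pixel counts must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        self.pixels = px

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[-2:]


@dataclass
class ROISet:
    """Integer label image; label 0 marks background-candidate pixels."""

    labels: np.ndarray

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be a 2-d image")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be integer")
        if lab.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = lab

    @property
    def roi_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


def _background(frames: np.ndarray, rois: ROISet, mode: str, value: float) -> np.ndarray:
    """Per-frame scalar background estimate for a TYX array."""
    if mode == "label0_median":
        mask = rois.labels == 0
        if not mask.any():
            raise ValueError("no background (label 0) pixels for label0_median mode")
        return np.median(frames[:, mask], axis=1)
    if mode == "darkest_quantile":
        flat = frames.reshape(frames.shape[0], -1)
        q = np.quantile(flat, 0.01, axis=1)
        # mean of the darkest 1% of pixels in each frame
        return np.array([f[f <= qi].mean() for f, qi in zip(flat, q)])
    if mode == "fixed":
        return np.full(frames.shape[0], float(value))
    if mode == "none":
        return np.zeros(frames.shape[0])
    raise ValueError(f"unknown background mode {mode!r}")


def extract_traces(
    stack: ImageStack,
    rois: ROISet,
    background_mode: str = "label0_median",
    background_value: float = 0.0,
    t0_average_frames: int = 1,
) -> list[BleachingTrace]:
    """Per-ROI background-subtracted traces normalized to 1 at t = 0.

    For each ROI label the mean pixel value per frame is computed, the
    per-frame background estimate subtracted, and the result divided by
    its first-frame value (or the mean of the first
    ``t0_average_frames`` frames).  ROIs whose t = 0 value is <= 0 after
    background subtraction are excluded and logged.
    """
    px = stack.pixels
    if px.ndim == 4:
        raise ValueError("extract_traces expects a single-plane TYX stack; "
                         "select a z plane first")
    if rois.labels.shape != stack.frame_shape:
        raise ValueError("ROI label image shape does not match stack frames")
    ids = rois.roi_ids
    if ids.size == 0:
        raise ValueError("ROI set contains no labels > 0")
    bg = _background(px, rois, background_mode, background_value)
    times = stack.times
    traces: list[BleachingTrace] = []
    for roi in ids:
        mask = rois.labels == roi
        mean = px[:, mask].mean(axis=1) - bg
        ref = mean[: max(1, t0_average_frames)].mean()
        if ref <= 0:
            log.warning("ROI %d excluded: non-positive t=0 signal (%.3g)", roi, ref)
            continue
        traces.append(BleachingTrace(times=times, signal=np.clip(mean, 0, None) / ref,
                                     roi_id=int(roi)))
    return traces


def select_rois_by_initial_intensity(
    stack: ImageStack,
    rois: ROISet,
    tolerance: float = 0.1,
    background_mode: str = "label0_median",
    background_value: float = 0.0,
) -> list[int]:
    """ROI labels whose t=0 background-subtracted mean lies within
    ``tolerance`` (relative) of the median initial intensity across ROIs.

    Optional matching filter for experiments where compared ROIs should
    start at the same brightness.
    """
    px = stack.pixels
    bg = _background(px, rois, background_mode, background_value)[0]
    ids = rois.roi_ids
    t0 = np.array([px[0, rois.labels == roi].mean() - bg for roi in ids])
    ref = np.median(t0)
    keep = np.abs(t0 - ref) <= tolerance * abs(ref)
    return [int(r) for r in ids[keep]]


def compute_rp_from_traces(
    trace_with: BleachingTrace,
    trace_without: BleachingTrace,
    window: float | None = None,
) -> RPResult:
    """RP as the ratio of areas under paired photobleaching curves.

    Traces are resampled (linear interpolation) onto the overlap of
    their time ranges when the grids differ; areas are trapezoidal over
    the common window (default: the full common acquisition span).
    """
    t_lo = max(trace_with.times[0], trace_without.times[0])
    t_hi = min(trace_with.times[-1], trace_without.times[-1])
    if window is not None:
        t_hi = min(t_hi, t_lo + window)
    if t_hi <= t_lo:
        raise ValueError("traces have no overlapping time range")
    if trace_with.times.shape == trace_without.times.shape and np.allclose(
        trace_with.times, trace_without.times
    ):
        t = trace_with.times
        sel = (t >= t_lo) & (t <= t_hi)
        t = t[sel]
        s_w = trace_with.signal[sel]
        s_o = trace_without.signal[sel]
    else:
        n = max(len(trace_with), len(trace_without))
        t = np.linspace(t_lo, t_hi, n)
        s_w = np.interp(t, trace_with.times, trace_with.signal)
        s_o = np.interp(t, trace_without.times, trace_without.signal)
    auc_w = float(np.trapezoid(s_w, t))
    auc_o = float(np.trapezoid(s_o, t))
    if auc_o <= 0:
        raise ValueError("reference (no-NIR) area is non-positive")
    return RPResult(rp=auc_w / auc_o, window=float(t_hi - t_lo),
                    auc_with=auc_w, auc_without=auc_o)


@dataclass(frozen=True)
class TemperatureCalibration:
    """Monotone linear map ratio = intercept + slope * T on [t_min, t_max] degC."""

    slope: float
    intercept: float
    t_min: float = 30.0
    t_max: float = 45.0
    residual: float = 0.0

    def __post_init__(self):
        if self.slope == 0:
            raise ValueError("calibration map must be strictly monotone (slope != 0)")
        if not self.t_min < self.t_max:
            raise ValueError("need t_min < t_max")

    def ratio(self, T):
        return self.intercept + self.slope * np.asarray(T, float)

    def temperature(self, ratio):
        return (np.asarray(ratio, float) - self.intercept) / self.slope

    @property
    def ratio_range(self) -> tuple[float, float]:
        r = sorted((float(self.ratio(self.t_min)), float(self.ratio(self.t_max))))
        return r[0], r[1]


def fit_temperature_calibration(
    temperatures_C,
    ratios,
    valid_range: tuple[float, float] = (30.0, 45.0),
) -> TemperatureCalibration:
    """Fit the linear green/red-ratio vs temperature calibration curve.

    Requires >= 3 points spanning >= 5 degC within the valid range, and a
    monotone trend beyond noise (|Spearman rho| >= 0.7); otherwise an
    error advises checking the temperature range.
    """
    T = np.asarray(temperatures_C, float)
    r = np.asarray(ratios, float)
    if T.shape != r.shape or T.ndim != 1:
        raise ValueError("temperatures and ratios must be matching 1-d arrays")
    if T.size < 3:
        raise ValueError("need at least 3 calibration points")
    if T.max() - T.min() < 5.0:
        raise ValueError("calibration points must span at least 5 degC")
    lo, hi = valid_range
    if T.min() < lo or T.max() > hi:
        raise ValueError(f"calibration temperatures must lie in [{lo}, {hi}] degC")
    rho = spearmanr(T, r).statistic
    if not np.isfinite(rho) or abs(rho) < 0.7:
        raise ValueError(
            "ratio is not monotone in temperature beyond noise; "
            "check the probe and temperature range"
        )
    slope, intercept = np.polyfit(T, r, 1)
    resid = float(np.sqrt(np.mean((intercept + slope * T - r) ** 2)))
    return TemperatureCalibration(
        slope=float(slope), intercept=float(intercept),
        t_min=float(lo), t_max=float(hi), residual=resid,
    )


def temperature_map(
    green: np.ndarray,
    red: np.ndarray,
    cal: TemperatureCalibration,
    baseline_T: float = 37.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pixelwise temperature elevation from a green/red image pair.

    Returns ``(delta_T, out_of_range)``: delta_T [degC] with NaN where
    red <= 0 (masked) or the ratio falls outside the calibration range
    (flagged, never silently extrapolated), and the boolean out-of-range
    mask.
    """
    g = np.asarray(green, float)
    r = np.asarray(red, float)
    if g.shape != r.shape:
        raise ValueError("green and red images must have the same shape")
    valid = r > 0
    ratio = np.full(g.shape, np.nan)
    np.divide(g, r, out=ratio, where=valid)
    r_lo, r_hi = cal.ratio_range
    out_of_range = valid & ((ratio < r_lo) | (ratio > r_hi))
    T = cal.temperature(ratio)
    delta = T - baseline_T
    delta[~valid | out_of_range] = np.nan
    if out_of_range.any():
        log.warning("%d pixels outside calibration range flagged as NaN",
                    int(out_of_range.sum()))
    return delta, out_of_range
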