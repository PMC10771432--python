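"""Contrast-harmonic recordings -> decay-constant perfusion maps.

Each pixel's time-intensity curve (TIC) is smoothed with a 32-sample moving
average, and the segment after the intensity peak is fit to a first-order
exponential washout ``y(t) = A·exp(−k·(t − t_peak))``.  The decay-constant
magnitude k (1/s) is the flow surrogate: the faster the microbubble signal
clears, the greater the perfusion.  Pixels that never receive contrast are
assigned 0 1/s — operationally, pixels whose smoothed TIC never reaches
0.015 AU or whose peak arrives at or after 75 s into the recording.  Maps
can finally be cleaned of microbubble-aggregate speckle with a grayscale
opening by a non-flat ("offset disk") structuring element.

The fit is log-linear least squares on the logarithm of the post-peak
segment (exact on a clean exponential), with an optional nonlinear
refinement.  Samples at or below a small relative floor are excluded (the
log is undefined at 0 and noise dominates there), as are samples within one
filter length of the peak and of the series end, where the moving average
mixes the rise and decay regimes or shrinks asymmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datatypes import FlowMap, FrameStack

__all__ = [
    "DecayFitResult",
    "smooth_tic",
    "fit_decay",
    "decay_map",
    "open_offset_disk",
    "offset_disk",
]

#: moving-average length (samples) used for TIC denoising
SMOOTHING_WINDOW = 32
#: minimum smoothed peak intensity (AU) for a pixel to count as perfused
MAX_INTENSITY_THRESHOLD = 0.015
#: latest admissible peak time (s); a later peak marks an unperfused pixel
LATEST_PEAK_TIME = 75.0


@dataclass
class DecayFitResult:
    """Outcome of one pixel's washout fit.

    ``fit_ok`` is False (and ``decay_constant`` 0) for unperfused pixels —
    sub-threshold peak, too-late peak, or too few usable post-peak samples.
    """

    decay_constant: float
    peak_time: float
    peak_value: float
    fit_ok: bool
    rss: float = np.nan

    def __post_init__(self) -> None:
        if not self.fit_ok and self.decay_constant != 0.0:
            raise ValueError("failed fits must carry a zero decay constant")


def _window_bounds(n: int, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered window [i - w//2, i + (w - w//2) - 1], clipped to the series."""
    i = np.arange(n)
    lo = np.clip(i - window // 2, 0, n)
    hi = np.clip(i + (window - window // 2), 0, n)
    return lo, hi


def smooth_tic(series: np.ndarray, window: int = SMOOTHING_WINDOW) -> np.ndarray:
    """Centered simple moving average; edges use shrinking windows.

    Output length equals input length.  Series shorter than the window are
    rejected (too short for a meaningful washout fit).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("smooth_tic expects a 1-D series")
    if series.size < window:
        raise ValueError(f"series of {series.size} samples is shorter than the window ({window})")
    lo, hi = _window_bounds(series.size, window)
    c = np.concatenate([[0.0], np.cumsum(series)])
    return (c[hi] - c[lo]) / (hi - lo)


def _smooth_columns(y: np.ndarray, window: int) -> np.ndarray:
    """Moving average along axis 0 of a (T, P) array, shrinking at edges."""
    t = y.shape[0]
    lo, hi = _window_bounds(t, window)
    c = np.vstack([np.zeros((1, y.shape[1])), np.cumsum(y, axis=0)])
    return (c[hi] - c[lo]) / (hi - lo)[:, None]


def _loglinear(
    x: np.ndarray, z: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Masked least squares of z ~ a + b·x along axis 0; returns (a, b, n)."""
    n = w.sum(axis=0)
    sx = (w * x).sum(axis=0)
    sz = np.where(w, z, 0.0).sum(axis=0)
    sxx = (w * x * x).sum(axis=0)
    sxz = (np.where(w, z, 0.0) * x * w).sum(axis=0)
    denom = n * sxx - sx * sx
    safe = denom > 0
    b = np.where(safe, (n * sxz - sx * sz) / np.where(safe, denom, 1.0), 0.0)
    a = np.where(n > 0, (sz - b * sx) / np.maximum(n, 1), 0.0)
    return a, b, n


def fit_decay(
    series: np.ndarray,
    fps: float,
    max_intensity_threshold: float = MAX_INTENSITY_THRESHOLD,
    latest_peak_time: float = LATEST_PEAK_TIME,
    edge_guard: int = SMOOTHING_WINDOW,
    rel_floor: float = 0.02,
    min_post_peak: int = 10,
    refine: bool = False,
) -> DecayFitResult:
    """Fit the post-peak washout of one (already smoothed) TIC.

    Parameters mirror the map-level rules: a smoothed peak below
    ``max_intensity_threshold`` or at/after ``latest_peak_time`` marks the
    pixel unperfused (k = 0, ``fit_ok=False``).  ``edge_guard`` samples after
    the peak and before the series end are excluded (moving-average edge
    regions); if that leaves fewer than ``min_post_peak`` usable samples the
    guard is dropped, and if still too few the fit is marked failed.
    ``refine=True`` polishes the log-linear solution with a nonlinear
    least-squares pass in the linear domain.
    """
    series = np.asarray(series, dtype=float)
    if not (fps > 0):
        raise ValueError("fps must be positive")
    n = series.size
    peak_idx = int(np.argmax(series))
    peak_value = float(series[peak_idx])
    peak_time = peak_idx / fps

    failed = DecayFitResult(0.0, peak_time, peak_value, False)
    if peak_value < max_intensity_threshold or peak_time >= latest_peak_time:
        return failed

    floor = max(rel_floor * peak_value, 0.0)
    t = np.arange(n) / fps
    usable = series > floor

    sel = usable.copy()
    sel[: peak_idx + edge_guard] = False
    sel[n - edge_guard :] = False
    if sel.sum() < min_post_peak:
        sel = usable.copy()
        sel[:peak_idx] = False
    if sel.sum() < min_post_peak:
        return failed

    x = t[sel] - peak_time
    z = np.log(series[sel])
    a, b, _ = _loglinear(x[:, None], z[:, None], np.ones((x.size, 1), dtype=bool))
    amp = float(np.exp(a[0]))
    k = max(-float(b[0]), 0.0)

    if refine:
        from scipy.optimize import curve_fit

        try:
            popt, _ = curve_fit(
                lambda tt, aa, kk: aa * np.exp(-kk * tt),
                x,
                series[sel],
                p0=(amp, k),
                maxfev=2000,
            )
            amp, k = float(popt[0]), max(float(popt[1]), 0.0)
        except RuntimeError:
            pass

    rss = float(np.sum((series[sel] - amp * np.exp(-k * x)) ** 2))
    return DecayFitResult(k, peak_time, peak_value, True, rss)


def decay_map(
    stack: FrameStack,
    window: int = SMOOTHING_WINDOW,
    max_intensity_threshold: float = MAX_INTENSITY_THRESHOLD,
    latest_peak_time: float = LATEST_PEAK_TIME,
    edge_guard: int | None = None,
    rel_floor: float = 0.02,
    min_post_peak: int = 10,
    chunk_px: int = 2048,
) -> FlowMap:
    """Per-pixel smooth + washout fit over a contrast stack.

    The zero-assignment rules are exhaustive: every pixel is either fit
    (``valid_mask`` True) or explicitly assigned 0 1/s; the output contains
    no NaNs.  Work proceeds in pixel chunks to bound memory on long
    recordings.
    """
    if stack.modality != "contrast":
        raise ValueError("decay_map expects a contrast stack")
    if edge_guard is None:
        edge_guard = window
    t_frames, h, w = stack.data.shape
    if t_frames < window:
        raise ValueError("recording shorter than the smoothing window")

    flat = stack.data.reshape(t_frames, h * w)
    k_out = np.zeros(h * w)
    ok_out = np.zeros(h * w, dtype=bool)
    t = np.arange(t_frames) / stack.fps

    for start in range(0, h * w, chunk_px):
        y = np.asarray(flat[:, start : start + chunk_px], dtype=float)
        ys = _smooth_columns(y, window)
        peak_idx = np.argmax(ys, axis=0)
        peak_val = ys[peak_idx, np.arange(ys.shape[1])]
        peak_time = peak_idx / stack.fps

        eligible = (peak_val >= max_intensity_threshold) & (peak_time < latest_peak_time)
        if not eligible.any():
            continue

        tt = np.arange(t_frames)[:, None]
        floor = rel_floor * peak_val[None, :]
        usable = ys > floor
        sel = usable & (tt >= (peak_idx + edge_guard)[None, :]) & (tt < t_frames - edge_guard)
        n_sel = sel.sum(axis=0)

        # log-linear slope per pixel over the selected samples
        z = np.log(np.where(sel, ys, 1.0))
        x = (t[:, None] - peak_time[None, :])
        _, slope, n_fit = _loglinear(np.where(sel, x, 0.0), z, sel)
        k = np.maximum(-slope, 0.0)

        good = eligible & (n_fit >= min_post_peak)
        # rare pixels with too few guarded samples: retry without the guard
        deficient = eligible & (n_sel < min_post_peak)
        for j in np.nonzero(deficient)[0]:
            res = fit_decay(
                ys[:, j],
                stack.fps,
                max_intensity_threshold,
                latest_peak_time,
                edge_guard,
                rel_floor,
                min_post_peak,
            )
            k[j] = res.decay_constant
            good[j] = res.fit_ok

        idx = slice(start, start + y.shape[1])
        k_out[idx] = np.where(good, k, 0.0)
        ok_out[idx] = good

    return FlowMap(
        values=k_out.reshape(h, w),
        units="1/s",
        pixel_size=stack.pixel_size,
        valid_mask=ok_out.reshape(h, w),
        meta=dict(stack.meta),
    )


def offset_disk(radius_px: int = 5, height: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Non-flat disk structuring element: footprint mask and heights.

    The element is ``b(s) = height·sqrt(1 − |s|²/r²)`` on the disk
    ``|s| <= r`` — a spherical cap of the given height over a flat disk.
    """
    if radius_px < 1:
        raise ValueError("radius must be at least 1 pixel")
    if height < 0:
        raise ValueError("height must be non-negative")
    yy, xx = np.mgrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    r2 = (yy**2 + xx**2) / radius_px**2
    footprint = r2 <= 1.0
    heights = np.where(footprint, height * np.sqrt(np.clip(1.0 - r2, 0.0, None)), 0.0)
    return footprint, heights


def open_offset_disk(
    image: np.ndarray, radius_px: int = 5, height: float = 0.05
) -> np.ndarray:
    """Grayscale opening with the non-flat offset-disk element.

    Erosion then dilation with the same element; anti-extensive (output <=
    input) and idempotent, it suppresses isolated bright speckle narrower
    than the disk while leaving extended structures intact.  Image borders
    are handled by reflection.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    if radius_px > min(image.shape) // 2:
        raise ValueError("structuring element larger than half the image")
    footprint, heights = offset_disk(radius_px, height)
    return ndimage.grey_opening(
        image, footprint=footprint, structure=heights, mode="reflect"
    )
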