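"""Spatial distribution of flow versus signed distance from the injury.

The pipeline here mirrors how the recordings are reduced to one curve per
image: every ROI pixel gets its minimum Euclidean distance to the manually
drawn injury line (rostral side negative, caudal positive), pixels are binned
into 0.1 mm distance bins, each bin is summarized by the area-adjusted index

    I = v * (A_px / A_ROI)

(v: mean value of "colored" pixels in the bin, A_px/A_ROI: fraction of bin
pixels that are colored), and the binned curve is smoothed with a 1 mm
moving-average filter to damp the imprint of individual vessels.
"""

from __future__ import annotations

import numpy as np

from .datatypes import FlowMap, InjuryGeometry, SpatialProfile

__all__ = [
    "signed_distance_map",
    "roi_mask",
    "area_adjusted_index",
    "bin_profile",
    "smooth_profile",
]


def signed_distance_map(geometry: InjuryGeometry, shape: tuple[int, int]) -> np.ndarray:
    """Signed distance (mm) from every pixel center to the injury segment.

    The magnitude is the minimum Euclidean distance from the pixel to the
    two-point injury segment, scaled by ``pixel_size``.  The sign splits the
    image along the infinite line through the segment: pixels on the rostral
    side are negative.  With ``geometry.rostral_left`` (default) the rostral
    side is the one with smaller column index.
    """
    h, w = shape
    p0, p1 = geometry.injury_line
    d = p1 - p0
    seg_len2 = float(d @ d)
    if seg_len2 == 0:
        raise ValueError("degenerate injury line")

    cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    px = cols - p0[0]
    py = rows - p0[1]

    # closest point on the segment
    t = np.clip((px * d[0] + py * d[1]) / seg_len2, 0.0, 1.0)
    dist = np.hypot(px - t * d[0], py - t * d[1])

    # side of the infinite line, oriented so +x (caudal when rostral_left) is +
    n = np.array([-d[1], d[0]])  # a normal of the line
    if n[0] < 0 or (n[0] == 0 and n[1] < 0):
        n = -n
    side = np.sign(px * n[0] + py * n[1])
    if not geometry.rostral_left:
        side = -side
    return side * dist * geometry.pixel_size


def _border_rows(border: np.ndarray, w: int) -> np.ndarray:
    """Interpolated border row (y) at every pixel column, clamped outside."""
    order = np.argsort(border[:, 0])
    xs = border[order, 0]
    ys = border[order, 1]
    return np.interp(np.arange(w, dtype=float), xs, ys)


def roi_mask(geometry: InjuryGeometry, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels strictly between the two border polylines."""
    h, w = shape
    y_up = _border_rows(geometry.upper_border, w)
    y_lo = _border_rows(geometry.lower_border, w)
    rows = np.arange(h, dtype=float)[:, None]
    return (rows > y_up[None, :]) & (rows < y_lo[None, :])


def area_adjusted_index(values: np.ndarray, colored_threshold: float = 0.0) -> float:
    """Area-adjusted index I of one bin of pixel values.

    ``v`` is the mean over pixels strictly above ``colored_threshold`` (0 if
    none are); the fraction of such pixels is A_px / A_ROI; I is their
    product.  With the default threshold 0 this collapses algebraically to
    the plain mean including zeros.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty bin: no pixels to summarize")
    colored = values > colored_threshold
    n_col = int(colored.sum())
    if n_col == 0:
        return 0.0
    v = float(values[colored].mean())
    return v * (n_col / values.size)


def bin_profile(
    flow: FlowMap | np.ndarray,
    distances: np.ndarray,
    mask: np.ndarray,
    bin_width: float = 0.1,
    colored_threshold: float = 0.0,
    units: str | None = None,
) -> SpatialProfile:
    """Bin ROI pixels by signed distance and compute I per bin.

    Bins are half-open ``[edge, edge + bin_width)`` with an edge anchored at
    distance 0, so "the closest peak on either side of 0 mm" is well defined.
    Bins inside the covered distance range that receive no ROI pixels are
    flagged missing (NaN), not zero.
    """
    if isinstance(flow, FlowMap):
        values_img = flow.values
        if units is None:
            units = flow.units
    else:
        values_img = np.asarray(flow, dtype=float)
        if units is None:
            units = "AU"
    distances = np.asarray(distances, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values_img.shape != distances.shape or values_img.shape != mask.shape:
        raise ValueError("flow, distances and mask shapes must agree")
    if not mask.any():
        raise ValueError("empty ROI")
    if not (bin_width > 0):
        raise ValueError("bin_width must be positive")

    d = distances[mask]
    v = values_img[mask]

    idx = np.floor(d / bin_width).astype(int)
    lo = int(idx.min())
    hi = int(idx.max())
    nb = hi - lo + 1
    idx -= lo

    counts = np.bincount(idx, minlength=nb)
    colored = v > colored_threshold
    n_col = np.bincount(idx[colored], minlength=nb)
    s_col = np.bincount(idx[colored], weights=v[colored], minlength=nb)

    index_values = np.full(nb, np.nan)
    nonempty = counts > 0
    # I = (sum of colored values / n_colored) * (n_colored / n_total)
    #   = sum of colored values / n_total
    index_values[nonempty] = s_col[nonempty] / counts[nonempty]

    centers = (np.arange(lo, hi + 1) + 0.5) * bin_width
    return SpatialProfile(
        bin_centers=centers,
        index_values=index_values,
        bin_pixel_counts=counts,
        bin_width=bin_width,
        units=units,
    )


def smooth_profile(profile: SpatialProfile, window: float = 1.0) -> SpatialProfile:
    """Centered moving average of the profile over a window in mm.

    The window is converted to bins and rounded to the nearest odd count (a
    1 mm window over 0.1 mm bins uses 11 bins) so the filter is symmetric.
    Missing bins are excluded from each local mean; edges use shrinking
    windows.  Smoothing never fills a bin farther than half a window from the
    nearest observed bin.
    """
    if not (window > 0):
        raise ValueError("window must be positive")
    n = max(1, round(window / profile.bin_width))
    if n % 2 == 0:
        n += 1
    half = n // 2

    vals = profile.index_values
    ok = np.isfinite(vals)
    padded = np.concatenate([np.full(half, np.nan), np.where(ok, vals, np.nan), np.full(half, np.nan)])
    win = np.lib.stride_tricks.sliding_window_view(padded, n)
    with np.errstate(invalid="ignore"):
        counts = np.sum(np.isfinite(win), axis=1)
        sums = np.nansum(win, axis=1)
    smoothed = np.full(vals.shape, np.nan)
    nz = counts > 0
    smoothed[nz] = sums[nz] / counts[nz]
    return SpatialProfile(
        bin_centers=profile.bin_centers.copy(),
        index_values=smoothed,
        bin_pixel_counts=profile.bin_pixel_counts.copy(),
        bin_width=profile.bin_width,
        units=profile.units,
    )
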