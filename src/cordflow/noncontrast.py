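"""Non-contrast (SMI-type Doppler) recordings -> velocity-index flow maps.

Clinical scanners export color-Doppler frames as RGB overlays; the mapping
back to a scalar velocity index is performed against a user-supplied colormap
lookup table (the scanner's exact colormap is proprietary, so it is treated
as an input; a linear hot-scale default is provided).  Grayscale recordings
are assumed to be index-valued already and bypass the decode.  Each short
recording is then reduced to a single map by time-averaging, which cancels
cardiac pulsatility over the few cardiac cycles a 5 s clip contains.
"""

from __future__ import annotations

import numpy as np

from .datatypes import FlowMap, FrameStack

__all__ = [
    "default_hot_lut",
    "validate_lut",
    "color_to_velocity_index",
    "time_average_map",
]


def default_hot_lut(n: int = 16) -> np.ndarray:
    """A linear hot-scale LUT: ``(n, 4)`` rows of ``R, G, B, index``.

    Colors ramp black -> red -> yellow -> white (matplotlib 'hot'), indices
    linear on [1/n, 1] so that the darkest entry still codes nonzero flow and
    pure black background does not collide with a LUT color.
    """
    from matplotlib import colormaps

    cmap = colormaps["hot"]
    idx = np.linspace(1.0 / n, 1.0, n)
    rgb = np.asarray([cmap(x)[:3] for x in idx]) * 255.0
    return np.column_stack([rgb, idx])


def validate_lut(lut: np.ndarray) -> np.ndarray:
    """Validate and normalize a LUT to a float ``(n, 4)`` array."""
    lut = np.asarray(lut, dtype=float)
    if lut.ndim != 2 or lut.shape[1] != 4 or lut.shape[0] == 0:
        raise ValueError("LUT must be a nonempty (n, 4) array of R, G, B, index")
    idx = lut[:, 3]
    if np.any(idx < 0) or np.any(idx > 1):
        raise ValueError("LUT indices must lie in [0, 1]")
    if np.any(np.diff(idx) <= 0):
        raise ValueError("LUT indices must be strictly ascending")
    colors = lut[:, :3]
    uniq = np.unique(colors, axis=0)
    if uniq.shape[0] != colors.shape[0]:
        raise ValueError("LUT contains duplicate colors")
    return lut


def color_to_velocity_index(
    rgb_frame: np.ndarray,
    lut: np.ndarray,
    max_color_distance: float = 30.0,
) -> np.ndarray:
    """Decode an RGB color-Doppler frame to a velocity-index map.

    Each pixel is assigned the index of the nearest LUT color (Euclidean in
    RGB space).  Pixels farther than ``max_color_distance`` from every LUT
    entry — B-mode gray background, annotations — map to index 0.
    """
    lut = validate_lut(lut)
    frame = np.asarray(rgb_frame, dtype=float)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB frame")

    flat = frame.reshape(-1, 3)
    # squared distances to every LUT color: (Npx, Nlut)
    d2 = (
        np.einsum("ij,ij->i", flat, flat)[:, None]
        - 2.0 * flat @ lut[:, :3].T
        + np.einsum("ij,ij->i", lut[:, :3], lut[:, :3])[None, :]
    )
    nearest = np.argmin(d2, axis=1)
    mind = np.sqrt(np.maximum(d2[np.arange(flat.shape[0]), nearest], 0.0))
    out = lut[nearest, 3]
    out[mind > max_color_distance] = 0.0
    return out.reshape(frame.shape[:2])


def time_average_map(stack: FrameStack) -> FlowMap:
    """Per-pixel arithmetic mean across frames (one map per recording)."""
    if stack.n_frames < 1:
        raise ValueError("empty stack")
    values = stack.data.mean(axis=0, dtype=float)
    units = "1/s" if stack.modality == "contrast" else "AU"
    return FlowMap(
        values=values,
        units=units,
        pixel_size=stack.pixel_size,
        meta=dict(stack.meta),
    )
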