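"""Core containers shared across the pipeline.

These are deliberately thin: validated ``dataclass`` wrappers around numpy
arrays plus the calibration metadata (frame rate, pixel size) that every
downstream stage needs.  Flow is always a *surrogate* quantity — either a
velocity index in arbitrary units (non-contrast Doppler) or a microbubble
washout decay constant in 1/s (contrast harmonic imaging) — never an absolute
velocity in mm/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FrameStack",
    "FlowMap",
    "InjuryGeometry",
    "SpatialProfile",
    "ZoneLabels",
]


@dataclass
class FrameStack:
    """A single-modality recording: T frames of H x W non-negative intensities.

    Parameters
    ----------
    data
        ``(T, H, W)`` array.  Velocity-index frames for ``modality='noncontrast'``
        (AU), contrast-harmonic intensities for ``modality='contrast'`` (AU).
    fps
        Frame rate in frames per second.
    pixel_size
        Lateral calibration in mm/pixel (isotropic pixels assumed).
    modality
        ``'noncontrast'`` or ``'contrast'``.
    meta
        Free-form metadata (synthetic stacks store their ground truth here).
    """

    data: np.ndarray
    fps: float
    pixel_size: float
    modality: str = "noncontrast"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected (T, H, W) data, got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("stack must contain at least one frame")
        if not (self.fps > 0):
            raise ValueError(f"fps must be positive, got {self.fps}")
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        if self.modality not in ("noncontrast", "contrast"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite values")
        if np.any(self.data < 0):
            raise ValueError("stack contains negative intensities")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (H, W)."""
        return self.data.shape[1:]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_frames / self.fps

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds (first frame at t = 0)."""
        return np.arange(self.n_frames) / self.fps


@dataclass
class FlowMap:
    """A single H x W map of a flow surrogate with a validity mask.

    ``units`` is ``'AU'`` for velocity-index maps and ``'1/s'`` for decay-constant
    maps.  Invalid pixels (e.g. contrast pixels whose washout could not be fit)
    carry value 0 and ``valid_mask == False``.
    """

    values: np.ndarray
    units: str
    pixel_size: float
    valid_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("FlowMap values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FlowMap contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("flow surrogates are non-negative")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.values.shape:
                raise ValueError("valid_mask shape mismatch")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class InjuryGeometry:
    """User-drawn injury line and cord borders, in pixel coordinates.

    The injury line is a two-point segment drawn perpendicular to the long
    (rostro-caudal) axis of the cord.  The two borders are polylines of
    ``(x, y)`` vertices (x = column, y = row) bounding the band of perforating
    vessels; pixels strictly between them form the region of interest,
    excluding the anterior/posterior spinal arteries running along the cord
    surface.
    """

    injury_line: np.ndarray  # (2, 2) [(x0, y0), (x1, y1)]
    upper_border: np.ndarray  # (N, 2) (x, y) vertices, smaller y (dorsal)
    lower_border: np.ndarray  # (M, 2) (x, y) vertices, larger y (ventral)
    pixel_size: float
    rostral_left: bool = True

    def __post_init__(self) -> None:
        self.injury_line = np.asarray(self.injury_line, dtype=float)
        self.upper_border = np.asarray(self.upper_border, dtype=float)
        self.lower_border = np.asarray(self.lower_border, dtype=float)
        if self.injury_line.shape != (2, 2):
            raise ValueError("injury_line must be a 2-point segment")
        if np.allclose(self.injury_line[0], self.injury_line[1]):
            raise ValueError("injury_line is degenerate (zero length)")
        for b in (self.upper_border, self.lower_border):
            if b.ndim != 2 or b.shape[1] != 2 or b.shape[0] < 2:
                raise ValueError("borders must be (N>=2, 2) polylines")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be positive")

    def flipped(self) -> "InjuryGeometry":
        """Return a copy with the rostral/caudal sign convention reversed."""
        return replace(self, rostral_left=not self.rostral_left)


@dataclass
class SpatialProfile:
    """Area-adjusted flow versus signed distance from the injury.

    ``bin_centers`` are in mm, rostral negative, on a uniform grid of spacing
    ``bin_width``; ``index_values`` hold the area-adjusted index I per bin
    (NaN marks bins with no ROI pixels — flagged missing, never silently
    zero); ``bin_pixel_counts`` are total ROI pixels per bin.
    """

    bin_centers: np.ndarray
    index_values: np.ndarray
    bin_pixel_counts: np.ndarray
    bin_width: float = 0.1
    units: str = "AU"

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.index_values = np.asarray(self.index_values, dtype=float)
        self.bin_pixel_counts = np.asarray(self.bin_pixel_counts, dtype=int)
        n = self.bin_centers.size
        if self.index_values.size != n or self.bin_pixel_counts.size != n:
            raise ValueError("profile arrays must have equal length")
        if n >= 2:
            steps = np.diff(self.bin_centers)
            if np.any(steps <= 0):
                raise ValueError("bin_centers must be strictly increasing")
            if not np.allclose(steps, self.bin_width, atol=1e-9 * max(1.0, self.bin_width)):
                raise ValueError("bin_centers must be uniformly spaced by bin_width")
        with np.errstate(invalid="ignore"):
            if np.any(self.index_values < 0):
                raise ValueError("index values must be non-negative (NaN marks missing)")

    @property
    def n_bins(self) -> int:
        return self.bin_centers.size

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of bins with no data."""
        return ~np.isfinite(self.index_values)

    def value_at(self, location_mm: float) -> float:
        """Index value of the bin whose center is nearest ``location_mm``."""
        i = int(np.argmin(np.abs(self.bin_centers - location_mm)))
        return float(self.index_values[i])

    def same_grid(self, other: "SpatialProfile", atol: float = 1e-9) -> bool:
        return (
            self.n_bins == other.n_bins
            and np.allclose(self.bin_centers, other.bin_centers, atol=atol)
        )


@dataclass
class ZoneLabels:
    """Injury-zone parameters extracted from one spatial profile.

    Locations in mm (signed, rostral negative), flows in the profile's units.
    ``penumbra prominence`` is penumbra flow minus umbra flow, per side.
    ``injury_extent`` is the distance between the half-maximum crossings
    flanking the umbra.  ``labeling_ok`` is False when a penumbra peak is
    missing on either side or no half-maximum crossing exists; ``notes``
    records soft warnings (e.g. an umbra found at the search-interval edge).
    """

    umbra_location: float = np.nan
    umbra_flow: float = np.nan
    rostral_penumbra_location: float = np.nan
    rostral_penumbra_flow: float = np.nan
    caudal_penumbra_location: float = np.nan
    caudal_penumbra_flow: float = np.nan
    rostral_prominence: float = np.nan
    caudal_prominence: float = np.nan
    rostral_distal_flow: float = np.nan
    caudal_distal_flow: float = np.nan
    injury_extent: float = np.nan
    labeling_ok: bool = False
    notes: tuple = ()

    def as_dict(self) -> dict:
        return {
            "umbra_location_mm": self.umbra_location,
            "umbra_flow": self.umbra_flow,
            "rostral_penumbra_location_mm": self.rostral_penumbra_location,
            "rostral_penumbra_flow": self.rostral_penumbra_flow,
            "caudal_penumbra_location_mm": self.caudal_penumbra_location,
            "caudal_penumbra_flow": self.caudal_penumbra_flow,
            "rostral_prominence": self.rostral_prominence,
            "caudal_prominence": self.caudal_prominence,
            "rostral_distal_flow": self.rostral_distal_flow,
            "caudal_distal_flow": self.caudal_distal_flow,
            "injury_extent_mm": self.injury_extent,
            "labeling_ok": self.labeling_ok,
            "notes": list(self.notes),
        }
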