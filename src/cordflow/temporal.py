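"""Frame-by-frame zone tracking for continuous recordings.

Long non-contrast recordings are analyzed one frame at a time: each frame is
reduced to a spatial profile, the profile is smoothed and zone-labeled, and
the resulting location traces are median filtered (default 40-frame window)
to remove the occasional jump discontinuities produced by mislabeled peaks —
injury zones do not teleport.  Flows are then sampled at the filtered
locations, and distal means are recomputed per frame (optionally frozen to
the first frame's penumbra locations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datatypes import FrameStack, InjuryGeometry, SpatialProfile, ZoneLabels
from .profile import bin_profile, roi_mask, signed_distance_map, smooth_profile
from .zones import MIN_PROMINENCE, distal_flows, label_zones

__all__ = [
    "ZoneTimeSeries",
    "per_frame_profiles",
    "median_filter_locations",
    "zone_traces",
    "track_zones",
]

LOCATION_ZONES = ("umbra", "rostral_penumbra", "caudal_penumbra")
FLOW_ZONES = LOCATION_ZONES + ("rostral_distal", "caudal_distal")


@dataclass
class ZoneTimeSeries:
    """Per-frame zone locations (raw and filtered) and flows.

    All traces share the frame count; frames where labeling failed carry NaN
    and ``labeling_ok`` False.
    """

    times: np.ndarray
    raw_locations: dict
    locations: dict
    flows: dict
    labeling_ok: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: frame, time_s, zone, location_mm, flow."""
        rows = []
        for zone in FLOW_ZONES:
            loc = self.locations.get(zone)
            for i, t in enumerate(self.times):
                rows.append(
                    {
                        "frame": i,
                        "time_s": float(t),
                        "zone": zone,
                        "location_mm": float(loc[i]) if loc is not None else np.nan,
                        "flow": float(self.flows[zone][i]),
                    }
                )
        return pd.DataFrame(rows)


def per_frame_profiles(
    stack: FrameStack,
    geometry: InjuryGeometry,
    bin_width: float = 0.1,
    colored_threshold: float = 0.0,
) -> list[SpatialProfile]:
    """Unsmoothed spatial profile of every frame, on one shared bin grid."""
    if stack.modality != "noncontrast":
        raise ValueError("frame-by-frame tracking expects a non-contrast stack")
    shape = stack.shape
    dist = signed_distance_map(geometry, shape)
    mask = roi_mask(geometry, shape)
    units = "AU"
    return [
        bin_profile(stack.data[i], dist, mask, bin_width, colored_threshold, units)
        for i in range(stack.n_frames)
    ]


def median_filter_locations(trace: np.ndarray, window: int = 40) -> np.ndarray:
    """Centered running median of a location trace.

    Even window sizes are rounded up to the next odd count so the filter is
    symmetric and a glitch shorter than half the window can never reach the
    median (a 40-frame request uses 41 frames: a run of up to 20 mislabeled
    frames is removed exactly).  Edges use shrinking windows; NaNs (frames
    where labeling failed) are ignored within each window.  A trace shorter
    than the window shrinks the window with a warning.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ValueError("expected a 1-D trace")
    if window < 1:
        raise ValueError("window must be positive")
    if trace.size < window:
        warnings.warn(
            f"trace of {trace.size} frames shorter than the {window}-frame window; shrinking",
            stacklevel=2,
        )
        window = trace.size
    if window % 2 == 0:
        window += 1
    half = window // 2
    padded = np.concatenate([np.full(half, np.nan), trace, np.full(half, np.nan)])
    win = np.lib.stride_tricks.sliding_window_view(padded, window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        return np.nanmedian(win, axis=1)


def zone_traces(
    profiles: list[SpatialProfile],
    filtered_locations: dict,
    fps: float,
    raw_locations: dict | None = None,
    labeling_ok: np.ndarray | None = None,
    freeze_distal: bool = False,
) -> ZoneTimeSeries:
    """Sample per-frame flows at the filtered zone locations.

    Distal means are recomputed per frame outside that frame's filtered
    penumbra locations (or outside the first valid frame's when
    ``freeze_distal``).  A filtered location falling outside a frame's
    profile domain yields a missing (NaN) flow for that frame.
    """
    n = len(profiles)
    if labeling_ok is None:
        labeling_ok = np.ones(n, dtype=bool)
    flows = {zone: np.full(n, np.nan) for zone in FLOW_ZONES}

    frozen = None
    if freeze_distal:
        valid = np.nonzero(labeling_ok)[0]
        if valid.size:
            i0 = valid[0]
            frozen = (
                filtered_locations["rostral_penumbra"][i0],
                filtered_locations["caudal_penumbra"][i0],
            )

    for i, prof in enumerate(profiles):
        lo, hi = prof.bin_centers[0], prof.bin_centers[-1]
        for zone in LOCATION_ZONES:
            loc = filtered_locations[zone][i]
            if np.isfinite(loc) and lo - prof.bin_width / 2 <= loc <= hi + prof.bin_width / 2:
                flows[zone][i] = prof.value_at(loc)
        ro = frozen[0] if frozen else filtered_locations["rostral_penumbra"][i]
        ca = frozen[1] if frozen else filtered_locations["caudal_penumbra"][i]
        if np.isfinite(ro) and np.isfinite(ca):
            stub = ZoneLabels(rostral_penumbra_location=ro, caudal_penumbra_location=ca)
            r, c = distal_flows(prof, stub)
            flows["rostral_distal"][i] = r
            flows["caudal_distal"][i] = c

    times = np.arange(n) / fps
    return ZoneTimeSeries(
        times=times,
        raw_locations=raw_locations or {},
        locations=filtered_locations,
        flows=flows,
        labeling_ok=labeling_ok,
    )


def track_zones(
    stack: FrameStack,
    geometry: InjuryGeometry,
    bin_width: float = 0.1,
    smooth_window_mm: float = 1.0,
    min_prominence: float = MIN_PROMINENCE,
    median_window: int = 40,
    freeze_distal: bool = False,
) -> ZoneTimeSeries:
    """Full temporal pipeline: per-frame profile -> label -> median filter.

    Zones are re-detected on every (smoothed) frame profile; their location
    traces are median filtered; flows are then sampled at the filtered
    locations.
    """
    profiles = per_frame_profiles(stack, geometry, bin_width)
    smoothed = [smooth_profile(p, smooth_window_mm) for p in profiles]

    n = len(smoothed)
    raw = {zone: np.full(n, np.nan) for zone in LOCATION_ZONES}
    ok = np.zeros(n, dtype=bool)
    for i, prof in enumerate(smoothed):
        labels = label_zones(prof, min_prominence)
        ok[i] = labels.labeling_ok
        if labels.labeling_ok:
            raw["umbra"][i] = labels.umbra_location
            raw["rostral_penumbra"][i] = labels.rostral_penumbra_location
            raw["caudal_penumbra"][i] = labels.caudal_penumbra_location

    filtered = {z: median_filter_locations(raw[z], median_window) for z in LOCATION_ZONES}
    return zone_traces(
        smoothed,
        filtered,
        stack.fps,
        raw_locations=raw,
        labeling_ok=ok,
        freeze_distal=freeze_distal,
    )
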