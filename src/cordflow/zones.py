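"""Injury-zone labeling from a post-injury spatial profile.

The post-injury distribution of flow over distance shows a characteristic
shape: a trough of abolished flow at the epicenter (umbra) flanked by two
peaks of elevated flow (penumbras) decaying to an unchanged distal baseline.
Labeling proceeds as:

1. local maxima with topographic prominence >= 0.03 AU are detected; the
   closest qualifying peak on each side of 0 mm is the rostral / caudal
   penumbra;
2. the minimum of the profile strictly between the two penumbras is the
   umbra (a run of tied consecutive bins resolves to the run center);
3. penumbra prominence = penumbra flow − umbra flow, per side;
4. the injury extent is the distance between the half-maximum crossings —
   walking from the umbra toward each penumbra, the (interpolated) location
   where flow reaches the mean of that penumbra's and the umbra's flow;
5. distal flow is the mean over bins strictly outside the penumbras.

Pre-injury parameters are read from the pre-injury profile at the locations
labeled on the post-injury profile.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.signal import find_peaks

from .datatypes import SpatialProfile, ZoneLabels

__all__ = [
    "MIN_PROMINENCE",
    "find_penumbra_peaks",
    "locate_umbra",
    "injury_extent",
    "distal_flows",
    "label_zones",
    "pre_injury_parameters",
    "plot_zone_qc",
]

#: default minimum topographic peak prominence (AU) for penumbra detection
MIN_PROMINENCE = 0.03


def _dense_values(profile: SpatialProfile) -> tuple[np.ndarray, np.ndarray]:
    """Profile values with interior missing bins linearly interpolated.

    Peak detection needs a gap-free series; leading/trailing missing bins are
    dropped.  Returns (values, original bin indices).
    """
    vals = profile.index_values
    ok = np.isfinite(vals)
    if not ok.any():
        raise ValueError("profile has no observed bins")
    first, last = np.nonzero(ok)[0][[0, -1]]
    idx = np.arange(first, last + 1)
    v = vals[idx].copy()
    bad = ~np.isfinite(v)
    if bad.any():
        v[bad] = np.interp(idx[bad], idx[~bad], v[~bad])
    return v, idx


def find_penumbra_peaks(
    profile: SpatialProfile, min_prominence: float = MIN_PROMINENCE
) -> dict:
    """Detect penumbra candidates and pick the nearest peak per side of 0 mm.

    Peaks are local maxima whose topographic prominence (height above the
    lowest contour line isolating the peak) reaches ``min_prominence``.
    Returns a dict with all qualifying peaks and, per side, the one closest
    to 0 mm (``None`` when a side has no qualifying peak).
    """
    v, idx = _dense_values(profile)
    centers = profile.bin_centers[idx]
    pk, props = find_peaks(v, prominence=min_prominence)
    locs = centers[pk]
    heights = v[pk]

    rostral = caudal = None
    left = locs < 0
    right = locs > 0
    if left.any():
        i = np.nonzero(left)[0][np.argmax(locs[left])]
        rostral = (float(locs[i]), float(heights[i]))
    if right.any():
        i = np.nonzero(right)[0][np.argmin(locs[right])]
        caudal = (float(locs[i]), float(heights[i]))
    return {
        "rostral": rostral,
        "caudal": caudal,
        "all_locations": locs,
        "all_heights": heights,
        "prominences": props["prominences"],
    }


def locate_umbra(
    profile: SpatialProfile,
    rostral_location: float,
    caudal_location: float,
    tie_tol: float = 0.0,
) -> tuple[float, float, tuple]:
    """Minimum of the profile strictly between the two penumbra peaks.

    A run of consecutive bins tied at the minimum resolves to the center of
    the run; multiple separate tied runs resolve to the run closest to 0 mm.
    A minimum at the search-interval boundary (monotone segment) is returned
    but flagged in the notes.
    """
    centers = profile.bin_centers
    vals = profile.index_values
    between = (centers > rostral_location) & (centers < caudal_location) & np.isfinite(vals)
    if not between.any():
        raise ValueError("no observed bins between the penumbra peaks")
    idx = np.nonzero(between)[0]
    v = vals[idx]
    vmin = v.min()
    tied = np.nonzero(v <= vmin + tie_tol)[0]

    # split tied bins into consecutive runs
    runs = np.split(tied, np.nonzero(np.diff(tied) > 1)[0] + 1)
    run_centers = [float(centers[idx[r]].mean()) for r in runs]
    best = int(np.argmin(np.abs(run_centers)))
    location = run_centers[best]

    notes = []
    if len(runs) > 1:
        notes.append("non-consecutive minimum ties broken toward 0 mm")
    if tied.min() == 0 or tied.max() == v.size - 1:
        notes.append("umbra at the edge of the inter-penumbra interval")
    return location, float(vmin), tuple(notes)


def _half_max_crossing(
    centers: np.ndarray,
    vals: np.ndarray,
    umbra_idx: int,
    peak_location: float,
    threshold: float,
    step: int,
) -> float | None:
    """Walk from the umbra toward one penumbra; interpolate the first upward
    crossing of ``threshold``.  Returns None when no crossing exists."""
    i = umbra_idx
    while True:
        j = i + step
        if j < 0 or j >= centers.size:
            return None
        if step > 0 and centers[j] > peak_location + 1e-12:
            return None
        if step < 0 and centers[j] < peak_location - 1e-12:
            return None
        v0, v1 = vals[i], vals[j]
        if np.isfinite(v0) and np.isfinite(v1) and v0 < threshold <= v1:
            frac = (threshold - v0) / (v1 - v0)
            return float(centers[i] + frac * (centers[j] - centers[i]))
        i = j


def injury_extent(profile: SpatialProfile, labels: ZoneLabels) -> float:
    """Distance between the half-maximum crossings flanking the umbra.

    The half-maximum threshold per side is the mean of that side's penumbra
    flow and the umbra flow; crossings are located by linear interpolation
    between the bracketing bins.  Returns NaN when a side has no crossing
    (flat profile) — a labeling failure.
    """
    centers = profile.bin_centers
    vals = profile.index_values
    umbra_idx = int(np.argmin(np.abs(centers - labels.umbra_location)))

    thr_r = 0.5 * (labels.rostral_penumbra_flow + labels.umbra_flow)
    thr_c = 0.5 * (labels.caudal_penumbra_flow + labels.umbra_flow)
    xr = _half_max_crossing(centers, vals, umbra_idx, labels.rostral_penumbra_location, thr_r, -1)
    xc = _half_max_crossing(centers, vals, umbra_idx, labels.caudal_penumbra_location, thr_c, +1)
    if xr is None or xc is None:
        return np.nan
    return float(xc - xr)


def distal_flows(profile: SpatialProfile, labels: ZoneLabels) -> tuple[float, float]:
    """Mean flow over bins strictly outside the penumbras, per side.

    A side with no observed distal bins yields NaN (missing, not zero).
    """
    centers = profile.bin_centers
    vals = profile.index_values
    ok = np.isfinite(vals)
    ro = ok & (centers < labels.rostral_penumbra_location)
    ca = ok & (centers > labels.caudal_penumbra_location)
    ro_mean = float(vals[ro].mean()) if ro.any() else np.nan
    ca_mean = float(vals[ca].mean()) if ca.any() else np.nan
    return ro_mean, ca_mean


def label_zones(
    profile: SpatialProfile, min_prominence: float = MIN_PROMINENCE
) -> ZoneLabels:
    """Full zone labeling of one post-injury profile.

    ``labeling_ok`` is False when either side lacks a qualifying penumbra
    peak or a half-maximum crossing cannot be found.
    """
    if not ((profile.bin_centers < 0).any() and (profile.bin_centers > 0).any()):
        raise ValueError("profile must cover both sides of 0 mm")
    peaks = find_penumbra_peaks(profile, min_prominence)
    if peaks["rostral"] is None or peaks["caudal"] is None:
        missing = [s for s in ("rostral", "caudal") if peaks[s] is None]
        return ZoneLabels(
            labeling_ok=False,
            notes=tuple(f"no {s} penumbra peak with prominence >= {min_prominence}" for s in missing),
        )

    ro_loc, ro_flow = peaks["rostral"]
    ca_loc, ca_flow = peaks["caudal"]
    um_loc, um_flow, notes = locate_umbra(profile, ro_loc, ca_loc)

    labels = ZoneLabels(
        umbra_location=um_loc,
        umbra_flow=um_flow,
        rostral_penumbra_location=ro_loc,
        rostral_penumbra_flow=ro_flow,
        caudal_penumbra_location=ca_loc,
        caudal_penumbra_flow=ca_flow,
        rostral_prominence=ro_flow - um_flow,
        caudal_prominence=ca_flow - um_flow,
        labeling_ok=True,
        notes=notes,
    )
    extent = injury_extent(profile, labels)
    ro_distal, ca_distal = distal_flows(profile, labels)
    ok = np.isfinite(extent)
    if not ok:
        notes = labels.notes + ("no half-maximum crossing on at least one side",)
    else:
        notes = labels.notes
    return replace(
        labels,
        injury_extent=extent,
        rostral_distal_flow=ro_distal,
        caudal_distal_flow=ca_distal,
        labeling_ok=ok,
        notes=notes,
    )


def pre_injury_parameters(
    pre_profile: SpatialProfile, post_labels: ZoneLabels
) -> ZoneLabels:
    """Zone parameters of the pre-injury profile at post-injury locations.

    Flows are read from the pre-injury profile at the umbra/penumbra bins
    labeled on the post-injury distribution; prominences and distal means are
    recomputed.  The injury extent is left NaN — it is defined by crossings
    of the post-injury trough and has no pre-injury analog.
    """
    if not post_labels.labeling_ok:
        raise ValueError("post-injury labeling failed; nothing to transfer")
    um_flow = pre_profile.value_at(post_labels.umbra_location)
    ro_flow = pre_profile.value_at(post_labels.rostral_penumbra_location)
    ca_flow = pre_profile.value_at(post_labels.caudal_penumbra_location)
    base = replace(
        post_labels,
        umbra_flow=um_flow,
        rostral_penumbra_flow=ro_flow,
        caudal_penumbra_flow=ca_flow,
        rostral_prominence=ro_flow - um_flow,
        caudal_prominence=ca_flow - um_flow,
        injury_extent=np.nan,
        notes=("values read from pre-injury profile at post-injury locations",),
    )
    ro_distal, ca_distal = distal_flows(pre_profile, base)
    return replace(base, rostral_distal_flow=ro_distal, caudal_distal_flow=ca_distal)


def plot_zone_qc(profile: SpatialProfile, labels: ZoneLabels, path=None):
    """Quality-control plot of a labeled profile (visual-verification aid)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.2))
    ax.plot(profile.bin_centers, profile.index_values, color="0.2", lw=1.2)
    if labels.labeling_ok:
        ax.plot(labels.umbra_location, labels.umbra_flow, "v", color="tab:red", label="umbra")
        ax.plot(
            [labels.rostral_penumbra_location, labels.caudal_penumbra_location],
            [labels.rostral_penumbra_flow, labels.caudal_penumbra_flow],
            "^",
            color="tab:blue",
            label="penumbras",
        )
        ax.legend(loc="upper right", fontsize=8)
    ax.axvline(0.0, color="0.7", ls=":")
    ax.set_xlabel("distance from injury (mm)")
    ax.set_ylabel(f"area-adjusted index ({profile.units})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
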