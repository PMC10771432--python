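"""Reading and writing the pipeline's on-disk formats.

Recordings travel as multi-page TIFF stacks with a JSON sidecar
(``<stack>.json``) holding the calibration (fps, mm/pixel, modality) and,
for synthetic stacks, the ground truth.  Geometry (injury line + borders) is
JSON; colormap LUTs are CSV with columns R, G, B, index; profiles are CSV
with columns bin_center_mm, index, n_pixels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import FlowMap, FrameStack, InjuryGeometry, SpatialProfile, ZoneLabels

__all__ = [
    "write_stack",
    "read_stack",
    "write_flow_map",
    "read_flow_map",
    "write_geometry",
    "read_geometry",
    "read_lut",
    "write_profile",
    "read_profile",
    "write_zone_labels",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path, stack: FrameStack, truth: dict | None = None) -> None:
    """Write a multi-page TIFF plus its JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.data, dtype=np.float32))
    sidecar = {
        "fps": stack.fps,
        "pixel_size_mm": stack.pixel_size,
        "modality": stack.modality,
    }
    if truth is not None:
        sidecar["truth"] = truth
    _sidecar(path).write_text(json.dumps(sidecar, indent=2))


def read_stack(path, fps: float | None = None, pixel_size: float | None = None,
               modality: str | None = None) -> FrameStack:
    """Read a multi-page TIFF stack; calibration from sidecar unless given."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    fps = fps if fps is not None else meta.get("fps")
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size_mm")
    modality = modality or meta.get("modality", "noncontrast")
    if fps is None or pixel_size is None:
        raise ValueError(f"{path}: fps and pixel size must come from the sidecar or arguments")
    return FrameStack(
        data=np.asarray(data, dtype=float),
        fps=float(fps),
        pixel_size=float(pixel_size),
        modality=modality,
        meta={"truth": meta.get("truth")} if meta.get("truth") else {},
    )


def write_flow_map(path, flow: FlowMap) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(flow.values, dtype=np.float32))
    _sidecar(path).write_text(
        json.dumps({"units": flow.units, "pixel_size_mm": flow.pixel_size})
    )


def read_flow_map(path, units: str | None = None, pixel_size: float | None = None) -> FlowMap:
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=float)
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    units = units or meta.get("units", "AU")
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size_mm")
    if pixel_size is None:
        raise ValueError(f"{path}: pixel size must come from the sidecar or arguments")
    return FlowMap(values=np.maximum(values, 0.0), units=units, pixel_size=float(pixel_size))


def write_geometry(path, geometry: InjuryGeometry) -> None:
    doc = {
        "injury_line": geometry.injury_line.tolist(),
        "upper_border": geometry.upper_border.tolist(),
        "lower_border": geometry.lower_border.tolist(),
        "pixel_size_mm": geometry.pixel_size,
        "rostral_left": geometry.rostral_left,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_geometry(path) -> InjuryGeometry:
    doc = json.loads(Path(path).read_text())
    return InjuryGeometry(
        injury_line=np.asarray(doc["injury_line"], dtype=float),
        upper_border=np.asarray(doc["upper_border"], dtype=float),
        lower_border=np.asarray(doc["lower_border"], dtype=float),
        pixel_size=float(doc["pixel_size_mm"]),
        rostral_left=bool(doc.get("rostral_left", True)),
    )


def read_lut(path) -> np.ndarray:
    """Read a colormap LUT CSV with columns R, G, B, index."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    return df[["r", "g", "b", "index"]].to_numpy(dtype=float)


def write_profile(path, profile: SpatialProfile) -> None:
    pd.DataFrame(
        {
            "bin_center_mm": profile.bin_centers,
            "index": profile.index_values,
            "n_pixels": profile.bin_pixel_counts,
        }
    ).to_csv(path, index=False)


def read_profile(path, bin_width: float | None = None, units: str = "AU") -> SpatialProfile:
    df = pd.read_csv(path)
    centers = df["bin_center_mm"].to_numpy(dtype=float)
    if bin_width is None:
        if centers.size < 2:
            raise ValueError("cannot infer bin width from a single bin")
        bin_width = float(np.median(np.diff(centers)))
    return SpatialProfile(
        bin_centers=centers,
        index_values=df["index"].to_numpy(dtype=float),
        bin_pixel_counts=df["n_pixels"].to_numpy(dtype=int),
        bin_width=bin_width,
        units=units,
    )


def write_zone_labels(path, labels: ZoneLabels, extra: dict | None = None) -> None:
    doc = labels.as_dict()
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, default=float))
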