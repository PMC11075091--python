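"""File exchange: float32 TIFF rasters with JSON sidecar metadata.

Phantoms are written as paired delta/beta TIFFs, frame sets as 3D stacks
(frame, row, column), sinograms and reconstructed slices as single 2D
TIFFs; each raster gets a ``<name>.json`` sidecar carrying the geometry
needed to reinterpret it (voxel/pixel sizes in μm, axes, per-frame
schedule). Illumination curves and trajectories are plain CSV (see their
classes).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .assembly import Sinogram
from .forward import Frame, FrameSet
from .phantoms import OpticalMap
from .retrieval import ReconSlice

__all__ = [
    "save_optical_map",
    "load_optical_map",
    "save_frameset",
    "load_frameset",
    "save_sinogram",
    "load_sinogram",
    "save_slice",
    "load_slice",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_optical_map(omap: OpticalMap, basename: str | Path) -> None:
    """Write <basename>_delta.tif, <basename>_beta.tif and <basename>.json."""
    base = Path(basename)
    tifffile.imwrite(base.parent / f"{base.name}_delta.tif", omap.delta.astype(np.float32))
    tifffile.imwrite(base.parent / f"{base.name}_beta.tif", omap.beta.astype(np.float32))
    meta = {
        "voxel_size_um": omap.voxel_size * 1e6,
        "energy_kev": omap.energy,
        "meta": omap.meta,
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_optical_map(basename: str | Path) -> OpticalMap:
    base = Path(basename)
    delta = tifffile.imread(base.parent / f"{base.name}_delta.tif").astype(np.float64)
    beta = tifffile.imread(base.parent / f"{base.name}_beta.tif").astype(np.float64)
    meta = json.loads(base.with_suffix(".json").read_text())
    return OpticalMap(
        delta=delta,
        beta=beta,
        voxel_size=meta["voxel_size_um"] * 1e-6,
        energy=meta["energy_kev"],
        meta=meta.get("meta", {}),
    )


def save_frameset(frameset: FrameSet, path: str | Path) -> None:
    """3D float32 stack (frame, row=1, column) plus per-frame schedule sidecar."""
    path = Path(path)
    stack = np.stack([f.intensities[None, :] for f in frameset.frames]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")
    frames_meta = [
        {
            "angle_deg": f.angle_deg,
            "lateral_offset_um": f.lateral_offset * 1e6,
            "exposure_s": f.exposure,
            "type": f.kind,
            "band": f.band_name,
        }
        for f in frameset.frames
    ]
    _sidecar(path).write_text(json.dumps({"frames": frames_meta}, indent=1))


def load_frameset(path: str | Path) -> FrameSet:
    path = Path(path)
    stack = tifffile.imread(path).astype(np.float64)
    meta = json.loads(_sidecar(path).read_text())["frames"]
    frames = [
        Frame(
            intensities=stack[i, 0, :],
            angle_deg=m["angle_deg"],
            lateral_offset=m["lateral_offset_um"] * 1e-6,
            exposure=m["exposure_s"],
            kind=m["type"],
            band_name=m.get("band", ""),
        )
        for i, m in enumerate(meta)
    ]
    return FrameSet(frames=frames)


def save_sinogram(sino: Sinogram, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, sino.values.astype(np.float32))
    meta = {
        "angles_deg_start": float(sino.angles_deg[0]),
        "angles_deg_step": float(sino.angles_deg[1] - sino.angles_deg[0])
        if sino.angles_deg.size > 1
        else 0.0,
        "n_angles": int(sino.angles_deg.size),
        "lateral_start_um": float(sino.lateral[0] * 1e6),
        "lateral_pitch_um": float(sino.pitch * 1e6),
        "scheme": sino.scheme,
        "band": sino.band_name,
        "signed": sino.signed,
        "meta": {k: v for k, v in sino.meta.items() if isinstance(v, (int, float, str, bool))},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_sinogram(path: str | Path) -> Sinogram:
    path = Path(path)
    values = tifffile.imread(path).astype(np.float64)
    m = json.loads(_sidecar(path).read_text())
    angles = m["angles_deg_start"] + np.arange(m["n_angles"]) * m["angles_deg_step"]
    lateral = (m["lateral_start_um"] + np.arange(values.shape[1]) * m["lateral_pitch_um"]) * 1e-6
    return Sinogram(
        values=values,
        angles_deg=angles,
        lateral=lateral,
        scheme=m.get("scheme", ""),
        band_name=m.get("band", ""),
        signed=m.get("signed", False),
        meta=m.get("meta", {}),
    )


def save_slice(sl: ReconSlice, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, sl.values.astype(np.float32))
    meta = {
        "pixel_size_um": sl.pixel_size * 1e6,
        "meta": {k: v for k, v in sl.meta.items() if isinstance(v, (int, float, str, bool))},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_slice(path: str | Path) -> ReconSlice:
    path = Path(path)
    values = tifffile.imread(path).astype(np.float64)
    m = json.loads(_sidecar(path).read_text())
    return ReconSlice(values=values, pixel_size=m["pixel_size_um"] * 1e-6, meta=m.get("meta", {}))
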