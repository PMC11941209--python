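"""Volume interchange and run provenance.

Volumes travel as multi-page grayscale TIFF (one page per slow-axis
position, each page a depth x fast B-scan) with a JSON sidecar carrying
pixel spacing, axis order, refractive-index assumptions, and intensity
scaling.  There is no otologic OCT interchange standard; multi-page TIFF is
readable by Fiji and every scientific image library.

Linear float intensity is stored as uint16 with a recorded scale factor
(lossy at the 16-bit quantization step); data already in uint16 round-trips
losslessly.  Speckle-variance volumes are stored as 32-bit float TIFF.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .quantify import OCTVolume

__all__ = [
    "read_volume",
    "write_volume",
    "write_sv_volume",
    "read_sv_volume",
    "write_truth",
    "file_digest",
    "RunManifest",
]

SIDECAR_SUFFIX = ".json"
DEFAULT_SPACING = (1.0, 1.0, 1.0)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + SIDECAR_SUFFIX)


def write_volume(path: str | Path, volume: OCTVolume) -> Path:
    """Write a volume as multi-page TIFF (pages along the slow axis) plus a
    JSON sidecar.

    uint16 data is stored bit-for-bit; float data is scaled to the uint16
    range with the scale recorded in the sidecar.
    """
    path = Path(path)
    data = volume.data
    if data.dtype == np.uint16:
        pages, scale = data, 1.0
    else:
        peak = float(data.max())
        scale = 65535.0 / peak if peak > 0 else 1.0
        pages = np.round(data.astype(np.float64) * scale).astype(np.uint16)
    # page layout: (slow, depth, fast)
    tifffile.imwrite(path, np.transpose(pages, (0, 2, 1)), photometric="minisblack")
    sidecar = {
        "axis_order": "slow,fast,depth",
        "page_layout": "depth,fast",
        "pixel_spacing_mm": list(volume.pixel_spacing),
        "intensity_scale": scale,
        "source_dtype": str(data.dtype),
        "n_air": volume.meta.get("n_air", 1.0),
        "n_tissue": volume.meta.get("n_tissue", 1.4),
    }
    for key in ("preset", "seed", "n_repeats"):
        if key in volume.meta:
            sidecar[key] = volume.meta[key]
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_volume(path: str | Path) -> OCTVolume:
    """Read a multi-page TIFF volume and its sidecar.

    Pages must share one shape (the offending page is named otherwise).  A
    missing sidecar is tolerated: spacing defaults to 1.0 mm with the
    default recorded as a warning in the volume metadata.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        shapes = [p.shape for p in tif.pages]
        first = shapes[0]
        for i, s in enumerate(shapes):
            if s != first:
                raise ValueError(
                    f"{path}: page {i} has shape {s}, expected {first} (page 0)"
                )
        pages = tif.asarray()
    if pages.ndim == 2:
        pages = pages[None]
    warnings: list[str] = []
    sidecar_path = _sidecar_path(path)
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
    else:
        sidecar = {}
        warnings.append("missing sidecar; pixel spacing defaulted to 1.0 mm")
    spacing = tuple(sidecar.get("pixel_spacing_mm", DEFAULT_SPACING))
    scale = float(sidecar.get("intensity_scale", 1.0))
    src_dtype = sidecar.get("source_dtype", "uint16")
    data = np.transpose(pages, (0, 2, 1))  # back to (slow, fast, depth)
    if src_dtype != "uint16" or scale != 1.0:
        data = (data.astype(np.float64) / scale).astype(np.float32)
    meta = {k: v for k, v in sidecar.items() if k not in ("pixel_spacing_mm",)}
    if warnings:
        meta["warnings"] = warnings
    return OCTVolume(data=data, pixel_spacing=spacing, meta=meta)


def write_sv_volume(path: str | Path, sv: np.ndarray, meta: dict | None = None) -> Path:
    """Write a speckle-variance volume (slow, fast, depth) as float32 TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.transpose(sv.astype(np.float32), (0, 2, 1)),
                     photometric="minisblack")
    _sidecar_path(path).write_text(
        json.dumps({"axis_order": "slow,fast,depth", "units": "intensity^2",
                    **(meta or {})}, indent=2)
    )
    return path


def read_sv_volume(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    data = np.transpose(tifffile.imread(path), (0, 2, 1))
    sidecar_path = _sidecar_path(path)
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return data, meta


def write_truth(path_stem: str | Path, truth) -> tuple[Path, Path]:
    """Write phantom ground truth: label map as TIFF, the rest as JSON."""
    stem = Path(path_stem)
    label_path = stem.with_name(stem.name + "_labels.tif")
    tifffile.imwrite(label_path, np.transpose(truth.label_map, (0, 2, 1)),
                     photometric="minisblack")
    meta_path = stem.with_name(stem.name + "_truth.json")
    meta_path.write_text(
        json.dumps(
            {
                "class_preset": truth.class_preset,
                "landmarks": {k: list(v) for k, v in truth.landmarks.items()},
                "gap_mm": truth.gap_mm,
                "n_mass_voxels": int(truth.mass_mask.sum()),
            },
            indent=2,
        )
    )
    return label_path, meta_path


def file_digest(path: str | Path) -> str:
    """SHA-256 digest of a file's contents."""
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one pipeline run.

    Digests cover every output file, so a rerun with identical inputs can
    be verified byte-for-byte for deterministic stages.
    """

    tool: str
    version: str
    master_seed: int
    config_hash: str = ""
    outputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def record(self, path: str | Path) -> None:
        path = Path(path)
        self.outputs[path.name] = file_digest(path)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path
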