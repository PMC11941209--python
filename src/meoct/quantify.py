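"""Landmark-referenced quantification of middle-ear OCT volumes.

Conventions
-----------
Volumes are arrays of non-negative linear backscatter intensity with axis
order ``(slow y, fast x, depth z)``; z increases with depth away from the
probe and is measured in optical-path millimetres.  B-scan images extracted
from a volume are presented depth-down, i.e. with shape ``(depth, lateral)``.

Quantification follows the clinical workflow: pick cross-sections through
the malleus umbo, render an 8-bit log-compressed display image, measure mean
pixel intensity in a region-of-interest (ROI) box over the suspected mass
(or the aerated mesotympanum in a normal ear) and normalize it to a box over
the tympanic membrane (TM).  Angiography maps are quantified analogously
with the malleus lateral process as the normalization reference.  Depth
measurements convert optical path to physical distance using the refractive
index of the medium (1.0 in air; 1.4 assumed for soft tissue).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "OCTVolume",
    "RoiBox",
    "Landmark",
    "DepthCalibration",
    "RatioResult",
    "CrossSections",
    "GapMeasurement",
    "extract_cross_sections",
    "enface_projection",
    "roi_mean",
    "structural_ratio",
    "angio_ratio",
    "optical_to_physical_depth",
    "depth_uncertainty",
    "tumor_tm_gap",
    "render_display",
]

LANDMARK_NAMES = ("umbo", "malleus_lateral_process")


@dataclass
class OCTVolume:
    """3-D linear-intensity OCT volume with pixel spacing metadata.

    ``data`` has axis order (slow y, fast x, depth z).  ``pixel_spacing`` is
    (dx, dy, dz) in mm per voxel; dz is optical-path mm (divide by the
    medium's refractive index to obtain physical depth).
    """

    data: np.ndarray
    pixel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        if np.any(self.data < 0):
            raise ValueError("volume intensities must be non-negative")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValueError(f"pixel spacing must be positive, got {self.pixel_spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class RoiBox:
    """Rectangular pixel ROI: 0-based inclusive origin, (height, width) size."""

    row: int
    col: int
    height: int
    width: int
    plane_id: str = ""

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI box must be at least 1x1")
        if self.row < 0 or self.col < 0:
            raise ValueError("ROI origin must be non-negative")

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row, self.row + self.height),
                slice(self.col, self.col + self.width))

    def validate_within(self, image: np.ndarray) -> None:
        if self.row + self.height > image.shape[0] or self.col + self.width > image.shape[1]:
            raise ValueError(
                f"ROI {self} exceeds image of shape {image.shape[:2]}"
            )

    def overlaps(self, other: "RoiBox") -> bool:
        return not (
            self.row + self.height <= other.row
            or other.row + other.height <= self.row
            or self.col + self.width <= other.col
            or other.col + other.width <= self.col
        )


@dataclass(frozen=True)
class Landmark:
    """Named anatomical anchor point in voxel coordinates (slow, fast, depth)."""

    name: str
    coords: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.name not in LANDMARK_NAMES:
            raise ValueError(f"unknown landmark {self.name!r}; expected one of {LANDMARK_NAMES}")

    def validate_within(self, volume: OCTVolume) -> None:
        for c, n in zip(self.coords, volume.shape):
            if not (0 <= c < n):
                raise ValueError(
                    f"landmark {self.name!r} at {self.coords} outside volume {volume.shape}"
                )


@dataclass(frozen=True)
class DepthCalibration:
    """Refractive indices used to convert optical path length to physical depth.

    OCT measures optical distance.  In the air-filled middle-ear space the
    index is 1.0 (no correction); through soft tissue a nominal 1.4 is
    assumed, with a plausible range of 1.33-1.45 across soft-tissue and
    tumor types that bounds the depth uncertainty.
    """

    n_air: float = 1.0
    n_tissue: float = 1.4
    n_tissue_range: tuple[float, float] = (1.33, 1.45)

    def __post_init__(self) -> None:
        if self.n_air != 1.0:
            raise ValueError("refractive index of air is fixed at 1.0")
        lo, hi = self.n_tissue_range
        if not (lo <= self.n_tissue <= hi):
            raise ValueError(
                f"n_tissue {self.n_tissue} outside plausible range {self.n_tissue_range}"
            )


@dataclass(frozen=True)
class RatioResult:
    """ROI intensity ratio (numerator mean / denominator mean)."""

    kind: str  # "structural" or "angio"
    numerator_mean: float
    denominator_mean: float
    ratio: float
    numerator_box: RoiBox
    denominator_box: RoiBox
    ear_id: str = ""
    class_label: str = ""


@dataclass(frozen=True)
class CrossSections:
    """XZ and YZ cross-sections through the umbo, depth-down."""

    xz: np.ndarray  # (depth, fast) at the umbo's slow index
    yz: np.ndarray  # (depth, slow) at the umbo's fast index
    slow_index: int
    fast_index: int
    umbo_in_xz: tuple[int, int]  # (depth row, fast col)
    umbo_in_yz: tuple[int, int]  # (depth row, slow col)


@dataclass(frozen=True)
class GapMeasurement:
    """Per-A-line tumor-to-TM air gap over the mass footprint."""

    gap_mm: np.ndarray  # per-A-line gap, NaN outside footprint / flagged lines
    min_mm: float
    max_mm: float
    n_flagged: int  # A-lines where the mass surface sat above the TM inner surface


def extract_cross_sections(volume: OCTVolume, umbo: Landmark) -> CrossSections:
    """Extract the XZ and YZ cross-sections through the malleus umbo.

    The umbo is the standard landmark for representative cross-sections: the
    XZ image is the B-scan at the umbo's slow index, the YZ image the
    re-slice at its fast index.  Both are returned depth-down with the
    umbo's in-plane pixel coordinates recorded.
    """
    if umbo.name != "umbo":
        raise ValueError(f"cross-sections are anchored at the umbo, got {umbo.name!r}")
    umbo.validate_within(volume)
    y0, x0, z0 = umbo.coords
    xz = volume.data[y0].T  # (depth, fast)
    yz = volume.data[:, x0, :].T  # (depth, slow)
    return CrossSections(
        xz=xz, yz=yz, slow_index=y0, fast_index=x0,
        umbo_in_xz=(z0, x0), umbo_in_yz=(z0, y0),
    )


def enface_projection(volume: OCTVolume | np.ndarray, z_lo: int, z_hi: int) -> np.ndarray:
    """Averaged-intensity en-face (XY) projection over the depth window
    ``[z_lo, z_hi)``.

    A window of 40-50 depth pixels centred on the TM stratum shows the
    topography of the membrane with the malleus silhouette.
    """
    data = volume.data if isinstance(volume, OCTVolume) else np.asarray(volume)
    nz = data.shape[2]
    if not (0 <= z_lo < z_hi <= nz):
        raise ValueError(f"invalid depth window [{z_lo}, {z_hi}) for depth {nz}")
    return data[:, :, z_lo:z_hi].mean(axis=2)


def roi_mean(image: np.ndarray, box: RoiBox) -> float:
    """Arithmetic mean pixel intensity over an ROI box."""
    image = np.asarray(image)
    box.validate_within(image)
    return float(image[box.slices()].mean())


def _ratio(
    image: np.ndarray,
    num_box: RoiBox,
    den_box: RoiBox,
    kind: str,
    require_disjoint: bool,
    ear_id: str,
    class_label: str,
) -> RatioResult:
    if require_disjoint and num_box.overlaps(den_box):
        raise ValueError("ROI boxes must be disjoint")
    num = roi_mean(image, num_box)
    den = roi_mean(image, den_box)
    if den <= 0:
        raise ValueError(f"{kind} ratio undefined: reference ROI mean is {den}")
    return RatioResult(
        kind=kind, numerator_mean=num, denominator_mean=den, ratio=num / den,
        numerator_box=num_box, denominator_box=den_box,
        ear_id=ear_id, class_label=class_label,
    )


def structural_ratio(
    display_image: np.ndarray,
    mass_box: RoiBox,
    tm_box: RoiBox,
    ear_id: str = "",
    class_label: str = "",
) -> RatioResult:
    """Mass-to-TM mean pixel intensity ratio on a display cross-section.

    The mass box sits over the suspected middle-ear mass (for a normal ear,
    over the aerated mesotympanum at a comparable depth); the reference box
    sits on the tympanic membrane in the same image, normalizing out
    between-scan variation in focus and scattering.
    """
    return _ratio(display_image, mass_box, tm_box, "structural", True, ear_id, class_label)


def angio_ratio(
    angio_enface: np.ndarray,
    mass_box: RoiBox,
    malleus_box: RoiBox,
    ear_id: str = "",
    class_label: str = "",
) -> RatioResult:
    """Mass-to-malleus mean speckle-variance ratio on an angiography en-face map.

    The reference box sits over the malleus lateral process, a readily
    identifiable landmark whose overlying vascular strip gives a stable
    baseline angiography signal.  At clinical scale the boxes are 100x100
    (mass) and 50x50 (reference) pixels; on smaller grids they are scaled
    proportionally by the caller, who records the scaling.
    """
    return _ratio(angio_enface, mass_box, malleus_box, "angio", True, ear_id, class_label)


def optical_to_physical_depth(
    path_mm: float | np.ndarray,
    medium: str,
    cal: DepthCalibration = DepthCalibration(),
) -> float | np.ndarray:
    """Convert an optical path length (mm) to physical depth (mm).

    physical = optical / n_medium: 1 mm of optical path is 1 mm in air and
    1/1.4 mm through soft tissue at the assumed index.
    """
    path = np.asarray(path_mm, dtype=float)
    if np.any(path < 0):
        raise ValueError("optical path length must be non-negative")
    if medium == "air":
        n = cal.n_air
    elif medium == "tissue":
        n = cal.n_tissue
    else:
        raise ValueError(f"unknown medium {medium!r}; expected 'air' or 'tissue'")
    out = path / n
    return float(out) if np.isscalar(path_mm) else out


def depth_uncertainty(cal: DepthCalibration = DepthCalibration()) -> dict:
    """Relative depth-measurement error bounds from refractive-index uncertainty.

    If the true tissue index n lies in ``n_tissue_range`` but depths are
    converted with the assumed index, the relative error of the recovered
    physical depth is n_assumed/n - 1.  Returns the signed bounds at the
    range endpoints and their maximum magnitude; the bounds should accompany
    any through-tissue depth measurement.
    """
    lo, hi = cal.n_tissue_range
    bounds = (cal.n_tissue / hi - 1.0, cal.n_tissue / lo - 1.0)
    return {
        "lower": min(bounds),
        "upper": max(bounds),
        "max_abs": max(abs(b) for b in bounds),
    }


def tumor_tm_gap(
    tm_inner_z: np.ndarray,
    mass_top_z: np.ndarray,
    z_spacing_mm: float,
    cal: DepthCalibration = DepthCalibration(),
) -> GapMeasurement:
    """Per-A-line air gap between the TM inner surface and the mass upper surface.

    Both surfaces are depth indices over a common (slow, fast) footprint;
    NaN marks A-lines outside the mass footprint.  The gap is air, so the
    optical-path distance is converted with n = 1.0 (an identity).  A-lines
    where the mass surface sits above the TM inner surface are physically
    inconsistent (segmentation error); they are flagged, counted, and
    excluded from the min/max summary.
    """
    tm = np.asarray(tm_inner_z, dtype=float)
    mass = np.asarray(mass_top_z, dtype=float)
    if tm.shape != mass.shape:
        raise ValueError("TM and mass surfaces must share a common footprint shape")
    if z_spacing_mm <= 0:
        raise ValueError("z spacing must be positive")
    gap_px = mass - tm
    footprint = np.isfinite(mass) & np.isfinite(tm)
    inverted = footprint & (gap_px < 0)
    valid = footprint & ~inverted
    gap_mm = np.full(tm.shape, np.nan)
    gap_mm[valid] = gap_px[valid] * z_spacing_mm / cal.n_air
    if not valid.any():
        raise ValueError("no valid A-lines in the common footprint")
    return GapMeasurement(
        gap_mm=gap_mm,
        min_mm=float(np.nanmin(gap_mm)),
        max_mm=float(np.nanmax(gap_mm)),
        n_flagged=int(inverted.sum()),
    )


def render_display(
    volume: OCTVolume | np.ndarray, dynamic_range_db: float = 40.0
) -> np.ndarray:
    """Render a linear-intensity volume (or image) to 8-bit log-compressed display.

    display = clip(10*log10(I / I_max) + DR, 0, DR) * 255/DR, rounded
    half-up to integers.  The window top maps the volume maximum to 255 and
    anything at or below I_max * 10^(-DR/10) to 0.  Deterministic: the same
    linear data and window always yield bit-identical output.
    """
    data = volume.data if isinstance(volume, OCTVolume) else np.asarray(volume)
    if dynamic_range_db <= 0:
        raise ValueError("dynamic range must be positive (dB)")
    if data.size == 0:
        raise ValueError("cannot render an empty volume")
    i_max = float(data.max())
    if i_max <= 0:
        return np.zeros(data.shape, dtype=np.uint8)
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(np.asarray(data, dtype=float) / i_max)
    scaled = np.clip(db + dynamic_range_db, 0.0, dynamic_range_db) * (255.0 / dynamic_range_db)
    return np.floor(scaled + 0.5).astype(np.uint8)  # round half-up
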