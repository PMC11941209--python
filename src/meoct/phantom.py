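"""Synthetic middle-ear OCT phantoms with vascular ground truth.

The generator emulates what a handheld otologic OCT volume of the middle
ear contains: a curved tympanic membrane (TM) drawn inward to its apex at
the malleus umbo, the malleus handle and lateral process, the
incudostapedial joint, the bony cochlear promontory forming the medial
wall, an air-filled mesotympanum, and — for the pathological presets — a
soft-tissue mass draped beneath the TM that attenuates the beam and
shadows the structures beyond it.

Image formation is split into an expected-intensity render and a coherent
speckle stage:

* ``render_mean_intensity`` applies single-scatter Beer-Lambert optics:
  mu(x, y, z) = backscatter * exp(-2 * cumulative attenuation) + noise floor.
* ``sample_speckle_volume`` draws fully developed speckle: each voxel's
  field is zero-mean circular complex Gaussian with variance mu, so the
  intensity I = |E|^2 is exponentially distributed with mean mu.
* ``sample_repeat_stack`` adds the temporal dimension used by
  speckle-variance angiography: across consecutive B-scans the signal field
  follows a first-order autoregressive process
  E_{i+1} = rho * E_i + sqrt(1 - rho^2) * xi, giving lag-k field
  correlation rho^k.  Static tissue has rho = 1, perfused voxels a low rho.
  An optional temporally uncorrelated noise field (the detection noise
  floor) decorrelates even static speckle slightly, which is what gives the
  malleus reference region its stable baseline angiography signal.

Four class presets mirror the diagnostic groups of interest: ``normal``
(no mass), ``glomus`` (highly vascular mass reaching down to the
promontory, separated from the TM by a 0-0.2 mm air gap), ``cholesteatoma``
(avascular keratin debris attached to the TM), and ``schwannoma``
(intermediate vascularity).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .quantify import Landmark, OCTVolume
from .angio import RepeatStack

__all__ = [
    "REGION_LABELS",
    "TissueRegion",
    "MassSpec",
    "PhantomScene",
    "PhantomTruth",
    "EarData",
    "make_scene",
    "rasterize",
    "render_mean_intensity",
    "sample_speckle_volume",
    "sample_repeat_stack",
    "build_ear",
    "build_cohort",
    "PRESET_NAMES",
    "DEFAULT_GRID",
    "DEFAULT_SPACING",
]

# integer codes for the rendered label map
REGION_LABELS = {
    "air": 0,
    "tm": 1,
    "malleus": 2,
    "is_joint": 3,
    "promontory": 4,
    "mass": 5,
}

PRESET_NAMES = ("normal", "glomus", "cholesteatoma", "schwannoma")

DEFAULT_GRID = (64, 256, 512)  # (slow y, fast x, depth z)
DEFAULT_SPACING = (0.04, 0.10, 0.02)  # (dx, dy, dz) mm per voxel; dz is optical path


@dataclass(frozen=True)
class TissueRegion:
    """Optical properties of one tissue class.

    backscatter is a relative (dimensionless) backscatter coefficient;
    attenuation is a per-mm intensity attenuation coefficient applied
    two-way; flow_rho is the inter-repeat complex-field correlation
    (1 = static, 0 = fully decorrelated).
    """

    label: str
    backscatter: float
    attenuation: float
    flow_rho: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in REGION_LABELS:
            raise ValueError(f"unknown tissue label {self.label!r}")
        if self.backscatter < 0 or self.attenuation < 0:
            raise ValueError("backscatter and attenuation must be >= 0")
        if not (0.0 <= self.flow_rho <= 1.0):
            raise ValueError("flow_rho must lie in [0, 1]")


def _default_optics() -> dict[str, TissueRegion]:
    # air carries no backscatter of its own (the additive noise floor is
    # applied globally) and is static by definition
    return {
        "air": TissueRegion("air", 0.0, 0.0, 1.0),
        "tm": TissueRegion("tm", 1.0, 0.8, 1.0),
        "malleus": TissueRegion("malleus", 1.5, 2.0, 1.0),
        "is_joint": TissueRegion("is_joint", 1.3, 2.0, 1.0),
        "promontory": TissueRegion("promontory", 1.2, 2.0, 1.0),
        "mass": TissueRegion("mass", 0.45, 1.5, 1.0),
    }


@dataclass(frozen=True)
class MassSpec:
    """Soft-tissue mass primitive draped beneath the TM.

    The mass occupies an elliptical (slow, fast) footprint; its upper
    surface conforms to the TM inner surface at a uniform air gap of
    ``gap_mm`` (so the designed gap is recovered identically across the
    footprint), and its thickness tapers toward the footprint edge, capped
    below by the promontory.  ``vascular_fraction`` of its voxels are
    perfused with inter-repeat correlation ``rho_vessel``.
    """

    center_uv: tuple[float, float]  # (slow v, fast u), normalized [0, 1]
    radii_uv: tuple[float, float]  # footprint semi-axes, normalized
    max_thickness_frac: float  # peak thickness as a fraction of depth
    gap_mm: float
    vascular_fraction: float
    rho_vessel: float

    def __post_init__(self) -> None:
        if self.gap_mm < 0:
            raise ValueError("gap_mm must be >= 0")
        if not (0.0 <= self.vascular_fraction <= 1.0):
            raise ValueError("vascular_fraction must lie in [0, 1]")
        if not (0.0 <= self.rho_vessel <= 1.0):
            raise ValueError("rho_vessel must lie in [0, 1]")


@dataclass
class PhantomScene:
    """Geometric and optical description of one synthetic ear."""

    class_preset: str
    seed: int
    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    pixel_spacing: tuple[float, float, float] = DEFAULT_SPACING
    # TM geometry: shallow rim pulled inward to the umbo apex
    umbo_uv: tuple[float, float] = (0.5, 0.5)  # (slow v, fast u)
    tm_rim_frac: float = 0.16  # rim depth as a fraction of nz
    tm_umbo_frac: float = 0.30  # apex depth as a fraction of nz
    tm_indent_width: float = 0.25  # Gaussian indentation width, normalized
    tm_thickness_mm: float = 0.12
    # malleus: lateral process bump + handle running to the umbo
    lp_uv: tuple[float, float] = (0.30, 0.5)
    lp_radius_mm: float = 0.45
    handle_radius_mm: float = 0.30
    # incudostapedial joint
    isj_uv: tuple[float, float] = (0.5, 0.62)
    isj_frac: float = 0.50
    isj_radius_mm: float = 0.40
    # cochlear promontory (medial bony wall)
    prom_frac: float = 0.72
    prom_bump_frac: float = 0.04
    mass: Optional[MassSpec] = None
    optics: dict[str, TissueRegion] = field(default_factory=_default_optics)
    noise_floor: float = 0.010  # additive expected-intensity floor
    rho_static: float = 1.0
    n_repeats: int = 4

    def __post_init__(self) -> None:
        if self.class_preset not in PRESET_NAMES:
            raise ValueError(f"unknown preset {self.class_preset!r}")
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError(f"grid shape must be strictly positive, got {self.grid_shape}")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValueError(f"pixel spacing must be positive, got {self.pixel_spacing}")
        if self.class_preset == "normal" and self.mass is not None:
            raise ValueError("the normal preset has no mass")
        for uv, what in ((self.umbo_uv, "umbo"), (self.lp_uv, "malleus lateral process")):
            if not (0.0 < uv[0] < 1.0 and 0.0 < uv[1] < 1.0):
                raise ValueError(f"{what} coordinates {uv} must lie inside the grid")
        if not (0.0 < self.tm_rim_frac < self.tm_umbo_frac < self.prom_frac < 1.0):
            raise ValueError("depth ordering must be rim < umbo apex < promontory")
        if self.noise_floor < 0:
            raise ValueError("noise floor must be >= 0")


@dataclass
class PhantomTruth:
    """Voxel-level ground truth for one synthetic ear."""

    label_map: np.ndarray  # uint8 region codes, (ny, nx, nz)
    rho_map: np.ndarray  # float32 inter-repeat field correlation
    landmarks: dict[str, tuple[int, int, int]]  # name -> (slow, fast, depth)
    mass_mask: np.ndarray  # bool, (ny, nx, nz)
    tm_inner_surface: np.ndarray  # (ny, nx) depth index of the TM inner boundary
    mass_top_surface: np.ndarray  # (ny, nx) float depth of mass upper surface, NaN outside
    gap_mm: Optional[float]  # designed tumor-to-TM air gap
    class_preset: str


@dataclass
class EarData:
    """One realized synthetic ear: volume, repeat stacks, and truth."""

    ear_id: str
    class_label: str
    scene: PhantomScene
    truth: PhantomTruth
    volume: OCTVolume
    stacks: Optional[list[RepeatStack]] = None


# ---------------------------------------------------------------------------
# scene construction


def _preset_mass(preset: str, rng: np.random.Generator) -> Optional[MassSpec]:
    """Draw the per-ear mass primitive for a preset (None for normal).

    Glomus gaps are drawn uniformly over the clinically observed 0-0.2 mm
    range; cholesteatoma debris is attached to the TM (gap 0).  Vascular
    fractions encode the qualitative ordering highly vascular glomus >
    intermediate schwannoma > avascular cholesteatoma.
    """
    jit = lambda lo, hi: float(rng.uniform(lo, hi))
    if preset == "normal":
        return None
    if preset == "glomus":
        return MassSpec(
            center_uv=(jit(0.50, 0.60), jit(0.50, 0.60)),
            radii_uv=(jit(0.20, 0.24), jit(0.18, 0.22)),
            max_thickness_frac=0.45,
            gap_mm=jit(0.0, 0.2),
            vascular_fraction=jit(0.45, 0.55),
            rho_vessel=0.2,
        )
    if preset == "cholesteatoma":
        return MassSpec(
            center_uv=(jit(0.36, 0.44), jit(0.54, 0.62)),
            radii_uv=(jit(0.18, 0.22), jit(0.16, 0.20)),
            max_thickness_frac=0.30,
            gap_mm=0.0,
            vascular_fraction=0.0,
            rho_vessel=1.0,
        )
    if preset == "schwannoma":
        return MassSpec(
            center_uv=(jit(0.50, 0.60), jit(0.56, 0.64)),
            radii_uv=(jit(0.16, 0.20), jit(0.15, 0.19)),
            max_thickness_frac=0.35,
            gap_mm=jit(0.0, 0.1),
            vascular_fraction=jit(0.12, 0.18),
            rho_vessel=0.35,
        )
    raise ValueError(f"unknown preset {preset!r}")


def make_scene(
    preset: str,
    seed: int,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID,
    pixel_spacing: tuple[float, float, float] = DEFAULT_SPACING,
    n_repeats: int = 4,
    **overrides,
) -> PhantomScene:
    """Build a scene for one synthetic ear with per-ear anatomical jitter.

    The seed drives both the geometric jitter here and, downstream, the
    speckle realization, so an ear is fully reproducible from
    (preset, seed, grid).
    """
    if preset not in PRESET_NAMES:
        raise ValueError(f"unknown preset {preset!r}; expected one of {PRESET_NAMES}")
    rng = np.random.default_rng(seed)
    jitter = lambda lo, hi: float(rng.uniform(lo, hi))
    scene = PhantomScene(
        class_preset=preset,
        seed=seed,
        grid_shape=tuple(grid_shape),
        pixel_spacing=tuple(pixel_spacing),
        umbo_uv=(jitter(0.46, 0.54), jitter(0.46, 0.54)),
        tm_rim_frac=jitter(0.14, 0.18),
        tm_umbo_frac=jitter(0.28, 0.32),
        lp_uv=(jitter(0.27, 0.33), jitter(0.46, 0.54)),
        mass=_preset_mass(preset, rng),
        n_repeats=n_repeats,
    )
    for key, val in overrides.items():
        if not hasattr(scene, key):
            raise TypeError(f"unknown scene parameter {key!r}")
        setattr(scene, key, val)
    scene.__post_init__()
    return scene


# ---------------------------------------------------------------------------
# rasterization


def rasterize(scene: PhantomScene) -> tuple[PhantomTruth, np.ndarray, np.ndarray]:
    """Rasterize a scene to (truth, backscatter map, attenuation map).

    Paint order is air -> promontory -> mass -> incudostapedial joint ->
    malleus -> TM, so each voxel carries exactly one region label and the
    membrane stays visible over embedded structures.
    """
    ny, nx, nz = scene.grid_shape
    dx, dy, dz = scene.pixel_spacing
    code = REGION_LABELS

    v = (np.arange(ny) + 0.5)[:, None] / ny  # slow, normalized
    u = (np.arange(nx) + 0.5)[None, :] / nx  # fast, normalized
    zidx = np.arange(nz)[None, None, :]

    # --- TM surface: shallow rim with a Gaussian indentation to the umbo apex
    v0, u0 = scene.umbo_uv
    z_rim = scene.tm_rim_frac * nz
    z_apex = scene.tm_umbo_frac * nz
    w2 = 2.0 * scene.tm_indent_width**2
    indent = np.exp(-(((u - u0) ** 2) + ((v - v0) ** 2)) / w2)
    z_tm = z_rim + (z_apex - z_rim) * indent  # (ny, nx) float
    tm_thick = max(2, int(round(scene.tm_thickness_mm / dz)))
    tm_outer = np.rint(z_tm).astype(int)
    tm_inner = tm_outer + tm_thick  # first voxel *below* the membrane

    # --- promontory: medial bony wall bulging slightly toward the probe
    bump = scene.prom_bump_frac * nz * np.exp(
        -(((u - 0.55) ** 2) + ((v - 0.5) ** 2)) / (2.0 * 0.3**2)
    )
    z_prom = np.rint(scene.prom_frac * nz - bump).astype(int)
    z_prom = np.clip(z_prom, tm_inner + 2, nz - 1)

    label = np.zeros((ny, nx, nz), dtype=np.uint8)
    label[(zidx >= z_prom[:, :, None])] = code["promontory"]

    # --- mass draped beneath the TM at a uniform designed air gap
    mass_mask = np.zeros((ny, nx, nz), dtype=bool)
    mass_top = np.full((ny, nx), np.nan)
    gap_mm: Optional[float] = None
    if scene.mass is not None:
        m = scene.mass
        gap_mm = m.gap_mm
        d2 = ((v - m.center_uv[0]) / m.radii_uv[0]) ** 2 + (
            (u - m.center_uv[1]) / m.radii_uv[1]
        ) ** 2
        thickness = m.max_thickness_frac * nz * np.sqrt(np.clip(1.0 - d2, 0.0, None))
        footprint = thickness >= 1.0
        gap_px = int(round(m.gap_mm / dz))
        top = tm_inner + gap_px
        bot = np.minimum(top + np.rint(thickness).astype(int), z_prom)
        inside = footprint[:, :, None] & (zidx >= top[:, :, None]) & (zidx < bot[:, :, None])
        # footprint columns pinched out between TM and promontory hold no mass
        inside &= (bot > top)[:, :, None]
        mass_mask = inside
        label[inside] = code["mass"]
        _mass_top_design = top

    # physical coordinates for the ossicle primitives (mm)
    xx = u * nx * dx
    yy = v * ny * dy
    zz_mm = (np.arange(nz) + 0.5)[None, None, :] * dz

    def _interp_tm(uv: tuple[float, float]) -> float:
        vv, uu = uv
        return float(
            z_rim + (z_apex - z_rim) * np.exp(-(((uu - u0) ** 2) + ((vv - v0) ** 2)) / w2)
        )

    # --- incudostapedial joint: small ellipsoid in the posterior mesotympanum
    isj_c = np.array(
        [scene.isj_uv[0] * ny * dy, scene.isj_uv[1] * nx * dx, scene.isj_frac * nz * dz]
    )
    d_isj = (
        ((yy[:, :, None] - isj_c[0]) ** 2)
        + ((xx[:, :, None] - isj_c[1]) ** 2)
        + ((zz_mm - isj_c[2]) ** 2)
    )
    label[d_isj <= scene.isj_radius_mm**2] = code["is_joint"]

    # --- malleus: lateral-process bump plus a handle running to the umbo
    lp_z = (_interp_tm(scene.lp_uv) + tm_thick) * dz
    lp_p = np.array([scene.lp_uv[0] * ny * dy, scene.lp_uv[1] * nx * dx, lp_z])
    umbo_z = (z_apex + tm_thick + 1) * dz
    umbo_p = np.array([v0 * ny * dy, u0 * nx * dx, umbo_z])
    seg = umbo_p - lp_p
    seg_len2 = float(seg @ seg)
    py = yy[:, :, None] - lp_p[0]
    px = xx[:, :, None] - lp_p[1]
    pz = zz_mm - lp_p[2]
    t = np.clip((py * seg[0] + px * seg[1] + pz * seg[2]) / seg_len2, 0.0, 1.0)
    d_handle = (
        (py - t * seg[0]) ** 2 + (px - t * seg[1]) ** 2 + (pz - t * seg[2]) ** 2
    )
    malleus = d_handle <= scene.handle_radius_mm**2
    d_lp = py**2 + px**2 + (zz_mm - (lp_z - 0.1)) ** 2
    malleus |= d_lp <= scene.lp_radius_mm**2
    label[malleus] = code["malleus"]

    # --- TM painted last so the membrane overrides embedded structures
    in_tm = (zidx >= tm_outer[:, :, None]) & (zidx < tm_inner[:, :, None])
    label[in_tm] = code["tm"]

    # ossicles painted over the mass reclaim their voxels: keep the mask
    # consistent with the final label map
    if scene.mass is not None:
        mass_mask &= label == code["mass"]
        has_mass = mass_mask.any(axis=2)
        mass_top = np.where(has_mass, _mass_top_design.astype(float), np.nan)

    # --- optical property maps
    back = np.zeros((ny, nx, nz), dtype=np.float32)
    atten = np.zeros((ny, nx, nz), dtype=np.float32)
    rho = np.full((ny, nx, nz), scene.rho_static, dtype=np.float32)
    for name, c in code.items():
        region = scene.optics[name]
        sel = label == c
        back[sel] = region.backscatter
        atten[sel] = region.attenuation
    rho[label == code["air"]] = 1.0

    if scene.mass is not None and scene.mass.vascular_fraction > 0:
        rng = np.random.default_rng(scene.seed + 1)  # vessel placement substream
        vascular = mass_mask & (
            rng.random((ny, nx, nz)) < scene.mass.vascular_fraction
        )
        rho[vascular] = scene.mass.rho_vessel

    # landmarks: umbo on the TM apex, lateral process atop its bump
    umbo_ix = (
        int(round(v0 * ny)),
        int(round(u0 * nx)),
        int(round(z_apex)),
    )
    lp_ix = (
        int(round(scene.lp_uv[0] * ny)),
        int(round(scene.lp_uv[1] * nx)),
        int(round(lp_z / dz)),
    )
    clip_ix = lambda ix: tuple(
        int(np.clip(c, 0, n - 1)) for c, n in zip(ix, (ny, nx, nz))
    )

    truth = PhantomTruth(
        label_map=label,
        rho_map=rho,
        landmarks={"umbo": clip_ix(umbo_ix), "malleus_lateral_process": clip_ix(lp_ix)},
        mass_mask=mass_mask,
        tm_inner_surface=tm_inner,
        mass_top_surface=mass_top,
        gap_mm=gap_mm,
        class_preset=scene.class_preset,
    )
    return truth, back, atten


# ---------------------------------------------------------------------------
# image formation


def render_mean_intensity(
    scene: PhantomScene, _rasterized: Optional[tuple] = None
) -> np.ndarray:
    """Expected linear intensity under single-scatter Beer-Lambert optics.

    mu(x, y, z) = backscatter * exp(-2 * sum_{z' < z} attenuation * dz)
                  + noise_floor,

    with the round-trip factor 2 and the cumulative sum exclusive of the
    voxel itself.  Deterministic given the scene.
    """
    truth, back, atten = _rasterized if _rasterized is not None else rasterize(scene)
    dz = scene.pixel_spacing[2]
    cum = np.cumsum(atten, axis=2, dtype=np.float64) - atten  # exclusive prefix sum
    mu = back * np.exp(-2.0 * cum * dz) + scene.noise_floor
    return mu.astype(np.float64)


def sample_speckle_volume(mean_volume: np.ndarray, seed: int) -> np.ndarray:
    """Single-shot fully developed speckle realization of an expected-intensity
    volume.

    Each voxel's field is circular complex Gaussian with variance mu, so
    I = |E|^2 is exponential with mean mu; the intensities are sampled
    directly from that distribution.  Reproducible under a fixed seed.
    """
    mu = np.asarray(mean_volume, dtype=np.float64)
    if np.any(mu < 0):
        raise ValueError("expected intensity must be non-negative")
    rng = np.random.default_rng(seed)
    return rng.exponential(mu)


def sample_repeat_stack(
    mean_bscan: np.ndarray,
    rho_slice: np.ndarray,
    n_repeats: int,
    seed: int,
    noise_floor: float = 0.0,
    slow_index: int = 0,
) -> RepeatStack:
    """Sample N consecutive B-scans of one slow position with AR(1) speckle
    decorrelation.

    ``mean_bscan`` is the signal expected intensity (depth, fast) and
    ``rho_slice`` the per-pixel inter-repeat field correlation.  The signal
    field evolves as E_1 ~ CN(0, mu),
    E_{i+1} = rho E_i + sqrt(1 - rho^2) xi_i with xi_i ~ CN(0, mu), so the
    lag-k field correlation is rho^k and the lag-k intensity correlation
    rho^(2k).  A temporally uncorrelated detection-noise field of expected
    intensity ``noise_floor`` is added per repeat; with noise_floor = 0 and
    rho = 1 all repeats are identical.
    """
    mu = np.asarray(mean_bscan, dtype=np.float64)
    rho = np.asarray(rho_slice, dtype=np.float64)
    if mu.shape != rho.shape:
        raise ValueError(f"mean {mu.shape} and rho {rho.shape} shapes differ")
    if np.any(mu < 0):
        raise ValueError("expected intensity must be non-negative")
    if np.any((rho < 0) | (rho > 1)):
        raise ValueError("rho must lie in [0, 1]")
    if n_repeats < 2:
        raise ValueError("angiography needs n_repeats >= 2")
    if noise_floor < 0:
        raise ValueError("noise floor must be >= 0")
    rng = np.random.default_rng(seed)
    amp = np.sqrt(mu / 2.0)

    def cn(scale: np.ndarray | float) -> np.ndarray:
        return scale * (
            rng.standard_normal(mu.shape) + 1j * rng.standard_normal(mu.shape)
        )

    innov = np.sqrt(1.0 - rho**2)
    noise_amp = np.sqrt(noise_floor / 2.0)
    frames = np.empty((n_repeats,) + mu.shape, dtype=np.float64)
    sig = cn(amp)
    for i in range(n_repeats):
        if i > 0:
            sig = rho * sig + innov * cn(amp)
        total = sig + cn(noise_amp) if noise_floor > 0 else sig
        frames[i] = np.abs(total) ** 2
    return RepeatStack(data=frames, slow_index=slow_index)


# ---------------------------------------------------------------------------
# cohort assembly


def build_ear(
    preset: str,
    seed: int,
    ear_id: str = "",
    grid_shape: tuple[int, int, int] = DEFAULT_GRID,
    n_repeats: int = 4,
    with_stacks: bool = True,
    **scene_overrides,
) -> EarData:
    """Realize one synthetic ear: structural volume, repeat stacks, truth."""
    scene = make_scene(
        preset, seed, grid_shape=grid_shape, n_repeats=n_repeats, **scene_overrides
    )
    rasterized = rasterize(scene)
    truth = rasterized[0]
    mu = render_mean_intensity(scene, _rasterized=rasterized)
    intensity = sample_speckle_volume(mu, seed=seed + 2)
    volume = OCTVolume(
        data=intensity.astype(np.float32),
        pixel_spacing=scene.pixel_spacing,
        meta={
            "preset": preset,
            "seed": seed,
            "axis_order": "slow,fast,depth",
            "n_air": 1.0,
            "n_tissue": 1.4,
        },
    )
    stacks = None
    if with_stacks:
        mu_signal = mu - scene.noise_floor
        stacks = [
            sample_repeat_stack(
                mu_signal[j].T,
                truth.rho_map[j].T,
                n_repeats=n_repeats,
                seed=seed + 10 + j,
                noise_floor=scene.noise_floor,
                slow_index=j,
            )
            for j in range(scene.grid_shape[0])
        ]
    return EarData(
        ear_id=ear_id or f"{preset}_{seed}",
        class_label=preset,
        scene=scene,
        truth=truth,
        volume=volume,
        stacks=stacks,
    )


def cohort_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic independent per-ear seeds derived from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def build_cohort(
    presets: list[tuple[str, int]],
    seed: int,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID,
    n_repeats: int = 4,
    with_stacks: bool = True,
) -> list[EarData]:
    """Build a cohort of synthetic ears, e.g. the default study arms
    [("normal", 6), ("glomus", 6), ("cholesteatoma", 4), ("schwannoma", 1)].

    Per-ear seeds are spawned deterministically from the master seed, so the
    whole cohort is reproducible and each ear is independent.
    """
    for name, count in presets:
        if name not in PRESET_NAMES:
            raise ValueError(f"unknown preset {name!r}")
        if count < 0:
            raise ValueError(f"negative count for preset {name!r}")
    total = sum(count for _, count in presets)
    seeds = cohort_seeds(seed, total)
    ears = []
    k = 0
    for name, count in presets:
        for i in range(count):
            ears.append(
                build_ear(
                    name,
                    seeds[k],
                    ear_id=f"{name}_{i + 1:02d}",
                    grid_shape=grid_shape,
                    n_repeats=n_repeats,
                    with_stacks=with_stacks,
                )
            )
            k += 1
    return ears
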