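"""Speckle-variance OCT angiography.

Flow contrast comes from temporal decorrelation of coherent speckle: static
tissue keeps a stable speckle pattern across consecutive B-scans acquired at
the same slow-axis position, while moving blood decorrelates it.  The
angiogram is the per-pixel variance of linear intensity over the N repeats,

    SV = (1/N) * sum_i (I_i - Ibar)^2,

with population (1/N) normalization by default, computed on linear intensity
(variance of log-compressed display values would conflate mean brightness
with flow).  The sample-variance (1/(N-1)) normalization is available via
``ddof=1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RepeatStack",
    "Angiogram",
    "speckle_variance",
    "assemble_angio_volume",
    "angio_enface",
    "overlay",
]


@dataclass
class RepeatStack:
    """N consecutive B-scans at one slow-axis position.

    ``data`` has shape (n_repeats, depth, fast) in linear intensity units.
    """

    data: np.ndarray
    slow_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"repeat stack must be (n_repeats, depth, fast), got shape {self.data.shape}"
            )
        if self.data.shape[0] < 2:
            raise ValueError(
                f"speckle variance needs at least 2 repeats, got {self.data.shape[0]}"
            )

    @property
    def n_repeats(self) -> int:
        return self.data.shape[0]


@dataclass
class Angiogram:
    """Per-pixel speckle variance (intensity^2 units), single B-scan or volume.

    A per-position angiogram has ``sv`` of shape (depth, fast); an assembled
    volume has (slow, fast, depth), matching the structural volume layout.
    """

    sv: np.ndarray
    n_repeats: int
    slow_index: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sv = np.asarray(self.sv)
        if np.any(self.sv < 0):
            raise ValueError("speckle variance must be non-negative")


def speckle_variance(stack: RepeatStack, ddof: int = 0) -> Angiogram:
    """Per-pixel variance of intensity across the repeats of one stack."""
    if ddof not in (0, 1):
        raise ValueError("ddof must be 0 (population, default) or 1")
    sv = stack.data.astype(float).var(axis=0, ddof=ddof)
    # identical repeats give exactly zero (mean rounding can leave ~1e-33)
    sv[(stack.data == stack.data[0]).all(axis=0)] = 0.0
    return Angiogram(
        sv=sv, n_repeats=stack.n_repeats, slow_index=stack.slow_index,
        meta={"ddof": ddof},
    )


def assemble_angio_volume(angiograms: list[Angiogram]) -> Angiogram:
    """Concatenate per-position angiograms into an SV volume (slow, fast, depth).

    The inputs must cover contiguous, strictly increasing slow-axis
    positions; gaps, duplicates, or shuffled order are rejected so the
    assembled volume aligns voxel-for-voxel with the structural volume.
    """
    if not angiograms:
        raise ValueError("no angiograms to assemble")
    idx = [a.slow_index for a in angiograms]
    if any(i is None for i in idx):
        raise ValueError("angiograms must carry slow indices for assembly")
    expected = list(range(idx[0], idx[0] + len(idx)))
    if idx != expected:
        raise ValueError(
            f"slow indices must be contiguous and increasing, got {idx}"
        )
    n_rep = {a.n_repeats for a in angiograms}
    if len(n_rep) != 1:
        raise ValueError(f"inconsistent n_repeats among stacks: {sorted(n_rep)}")
    shapes = {a.sv.shape for a in angiograms}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent B-scan shapes among stacks: {sorted(shapes)}")
    # per-position sv is (depth, fast); volume layout is (slow, fast, depth)
    vol = np.stack([a.sv.T for a in angiograms], axis=0)
    return Angiogram(
        sv=vol, n_repeats=n_rep.pop(), slow_index=None,
        meta={"slow_start": idx[0], "n_positions": len(idx)},
    )


def angio_enface(angio_volume: Angiogram, z_lo: int, z_hi: int, mode: str = "mean") -> np.ndarray:
    """En-face projection of an SV volume over the depth window [z_lo, z_hi).

    Mean projection by default; ``mode="max"`` gives a maximum-intensity
    projection of the SV signal instead.
    """
    sv = angio_volume.sv
    if sv.ndim != 3:
        raise ValueError("en-face projection needs an assembled SV volume")
    nz = sv.shape[2]
    if not (0 <= z_lo < z_hi <= nz):
        raise ValueError(f"invalid depth window [{z_lo}, {z_hi}) for depth {nz}")
    window = sv[:, :, z_lo:z_hi]
    if mode == "mean":
        return window.mean(axis=2)
    if mode == "max":
        return window.max(axis=2)
    raise ValueError(f"unknown projection mode {mode!r}")


def overlay(
    enface_structural: np.ndarray,
    enface_angio: np.ndarray,
    threshold: float,
) -> tuple[np.ndarray, dict]:
    """Red angiography overlay on a grayscale structural en-face image.

    Pixels whose SV exceeds ``threshold`` are tinted red with strength
    proportional to SV above threshold (saturating at the map maximum);
    everything else stays grayscale.  Returns the uint8 RGB image and
    metadata recording the threshold used.
    """
    base = np.asarray(enface_structural, dtype=float)
    sv = np.asarray(enface_angio, dtype=float)
    if base.shape != sv.shape:
        raise ValueError(
            f"structural {base.shape} and angio {sv.shape} en-face shapes differ"
        )
    lo, hi = base.min(), base.max()
    gray = (base - lo) / (hi - lo) if hi > lo else np.zeros_like(base)
    rgb = np.repeat(gray[:, :, None], 3, axis=2)
    mask = sv > threshold
    if mask.any():
        sv_max = sv[mask].max()
        span = sv_max - threshold
        strength = (sv[mask] - threshold) / span if span > 0 else np.ones(mask.sum())
        rgb[mask, 0] = np.maximum(rgb[mask, 0], strength)
        rgb[mask, 1] *= 1.0 - strength
        rgb[mask, 2] *= 1.0 - strength
    out = np.floor(rgb * 255.0 + 0.5).astype(np.uint8)
    return out, {"threshold": float(threshold), "n_tinted": int(mask.sum())}
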