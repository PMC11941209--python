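"""End-to-end analysis of synthetic cohorts.

Ties the stages together per ear: realize the phantom, render the 8-bit
display, extract umbo-referenced cross-sections, compute the
speckle-variance volume from the repeat stacks, place the ROI boxes from
the phantom's ground-truth landmarks, and emit tidy per-ear ratio rows
ready for group statistics.

ROI box sizes follow the clinical convention (100 x 100 pixel mass box and
50 x 50 pixel malleus box on the angiography en-face map; 100 x 100 mass
and 50 x 20 TM boxes on the structural cross-section) scaled proportionally
from the clinical grid (417 slow x 1280 fast x 2048 depth) to the synthetic
grid; the scaling is recorded in each row's provenance.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import stats as mstats
from .angio import Angiogram, angio_enface, assemble_angio_volume, overlay, speckle_variance
from .phantom import EarData, REGION_LABELS, build_ear, cohort_seeds
from .quantify import (
    Landmark,
    RoiBox,
    extract_cross_sections,
    render_display,
    roi_mean,
    structural_ratio,
    angio_ratio,
    tumor_tm_gap,
)

__all__ = [
    "DEFAULT_COHORT",
    "CLINICAL_GRID",
    "sv_volume_from_stacks",
    "roi_plan_from_truth",
    "analyze_ear",
    "analyze_cohort",
    "group_summaries",
    "run_report",
]

DEFAULT_COHORT = [("normal", 6), ("glomus", 6), ("cholesteatoma", 4), ("schwannoma", 1)]
CLINICAL_GRID = (417, 1280, 2048)  # (slow, fast, depth) of the clinical angio volume
DISPLAY_DR_DB = 30.0


def _scaled(n_clinical: int, n_here: int, n_ref: int, minimum: int = 3) -> int:
    return max(minimum, int(round(n_clinical * n_here / n_ref)))


def _clamp_box(row: int, col: int, h: int, w: int, shape: tuple[int, int],
               plane_id: str) -> RoiBox:
    row = int(np.clip(row, 0, shape[0] - h))
    col = int(np.clip(col, 0, shape[1] - w))
    return RoiBox(row=row, col=col, height=h, width=w, plane_id=plane_id)


def _promontory_surface(label_map: np.ndarray) -> np.ndarray:
    """First depth index of promontory bone per (slow, fast) column."""
    is_prom = label_map == REGION_LABELS["promontory"]
    surf = np.argmax(is_prom, axis=2)
    surf[~is_prom.any(axis=2)] = label_map.shape[2] - 1
    return surf


def sv_volume_from_stacks(ear: EarData, ddof: int = 0) -> Angiogram:
    """Speckle-variance volume assembled from an ear's repeat stacks."""
    if ear.stacks is None:
        raise ValueError(f"ear {ear.ear_id!r} carries no repeat stacks")
    return assemble_angio_volume([speckle_variance(s, ddof=ddof) for s in ear.stacks])


def roi_plan_from_truth(ear: EarData) -> dict:
    """Derive the ROI/landmark plan for one ear from phantom ground truth.

    Mirrors the manual clinical placement: the structural mass box sits over
    the mass seen in the umbo cross-section (for normal ears, over the
    aerated mesotympanum at a comparable depth), the TM box on the membrane
    in the same image; the angio mass box sits over the mass footprint on
    the en-face map (normal ears: mesotympanum), the reference box over the
    malleus lateral process.
    """
    ny, nx, nz = ear.scene.grid_shape
    dz = ear.scene.pixel_spacing[2]
    truth = ear.truth
    umbo = truth.landmarks["umbo"]
    lp = truth.landmarks["malleus_lateral_process"]
    tm_thick = max(2, int(round(ear.scene.tm_thickness_mm / dz)))
    tm_inner = truth.tm_inner_surface
    prom = _promontory_surface(truth.label_map)

    # --- structural boxes on the XZ display image (rows = depth, cols = fast)
    h_mass = _scaled(100, nz, CLINICAL_GRID[2], 4)
    w_mass = _scaled(100, nx, CLINICAL_GRID[1], 4)
    w_tm = _scaled(20, nx, CLINICAL_GRID[1], 3)
    tm_col = int(np.clip(umbo[1] + round(0.12 * nx), 0, nx - w_tm))
    tm_row = int(tm_inner[umbo[0], tm_col]) - tm_thick
    tm_box = _clamp_box(tm_row, tm_col, tm_thick, w_tm, (nz, nx), "xz_display")

    slice_mass = truth.mass_mask[umbo[0]]  # (fast, depth)
    if slice_mass.any():
        # box over the visible upper part of the mass: deeper mass voxels are
        # shadowed by the mass's own attenuation, as in the clinical images
        cols, depths = np.nonzero(slice_mass)
        c_col = int(cols[np.argmin(np.abs(cols - cols.mean()))])  # nearest populated column
        top = int(depths[cols == c_col].min())
        c_row = top + h_mass // 2 + 1
    else:
        # normal ear (or mass missing the umbo plane): aerated anterior
        # mesotympanum at mass-comparable depth, clear of the ossicles
        c_col = int(np.clip(umbo[1] - round(0.12 * nx), 0, nx - 1))
        c_row = int((tm_inner[umbo[0], c_col] + prom[umbo[0], c_col]) // 2)
    row = max(c_row - h_mass // 2, tm_box.row + tm_box.height)  # keep below the TM box
    mass_box = _clamp_box(row, c_col - w_mass // 2, h_mass, w_mass, (nz, nx), "xz_display")

    # --- angio boxes on the en-face SV map (rows = slow, cols = fast)
    h_a = _scaled(100, ny, CLINICAL_GRID[0], 4)
    w_a = _scaled(100, nx, CLINICAL_GRID[1], 4)
    h_r = _scaled(50, ny, CLINICAL_GRID[0], 3)
    w_r = _scaled(50, nx, CLINICAL_GRID[1], 3)
    ref_box = _clamp_box(lp[0] - h_r // 2, lp[1] - w_r // 2, h_r, w_r, (ny, nx), "enface_sv")
    footprint = truth.mass_mask.any(axis=2)
    if footprint.any():
        rows, cols = np.nonzero(footprint)
        a_row, a_col = int(rows.mean()), int(cols.mean())
    else:
        a_row = umbo[0] + int(round(0.20 * ny))
        a_col = umbo[1] - int(round(0.05 * nx))
    angio_box = _clamp_box(a_row - h_a // 2, a_col - w_a // 2, h_a, w_a, (ny, nx), "enface_sv")
    while angio_box.overlaps(ref_box) and angio_box.col + angio_box.width < nx:
        angio_box = _clamp_box(
            angio_box.row, angio_box.col + 1, h_a, w_a, (ny, nx), "enface_sv"
        )

    # en-face depth window: TM stratum down to just above the promontory
    z_lo = max(0, int(tm_inner.min()) - tm_thick - 2)
    z_hi = max(z_lo + 2, int(prom.min()) - 2)
    return {
        "structural": {"mass_box": mass_box, "tm_box": tm_box},
        "angio": {"mass_box": angio_box, "malleus_box": ref_box,
                  "z_lo": z_lo, "z_hi": z_hi},
        "scaling": {
            "clinical_grid": list(CLINICAL_GRID),
            "grid": [ny, nx, nz],
            "angio_mass_box_px": [h_a, w_a],
            "angio_malleus_box_px": [h_r, w_r],
            "structural_mass_box_px": [h_mass, w_mass],
        },
    }


def analyze_ear(
    ear: EarData,
    plan: Optional[dict] = None,
    dynamic_range_db: float = DISPLAY_DR_DB,
    image_dir: Optional[Path] = None,
) -> dict:
    """Quantify one ear: structural and angio ratios plus the tumor-TM gap.

    Returns a tidy row.  With ``image_dir`` set, also writes the display
    cross-sections, structural en-face, and angiography overlay as PNG.
    """
    if plan is None:
        plan = roi_plan_from_truth(ear)
    umbo = Landmark("umbo", ear.truth.landmarks["umbo"])
    xs = extract_cross_sections(ear.volume, umbo)
    xz_display = render_display(xs.xz, dynamic_range_db)
    sres = structural_ratio(
        xz_display, plan["structural"]["mass_box"], plan["structural"]["tm_box"],
        ear_id=ear.ear_id, class_label=ear.class_label,
    )
    # linear-domain companion ratio (same boxes, un-compressed intensities)
    lin_num = roi_mean(xs.xz, plan["structural"]["mass_box"])
    lin_den = roi_mean(xs.xz, plan["structural"]["tm_box"])

    sv_vol = sv_volume_from_stacks(ear)
    a = plan["angio"]
    enface_sv = angio_enface(sv_vol, a["z_lo"], a["z_hi"])
    ares = angio_ratio(
        enface_sv, a["mass_box"], a["malleus_box"],
        ear_id=ear.ear_id, class_label=ear.class_label,
    )

    gap_min = gap_max = gap_designed = float("nan")
    if ear.truth.gap_mm is not None and np.isfinite(ear.truth.mass_top_surface).any():
        gap = tumor_tm_gap(
            ear.truth.tm_inner_surface.astype(float),
            ear.truth.mass_top_surface,
            z_spacing_mm=ear.scene.pixel_spacing[2],
        )
        gap_min, gap_max, gap_designed = gap.min_mm, gap.max_mm, ear.truth.gap_mm

    if image_dir is not None:
        _write_images(ear, xs, xz_display, sv_vol, enface_sv, plan, Path(image_dir))

    return {
        "ear_id": ear.ear_id,
        "class_label": ear.class_label,
        "structural_ratio": sres.ratio,
        "structural_num": sres.numerator_mean,
        "structural_den": sres.denominator_mean,
        "structural_ratio_linear": lin_num / lin_den,
        "angio_ratio": ares.ratio,
        "angio_num": ares.numerator_mean,
        "angio_den": ares.denominator_mean,
        "gap_designed_mm": gap_designed,
        "gap_min_mm": gap_min,
        "gap_max_mm": gap_max,
        "seed": ear.scene.seed,
        "roi_provenance": json.dumps(_plan_as_jsonable(plan), sort_keys=True),
    }


def _plan_as_jsonable(plan: dict) -> dict:
    def conv(obj):
        if isinstance(obj, RoiBox):
            return {"row": obj.row, "col": obj.col,
                    "height": obj.height, "width": obj.width, "plane": obj.plane_id}
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items()}
        return obj

    return conv(plan)


def _write_images(ear, xs, xz_display, sv_vol, enface_sv, plan, image_dir: Path) -> None:
    import imageio.v3 as iio

    from .quantify import enface_projection

    image_dir.mkdir(parents=True, exist_ok=True)
    stem = ear.ear_id
    iio.imwrite(image_dir / f"{stem}_xz.png", xz_display)
    iio.imwrite(
        image_dir / f"{stem}_yz.png", render_display(xs.yz, DISPLAY_DR_DB)
    )
    tm_mid = int(ear.truth.tm_inner_surface.mean())
    half = max(1, _scaled(45, ear.scene.grid_shape[2], CLINICAL_GRID[2], 2) // 2)
    z_lo = max(0, tm_mid - half)
    z_hi = min(ear.scene.grid_shape[2], tm_mid + half)
    enface_struct = enface_projection(ear.volume, z_lo, z_hi)
    iio.imwrite(
        image_dir / f"{stem}_enface.png", render_display(enface_struct, DISPLAY_DR_DB)
    )
    # overlay threshold: 95th percentile of SV over mass-free columns
    footprint = ear.truth.mass_mask.any(axis=2)
    static_vals = enface_sv[~footprint] if (~footprint).any() else enface_sv.ravel()
    thr = float(np.percentile(static_vals, 95.0))
    rgb, meta = overlay(enface_struct, enface_sv, thr)
    iio.imwrite(image_dir / f"{stem}_overlay.png", rgb)
    (image_dir / f"{stem}_overlay.json").write_text(json.dumps(meta, indent=2))


def analyze_cohort(
    presets: list[tuple[str, int]] = DEFAULT_COHORT,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (64, 256, 512),
    n_repeats: int = 4,
    image_dir: Optional[Path] = None,
    image_classes: Optional[set[str]] = None,
    on_error: str = "raise",
) -> pd.DataFrame:
    """Build and quantify a cohort ear-by-ear (streaming, bounded memory).

    Equivalent to quantifying ``phantom.build_cohort`` output, but each ear's
    volume and repeat stacks are released once its row is computed.  With
    ``on_error="isolate"`` a failing ear is recorded and the run continues.
    """
    total = sum(c for _, c in presets)
    seeds = cohort_seeds(seed, total)
    rows = []
    imaged: set[str] = set()
    k = 0
    for name, count in presets:
        for i in range(count):
            ear_id = f"{name}_{i + 1:02d}"
            try:
                ear = build_ear(
                    name, seeds[k], ear_id=ear_id,
                    grid_shape=grid_shape, n_repeats=n_repeats,
                )
                want_image = (
                    image_dir is not None
                    and (image_classes is None or name in image_classes)
                    and name not in imaged
                )
                row = analyze_ear(ear, image_dir=image_dir if want_image else None)
                if want_image:
                    imaged.add(name)
                rows.append(row)
            except Exception as exc:  # noqa: BLE001 - per-ear isolation is the contract
                if on_error != "isolate":
                    raise
                rows.append({"ear_id": ear_id, "class_label": name, "error": str(exc)})
            k += 1
    return pd.DataFrame(rows)


def group_summaries(ratios: pd.DataFrame, value_col: str) -> list[mstats.GroupSummary]:
    return [
        mstats.summarize(sub[value_col].dropna().to_numpy(), label=str(name))
        for name, sub in ratios.groupby("class_label", sort=True)
        if sub[value_col].notna().any()
    ]


def run_report(
    out_dir: str | Path,
    presets: list[tuple[str, int]] = DEFAULT_COHORT,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (64, 256, 512),
    n_repeats: int = 4,
    variant: str = "pooled",
    save_images: bool = True,
) -> dict:
    """Run the full simulate -> angiography -> quantify -> statistics pipeline.

    Writes per-ear ratios (CSV), group summaries (CSV), pairwise tests for
    the structural and angiography ratios (CSV), representative images (PNG,
    one ear per class), a markdown summary, and a manifest with output
    digests.
    """
    from . import __version__
    from .io import RunManifest

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    image_dir = out / "images" if save_images else None
    ratios = analyze_cohort(
        presets, seed=seed, grid_shape=grid_shape, n_repeats=n_repeats,
        image_dir=image_dir, on_error="isolate",
    )
    config = {
        "presets": presets, "seed": seed, "grid_shape": list(grid_shape),
        "n_repeats": n_repeats, "variant": variant,
        "display_dynamic_range_db": DISPLAY_DR_DB,
    }
    manifest = RunManifest(
        tool="meoct", version=__version__, master_seed=seed,
        config_hash=__import__("hashlib").sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
    )
    ratios_path = out / "ratios.csv"
    ratios.to_csv(ratios_path, index=False, float_format="%.10g")
    manifest.record(ratios_path)

    ok = ratios[~ratios.get("error", pd.Series(dtype=object)).notna()] \
        if "error" in ratios.columns else ratios
    failed = len(ratios) - len(ok)
    if failed:
        manifest.warnings.append(f"{failed} ear(s) failed and were isolated")

    tests = {}
    summaries_rows = []
    for kind, col in (("structural", "structural_ratio"), ("angio", "angio_ratio")):
        if col not in ok.columns or not ok[col].notna().any():
            continue
        summaries = group_summaries(ok, col)
        summaries_rows += [
            {"kind": kind, "class_label": s.label, "n": s.n, "mean": s.mean,
             "se": s.se, "se_defined": s.se_defined}
            for s in summaries
        ]
        table = mstats.compare_all_from_summaries(summaries, variant=variant)
        path = out / f"tests_{kind}.csv"
        table.to_csv(path, index=False, float_format="%.10g")
        manifest.record(path)
        tests[kind] = table
    summaries_df = pd.DataFrame(summaries_rows)
    summaries_path = out / "group_summaries.csv"
    summaries_df.to_csv(summaries_path, index=False, float_format="%.10g")
    manifest.record(summaries_path)

    report_md = _report_markdown(config, summaries_df, tests, failed)
    report_path = out / "report.md"
    report_path.write_text(report_md)
    manifest.record(report_path)
    manifest.write(out / "manifest.json")
    return {"ratios": ratios, "summaries": summaries_df, "tests": tests,
            "out_dir": out}


def _report_markdown(config, summaries_df, tests, failed) -> str:
    lines = [
        "# Synthetic middle-ear OCT cohort report",
        "",
        f"Master seed: {config['seed']}; grid {config['grid_shape']}; "
        f"{config['n_repeats']} repeats per position; "
        f"{config['variant']} t-test.",
        "",
        "## Group summaries (mean ± SE)",
        "",
    ]
    for _, r in summaries_df.iterrows():
        se_txt = f" ± {r['se']:.3f}" if r["se_defined"] else " (n = 1, no SE)"
        lines.append(
            f"- {r['kind']} / {r['class_label']}: {r['mean']:.3f}{se_txt} (n = {r['n']})"
        )
    for kind, table in tests.items():
        lines += ["", f"## Pairwise {kind} t-tests "
                      f"({int(table['n_comparisons'].iloc[0]) if len(table) else 0} "
                      "comparisons, uncorrected)", ""]
        for _, r in table.iterrows():
            flag = "significant" if r["significant"] else "ns"
            lines.append(
                f"- {r['group_a']} vs {r['group_b']}: t = {r['t']:.3f}, "
                f"df = {r['df']:.0f}, p = {r['p']:.4g} ({flag})"
            )
    if failed:
        lines += ["", f"**Warning**: {failed} ear(s) failed and were excluded."]
    return "\n".join(lines) + "\n"
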