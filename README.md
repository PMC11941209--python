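# meoct — middle-ear OCT quantification on synthetic phantoms

Masses behind an intact tympanic membrane (TM) — highly vascular glomus
tumors, avascular cholesteatomas, facial nerve schwannomas — are hard to
tell apart at otoscopy. Handheld optical coherence tomography (OCT) can
image through the TM into the middle-ear space, and speckle-variance OCT
angiography can grade the vascularity of whatever sits behind it. `meoct`
implements that analysis workflow as a tested, reusable Python library:

- **Phantom generation** — synthetic middle-ear OCT volumes with a curved
  TM, malleus (umbo and lateral process), incudostapedial joint, cochlear
  promontory, optional soft-tissue masses with Beer–Lambert attenuation and
  shadowing, fully developed (exponential-intensity) speckle, and per-voxel
  AR(1) temporal decorrelation in perfused tissue. Every phantom carries a
  voxel-level label map, flow-correlation map, landmarks, and a designed
  tumor-to-TM gap as ground truth.
- **Angiography** — per-pixel speckle variance over N consecutive B-scans
  at the same slow-axis position, `SV = (1/N) Σᵢ (Iᵢ − Ī)²`, computed on
  linear intensity; volume assembly, en-face projections, red-overlay
  rendering.
- **Quantification** — umbo-referenced cross-sections, 8-bit log-compressed
  display rendering, mean ROI intensity ratios (mass box normalized to a
  TM box structurally, to a malleus-lateral-process box on angiography),
  optical-path-to-physical-depth conversion (n = 1.0 air, n = 1.4 tissue)
  with refractive-index uncertainty bounds, and per-A-line tumor-to-TM gap
  measurement.
- **Statistics** — group summaries (mean ± SE), unpaired Student's t-tests
  (pooled by default, Welch by flag) computed either from raw per-ear
  ratios or reconstructed exactly from printed (n, mean, SE) summaries via
  s² = SE²·n, and pairwise comparison tables at α = 0.05.

Because clinical volumes of this kind are not publicly deposited, the
phantom module is first-class: the shipped 17-ear cohort (6 normal,
6 glomus, 4 cholesteatoma, 1 schwannoma) reproduces the qualitative
structure of the clinical findings — masses separate from normals on
structural ratios, glomus separates from everything avascular on
angiography, the schwannoma falls in between.

## Worked example

```python
from meoct import GroupSummary, ttest_from_summary

glomus = GroupSummary("glomus", 6, 0.620, 0.095)          # n, mean, SE
chol = GroupSummary("cholesteatoma", 4, 0.558, 0.153)
res = ttest_from_summary(glomus, chol)                     # pooled Student's t
print(f"t = {res.t:.3f}, df = {res.df:.0f}, p = {res.p:.4g}")

import meoct

ear = meoct.build_ear("glomus", seed=7, grid_shape=(24, 96, 256))
row = meoct.analyze_ear(ear)
print(f"structural ratio {row['structural_ratio']:.3f}, "
      f"angio ratio {row['angio_ratio']:.3f}")
print(f"designed gap {row['gap_designed_mm']:.3f} mm, "
      f"measured max gap {row['gap_max_mm']:.3f} mm")
```

prints

```
t = 0.366, df = 8, p = 0.724
structural ratio 0.426, angio ratio 1.185
designed gap 0.061 mm, measured max gap 0.060 mm
```

The first line reconstructs a two-sample test purely from per-group
summary statistics: structurally, a glomus tumor and a cholesteatoma are
indistinguishable (p ≈ 0.72) — both are simply soft tissue where a normal
ear has air. The second block simulates one glomus ear, measures its
mass/TM display-intensity ratio (0.43, an order of magnitude above the
normal-ear regime of ~0.1), its angiography ratio over the malleus
reference (>1, reflecting the vascular mass), and recovers the designed
tumor-to-TM air gap to within one axial pixel (0.02 mm).

The same pipeline is scriptable from the shell:

```sh
meoct simulate --preset glomus --seed 7 --shape 24,96,256 --out ear/
meoct angio --in ear/ --out sv/
meoct report --seed 1 --out report/        # full 17-ear cohort end-to-end
```

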