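# Methods

## Image-formation model

Volumes use axis order (slow y, fast x, depth z); z is optical path, in mm,
increasing away from the probe. Expected intensity follows single-scatter
Beer–Lambert optics per A-line:

    μ(x, y, z) = b(x, y, z) · exp(−2 Σ_{z' < z} a(x, y, z') Δz) + μ₀,

where `b` is a relative backscatter coefficient, `a` a per-mm intensity
attenuation coefficient (the factor 2 accounts for the round trip), and
`μ₀` an additive detection-noise floor. The cumulative sum is exclusive of
the voxel itself. This ignores multiple scattering, the confocal/roll-off
profile, and refraction at interfaces; it reproduces the one property the
analysis depends on — soft tissue in the beam path darkens everything
beyond it (shadowing of the cochlear promontory under a mass).

Coherent speckle is fully developed: each voxel's field is a zero-mean
circular complex Gaussian with variance μ, so single-shot intensity is
exponentially distributed with mean μ (intensity SD equals the mean —
speckle is multiplicative). Structural volumes are sampled directly from
that exponential law.

## Temporal model for angiography

Across N consecutive B-scans at one slow position, the signal field
follows a first-order autoregressive process per pixel:

    E₁ ~ CN(0, μ),   E_{i+1} = ρ E_i + √(1 − ρ²) ξ_i,   ξ_i ~ CN(0, μ),

giving lag-k field correlation ρᵏ and, by the complex-Gaussian moment
theorem, lag-k intensity correlation ρ²ᵏ. Static tissue has ρ = 1, flowing
blood low ρ (0.2 in the glomus vessels). On top of the signal field each
repeat receives an independent noise field of expected intensity μ₀; this
temporally white component is what gives bright *static* structures a
small baseline speckle variance (≈ 2μμ₀ per pixel for μ ≫ μ₀), which is
the physical basis for normalizing angiography by the malleus lateral
process. With μ₀ = 0 and ρ = 1 all repeats are bit-identical.

The number of repeats defaults to N = 4 (common speckle-variance practice;
configurable). Speckle variance uses population normalization
SV = (1/N) Σ (Iᵢ − Ī)², the classic speckle-variance formulation; the
(N−1) form is available via `ddof=1`. SV is computed on linear intensity —
variance of log-compressed values would conflate brightness with flow.
Pixels whose repeats are exactly identical are set to exactly zero
(floating-point mean rounding can otherwise leave ~1e−33 residues).

## Phantom anatomy and presets

The scene is parametric: a TM surface (shallow rim with a Gaussian
indentation pulled to its apex at the umbo, thickness 0.12 mm), a malleus
modeled as a lateral-process sphere (0.45 mm) plus a handle cylinder
(0.30 mm radius) running to the umbo, an incudostapedial-joint ellipsoid,
and a promontory wall bulging slightly toward the probe. Masses occupy an
elliptical footprint, conform to the TM inner surface at a uniform
designed air gap (so the designed gap is the per-A-line gap everywhere in
the footprint), taper toward the edge, and are capped by the promontory.
Paint order air → promontory → mass → joint → malleus → TM guarantees one
label per voxel.

Default optical properties (relative backscatter, attenuation /mm):
TM (1.0, 0.8), malleus and joint (1.5/1.3, 2.0), promontory (1.2, 2.0),
mass (0.45, 1.5), air (0, 0); noise floor μ₀ = 0.01 (−20 dB of TM
backscatter). The floor level was set so the normal preset's structural
ratio lands in the ~0.1 regime reported for normal ears with this type of
measurement, i.e. the aerated mesotympanum reads near — but measurably
above — the display floor.

Class presets encode the diagnostic contrasts:

| preset        | mass | gap (mm)   | vascular fraction | ρ_vessel |
|---------------|------|------------|-------------------|----------|
| normal        | none | —          | —                 | —        |
| glomus        | deep, reaches promontory | U(0, 0.2) | 0.45–0.55 | 0.2 |
| cholesteatoma | attached to TM, posterior–superior | 0 | 0 | — |
| schwannoma    | posterior mesotympanum | U(0, 0.1) | 0.12–0.18 | 0.35 |

Per-ear geometry (umbo position, TM depths, mass center/size, vascular
fraction, gap) is jittered from the ear's seed, so cohort members differ
anatomically as patients do. Vascular fractions were chosen so the en-face
angiography ratios fall in the clinically reported regimes (glomus ≈ 2,
cholesteatoma below 1, schwannoma intermediate) while preserving the
orderings the analysis asserts; the glomus gap range matches the 0–0.2 mm
clinically observed spacing.

The default grid is 64 × 256 × 512 (slow × fast × depth) at
(0.04, 0.10, 0.02) mm spacing — a desk-scale stand-in for the clinical
417 × 1280 × 2048 acquisition; the full size is accepted via
configuration. Tests use smaller grids (down to 12 × 48 × 128) where the
property under test does not depend on resolution.

### What the phantoms do not emulate

No multiple scattering, no confocal gating, no bulk-motion artifacts (the
clinical workflow also applied no motion correction; a global-shift
injector could be added for robustness studies), no real vessel trees
(perfused voxels are a Bernoulli draw inside the mass, not tubes), no
chorda tympani, scutum, or ossicular detail beyond the malleus and joint,
and no inter-device variation in dynamic range or focus. Passing tests
therefore demonstrate that the *pipeline* measures what it claims on data
with known truth — not that the presets predict clinical ratio values.

## Quantification

Cross-sections are extracted at the umbo (XZ at its slow index, YZ at its
fast index), matching the clinical landmarking convention. Display
rendering is 8-bit log compression over a 30 dB window:
`clip(10·log₁₀(I/I_max) + DR, 0, DR)·255/DR`, rounded half-up so repeated
rendering is bit-stable. Structural ratios are measured on the display
image (the clinical measurements were made on rendered images in Fiji);
linear-domain ratios are emitted alongside for comparison.

ROI boxes follow the clinical sizes — 100 × 100 (mass) and 50 × 50
(malleus lateral process) pixels on the angiography en-face map, 100 × 100
mass and 50 × 20 TM boxes on the structural cross-section — scaled
proportionally to the synthetic grid and recorded in each row's
provenance. For phantoms the boxes are placed from ground truth: the
structural mass box under the mass's upper surface at the umbo plane (the
deeper mass is self-shadowed, as clinically), the TM box on the membrane
0.12·nx lateral of the umbo, and, for normal ears, the "mass" box in the
aerated anterior mesotympanum midway between TM and promontory — anterior
to avoid the incudostapedial joint, at a depth comparable to where masses
sit. The angiography en-face window spans the TM stratum down to just
above the promontory, excluding promontory bone whose baseline variance
would otherwise contaminate the mesotympanum reading. Landmarks for real
(non-phantom) volumes are supplied via YAML configuration; no automatic
umbo detector is claimed.

Depth measurements convert optical path to physical distance by dividing
by the refractive index: 1.0 in air (tumor–TM gaps cross air, so the
conversion is an identity), 1.4 assumed in soft tissue. Since soft-tissue
indices span roughly 1.33–1.45, converting with 1.4 carries a relative
depth error of n_assumed/n − 1, bounded at the range endpoints (+5.3 % /
−3.4 %); the bounds accompany any through-tissue measurement.

## Statistics

Groups are summarized as mean ± SE (SE = sample SD/√n, n−1 denominator);
singleton groups are reported without an SE. The two-sample test is the
unpaired Student's t; the pooled (equal-variance) variant is the default
because it exactly reproduces, from the printed per-group summaries, the
p-values printed in the clinical source (0.72 structural glomus vs
cholesteatoma; 0.67 angiographic cholesteatoma vs normal) — consistent
with a spreadsheet "unpaired Student's t-test" — with Welch available by
flag. From-summary tests reconstruct the sample variance exactly via
s² = SE²·n, so they agree with from-sample tests to 1e−10. All p-values
are two-tailed; no multiple-testing correction is applied (none was
applied clinically), and comparison tables carry the number of
comparisons. Pairwise testing excludes n = 1 groups, which appear
descriptively only.

## Numerical and interface choices

- All randomness flows from per-ear seeds spawned deterministically from
  one master seed (`numpy.random.SeedSequence`); identical seeds reproduce
  volumes bit-for-bit.
- Volumes interchange as multi-page TIFF (one page per slow position,
  pages laid out depth × fast) with a JSON sidecar for spacing, axis
  order, refractive indices, and intensity scale. Float volumes are
  quantized to uint16 with the scale recorded; uint16 round-trips
  losslessly. Speckle-variance volumes are float32 TIFF.
- Gap measurement flags A-lines where the mass surface sits above the TM
  inner surface (a segmentation inconsistency), excludes them from the
  min/max summary, and reports their count.
- The en-face projection is a mean over the depth window by default, with
  max projection by flag; which projection produced the published overlays
  is unknowable from the source, and no claim is made.
- Degenerate inputs are rejected loudly: fewer than 2 repeats, inverted or
  empty depth windows, out-of-bounds or overlapping ROI boxes, zero
  reference means, zero-variance t-tests, non-contiguous slow indices at
  assembly.

## Problem sizes and runtime

The shipped cohort analysis (17 ears at 64 × 256 × 512, 4 repeats per
position) runs in roughly a minute and a half on one CPU; Monte-Carlo
checks use ≥ 10⁵ pixels for distributional properties (lag-1 correlation
within ±0.05 of ρ²) and 400 replicates for the empirical test size. Gap
recovery uses 20 phantoms on a reduced 8 × 48 × 256 grid, which preserves
axial resolution (the only dimension the measurement depends on).

## Known limitations

Preset calibration to clinical ratio regimes is approximate by
construction — acquisition parameters (power, dynamic range, windowing) of
the clinical rendering are not published. The schwannoma arm has n = 1, as
clinically, so it contributes no variance information. The AR(1) flow
model is the simplest process with a tunable, analytically checkable
correlation; it does not model pulsatility, vessel orientation, or
fringe washout. Structural ratios depend on the display dynamic-range
window (30 dB default); comparisons across windows are not meaningful.
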