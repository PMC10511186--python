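# Methods

## Problem and approach

Unintentional finger ridge impressions (fingermarks) and tool strokes
survive on fired clay objects. Measured crease breadth — the spacing of
one ridge–furrow cycle — correlates strongly with the maker's age up to
about 22 years, so a breadth measured on a sculpture, corrected for the
clay's firing shrinkage, places the maker in a coarse age group. The
package implements the full quantitative chain for volumetric scans of
such surfaces:

1. **Segmentation** (`volume`): each grayscale slice of a reconstructed
   volume is binarized with Otsu's criterion (clay and mineral grains
   bright, air dark), small spurious islands of either phase are removed,
   borders smoothed morphologically, and the material/air interface is
   triangulated by marching cubes into a surface mesh in mm.
2. **Relief enhancement** (`relief`): the cropped impression is treated
   as high-frequency relief riding on the object's low-frequency shape.
   A full bivariate polynomial of degree 5 in each variable (36 terms) is
   fitted by least squares in a local frame and subtracted; the residual
   carries the crease signal. Because an impression is the reverse cast
   of the skin or tool that made it, the residual is negated before
   analysis.
3. **Breadth measurement** (`breadth`): a straight transect across the
   ridge bundle is intersected with the residual relief using the
   Möller–Trumbore ray–triangle algorithm. Crossings of the baseline
   mark crease boundaries; the ridge count is half the number of
   crossings. Kamp breadth = span of complete ridge–furrow pairs divided
   by the number of pairs; Penrose breadth = mean spacing of consecutive
   furrow centres. Three runs are averaged into the mean crease breadth
   (MCB).
4. **Demographics** (`demographics`): shrinkage correction
   `MCB_C = MCB_O (1 + ts)` and the three age regressions
   (`Age(months) = 614·MRB − 112` and its two shrinkage-aware variants),
   plus published classification bands (0.39/0.52 mm and 0.37/0.52 mm
   breadth thresholds; 13/16 ridges per 25 mm² for sex).

`phantom` generates all test inputs synthetically; `workflow`/`cli` tie
the stages into a reproducible seeded run.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| `voxel_mm` | 0.025 | mm | effective voxel pitch of the targeted micro-CT reconstructions; also the phantom grid pitch |
| `ridge_period` | 0.5 | mm | adult-scale ridge spacing; phantoms sweep 0.3–1.4 |
| `ridge_depth` | 0.12 | mm | no published depth figures exist; chosen once as plausible impressed-clay relief comfortably above half-voxel quantization |
| `min_island_voxels` | 27 | voxels | a 3³ neighbourhood; removes speckle and sub-grain debris without touching the surface |
| `smooth_radius_voxels` | 1 | voxels | border smoothing ball |
| `ts` (true shrinkage) | 0.05, 0.08 | fraction | the reference shrinkage range for the terracotta practice under study; physically 0–0.20 |
| `band_years` | 2.25 | years | reported half-width of the age estimate band |
| runs per impression | 3 | — | intra-observer replication of the line placement |

## The two shrinkage-aware age models

KAmod divides the breadth by `(1 − ts)` inside the regression; KAmod2
multiplies the observed breadth by `(1 + ts)` first. Since
`1/(1 − ts) > 1 + ts` for `ts ∈ (0, 1)`, KAmod is always the older
estimate, with equality only at `ts = 0` where both reduce to the plain
regression. Both are kept verbatim and never substituted for each other.
Estimates above 15 years are flagged questionable (the underlying
calibration data thin out there), estimates from breadths outside
0.3–0.6 mm are flagged extrapolated, and negative months (tiny breadths)
are returned with a flag rather than raised.

## What the phantoms emulate — and what they do not

Phantoms are height-field patches: a sinusoid of known period (smooth
crest/trough, finger-ridge analogue) or rectangular grooves repeating at
the tooth width (toolmark analogue), on a planar or spherical-cap
substrate, optionally scaled by `(1 − ts)` to emulate linear firing
shrinkage. Voxel phantoms embed the surface in a slab with two intensity
modes (air 50, clay 200), Gaussian noise (sd 10), and brighter spherical
mineral inclusions (density 0.5 mm⁻³, radius 0.04 mm). The voxel slab is
oriented so each slice cuts across the surface: every slice then contains
both phases, which is what makes per-slice thresholding well-posed.

Not emulated: X-ray physics (beam hardening, cone-beam artifacts),
pressure deformation of the skin, clay inhomogeneity at the surface, and
inclusions that pierce the clay/air interface (they are kept a small
clearance away). Passing recovery tests therefore demonstrate the
geometric correctness of the chain — segmentation bias, detrending
fidelity, crossing-based counting — not robustness to the local surface
corruption real scans exhibit; on real material those defects are
handled by the analyst's choice of transect and region.

## Numerical choices

- **Local frame.** The fit frame comes from principal-axes analysis of
  the cropped points, height = least-variance axis. Axis signs are made
  deterministic (largest-magnitude component positive, right-handed
  completion); residuals are therefore reproducible, and invariant under
  moderate rigid motions. Under rotations large enough to flip the sign
  convention the residual field changes sign as a whole, which leaves
  every breadth/count result unchanged.
- **Conditioning.** In-plane coordinates are normalized to [−1, 1]
  before building the degree-5 Vandermonde system; rank deficiency
  (collinear or one-axis point sets) is an error, not a silent fit.
- **Isosurface.** Marching cubes runs on the indicator volume smoothed
  with a 1-voxel Gaussian: a raw binary isosurface is quantized to
  half-voxel steps, which near a crease boundary produces spurious
  baseline crossings; the mild smoothing restores sub-voxel vertex
  placement. Vertices use the voxel-centre convention
  `(index + 0.5)·voxel_mm`, world axes `(x, y, z) = (col, row, slice)`.
- **Cleanup idempotence.** Island removal plus closing-then-opening is
  iterated to a fixed point (bounded passes), so applying the filter to
  its own output changes nothing.
- **Crossing bookkeeping.** Duplicate intersections at shared triangle
  edges are merged at 1 nm tolerance. A transect ending inside a crease
  leaves an incomplete pair, which is truncated with a warning. Furrow
  centres are taken as midpoints between bounding crossings (exact on
  symmetric profiles and insensitive to sampling), with crest/furrow
  identity decided by the relief height at the interval midpoint.
- **Report rounding.** Corrected breadth cells are computed in decimal
  arithmetic from the observed value and rounded half-away-from-zero to
  2 dp, so binary float representation cannot perturb a printed cell.
  Where a published corrected cell disagrees by ±0.01 (its upstream
  value was rounded before correction), the discrepancy is flagged, not
  reproduced.
- **Classification boundaries.** Breadths exactly on a band threshold go
  to the intermediate band.

## Problem sizes used in the shipped checks

Recovery checks run the complete voxel pipeline at periods
{0.3, 0.5, 0.8, 1.3} mm × shrinkage {0, 0.05, 0.08} with 6 ridges and a
1.5 mm cross extent per phantom (patches of ≥4 periods, the minimum for
stable detrending). Measured Kamp and Penrose MCBs land within ~1 % of
the post-shrinkage period, against a 5 % acceptance band. Oracle checks
use 10⁴ random ray/triangle pairs and 100 random histograms.

## Known limitations

- Surface fitting introduces local distortion near patch borders; no
  correction is attempted.
- Transect orientation is supplied by the caller (or by phantom truth);
  there is no automatic ridge-orientation estimation.
- The group thresholds and regressions are population-specific
  calibrations applied as published; no recalibration is provided.
- Ridge-density sex calls are refused on fragments below 6 mm², where a
  standard reference area cannot be embedded.
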