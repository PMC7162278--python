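# Methods

## Two-compartment model

A lung voxel is modelled as a volume-weighted mixture of two
submaterials with known CT numbers; the air fraction is

AV/TV = (HU_L − HU_T) / (HU_A − HU_T),

clipped to [0, 1] (clip counts and the raw range are logged). The model
assumes (i) CT numbers mix linearly with volume fraction — valid to
first order for materials of similar effective atomic number at fixed
spectrum — and (ii) that one "representative tissue" CT number describes
all non-air lung content. Muscle (≈51 HU) and blood (≈46 HU) are both
usable: because lung CT numbers sit near the air end of the scale, the
worst-case AV/TV disagreement between the two calibrations over
HU ∈ [−1000, −500] is about 0.2 percentage points (the package computes
it analytically in `experiments.calibration_pair_difference`).

Key property (the reason the method resists the partial volume effect):
the map HU → fraction is affine, so for any normalised, non-negative
blurring kernel the sum of unclipped fractions over a region is
unchanged up to boundary flux. Total air volume = Σ fraction × voxel
volume is therefore resolution-independent; per-voxel *values* are not,
which is exactly what the foam histogram experiment demonstrates.

Conventions: grids are (z, y, x) with spacing in mm; fractions are
stored in [0, 1] and rendered as percent only at reporting boundaries;
ROI membership is by voxel-centre inclusion (fractional centre
coordinates are allowed, e.g. for even-sized symmetric ROIs); ROI
statistics use the n−1 sample standard deviation.

## Segmentation

* Threshold segmentation uses strict inequality (HU < t for air-like,
  HU > t for solid); configurable, stated because the boundary case is
  convention-dependent.
* Otsu's threshold is computed on the integer-HU histogram (1 HU bins).
  Candidate cuts lie between consecutive *occupied* bins; the returned
  threshold is the midpoint of the two bin centres the best cut
  separates, ties broken toward the lowest threshold. (Midpoint-of-
  occupied-bins is what makes the two-spike histogram {−1000, 0} yield
  −500 rather than an arbitrary point of the empty plateau, where the
  between-class variance is constant.)
* The lung mask takes the AV/TV map, removes exterior air (components
  of fraction > 0.95 touching the grid boundary), keeps voxels above
  1 % AV/TV, and retains the largest components (default two). 1 % and
  the component count are configurable.
* When no trachea seed is given, `find_trachea_seed` scans the most
  superior axial slices for in-plane components of AV/TV ≥ 0.99 that do
  not touch the slice border and seeds the roundest one (smallest
  normalised second moment); a manually supplied seed always takes
  precedence. This is a convenience heuristic, not a validated detector.
* Airway removal region-grows (6-connectivity by default; 26 available)
  from a trachea seed over voxels with AV/TV ≥ 0.95 and subtracts the
  grown set. 6-connectivity is the conservative choice against diagonal
  leakage through the PVE-blurred airway wall. Documented consequence:
  any near-pure-air region connected to the airway tree above the
  criterion (e.g. a bulla opening into a bronchus) is removed with it.

## RAVH and biomarkers

40 half-open bins [2.5k, 2.5(k+1)) % with the last bin closed at 100 %;
bin centroids 1.25 %…98.75 %. Relative volume is the voxel-count share
(valid for the uniform grid of one scan; volume weighting for
anisotropic multi-scan pooling is out of scope). RV_NL sums the bins
centred 81.25–91.25 %, RV_DL is the 98.75 % bin, R_DL/NL their ratio —
reported as +inf with a warning when RV_NL = 0, preserving the ranking
of extreme disease-like cases. Group-mean RAVHs are per-bin arithmetic
means and remain normalised. Mean AV/TV is computed on the
airway-removed lung mask, after clipping.

## Digital phantoms

**Cavity phantoms.** Boxes of solid polyurethane (PU) whose interior is
split along one axis into n cavities of width w by septa of width s;
each cavity spans 20 × 20 mm in the other two axes, inside 5 mm
walls/caps. The five study geometries are
(s, w, n) = (3, 1.9, 4), (2, 2, 4), (0.7, 2.8, 8), (0.7, 3, 6),
(1, 4, 4) mm. The outer dimensions are derived from the layout plus the
wall (the printed 30 × 30 × 20 mm outer box cannot hold the 8-cavity
layout, and the physical phantoms' printed total volumes are not
reconcilable from their stated outer dimensions alone); ground truth is
always the voxel count of the rasterised scene, never a printed number.
Rasterisation requires ≥ 4 grid samples across the thinnest feature;
the studies use 0.1 mm scenes.

**Foam phantoms.** A foam of p pores per inch is modelled as an
orthogonal strut lattice with spacing a = 25.4/p mm. The strut radius is
not taken from the thin-strut closed form but solved on the generated
grid: the radius is the quantile of the distance-to-lattice field at the
target solid fraction f = mass / (density × cube volume), so the
realized fraction matches f essentially exactly (well inside the 5 %
relative tolerance the builder enforces). Two deliberate departures from
a literal axis-aligned lattice:

* the lattice is *tilted* (default 11° and 6° about the two in-plane
  axes) so strut planes sweep two or more lattice periods across the
  block. A real foam is statistically homogeneous at slice scale; an
  axis-aligned lattice concentrates two thirds of its mass in discrete
  z-planes and would make per-slice mass comparisons depend on where a
  slice happens to cut. Optional per-cell jitter (seeded) is available
  but defaults to off — at these strut densities jitter adds shot noise
  larger than the residual ripple of the tilted regular lattice;
* simulated blocks are representative interior slabs, not the full
  50 mm cube: 30 × 30 × 5 mm at 0.05 mm (10 PPI), 16 × 16 × 5 mm at
  0.025 mm (20 PPI), 8 × 8 × 5 mm at 0.015 mm (60 PPI). Pores are
  uniform by construction, so masses scale with the block's share of
  the cube volume; a strut-resolving full cube would exceed 10⁹ voxels.

## CT simulator

Occupancy → HU (volume-weighted mix of the solid and air CT numbers,
defaults 113.4 and −999.5 HU) → in-plane Gaussian PSF of stated FWHM →
box-average resampling to the reconstruction pitch in-plane and to the
slice thickness along z (exact integral-image evaluation of the
piecewise-constant voxel model) → optional additive Gaussian HU noise
from a seeded generator. Deterministic given (scene, config, seed); the
noise-free path is bit-reproducible. No helical/sinogram physics, no
beam hardening, no scatter: the simulator reproduces the *averaging*
behaviour of reconstruction, which is the effect under study. Blur edge
handling is configurable: "nearest" for scenes embedded in padding
(cavity phantoms get 3 mm of surrounding air), "wrap" for periodic
interior blocks (foams), which conserves in-plane sums exactly.

Cavity-volume evaluation uses the phantom's outer box inset by 2 mm:
inside the 5 mm wall, so cavity air blurred into the wall is still
counted while exterior air never reaches the region (the PSF reach is
≈ 1.5 mm). Foam per-slice masses are evaluated over the full periodic
block on slices from the middle third of the slab, against the
fractional mass (total mass × thickness / side, scaled to the covered
in-plane area); the foam RAVH uses an interior window 2 mm from the
block faces, clear of the periodic seam.

## Synthetic cohort

`generate_cohort` draws parenchyma-only AV/TV samples. Controls:
voxelwise Normal(μ_s, 6.5 %) with subject means μ_s ~ Normal(88.75 %,
1.5 %), truncated to [0, 97.5 %). COPD adds a trapped-air component:
with probability 0.18 (configurable) a voxel is drawn uniformly from
[98, 100) %. The truncation of the parenchymal component below the top
bin's lower edge makes the injected trapped-air fraction identifiable
as RV_DL (recovered to binomial sampling error), and reflects that in
these synthetic lungs "damaged lung" is exclusively the trapped-air
component. The defaults place the control histogram mode at the
88.75 %-centred bin with a peak share of roughly 15 %, and give
COPD-like subjects a second peak in the top bin. What the generator
does *not* emulate: spatial correlation of disease (voxels are iid),
airways and vessels, noise-induced negative/super-unit fractions, and
slice-thickness dependence — cohort-level tests therefore exercise the
biomarker and ROC machinery, not scanner physics (the phantom studies
cover that).

## Statistics

AUC is the Mann–Whitney probability (ties count ½) computed from rank
sums; orientation is auto-selected so AUC ≥ 0.5 and recorded. The
operating point maximises Youden's J over midpoints between adjacent
distinct values; sensitivity/specificity are reported in percent.
Bland–Altman returns the mean difference and mean ± 1.96 SD. The
independent-samples test is Welch's (no equal-variance assumption);
paired identical samples return (t, p) = (0, 1) rather than NaN.
Significance is 0.05 where a decision is needed. No multiple-testing
correction and no AUC confidence intervals are provided.

## Numerical notes and limitations

* Fractions outside [0, 1] (noise, artifacts, materials denser than the
  calibration tissue, e.g. bone at the lung boundary) are clipped and
  counted; heavy clipping is a signal the calibration does not fit the
  scene.
* The box resampler drops output samples whose window would leave the
  grid and centres the sample train, so a block whose extent is not an
  integer multiple of the pitch loses a sub-voxel margin at each edge
  (< 0.3 % of in-plane mass for the foam blocks).
* Under the simulator's stated noise-free, in-plane-PSF-only conditions
  the −850 HU threshold underestimates the widest-cavity phantom by
  30 % (and 43–76 % for the narrower ones), and −950 HU threshold
  segmentation of the 10 PPI foam overestimates per-slice PU mass by
  ≈ 660 %. Physical scans add z-direction blur and noise, which push
  both biases further in the same direction; the simulator
  intentionally omits them, so its threshold biases are lower bounds on
  scanner behaviour.
* The region-growing depth into the bronchial tree is governed solely
  by the 95 % criterion; no anatomical generation limit is imposed.
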