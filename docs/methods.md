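# Methods

This note documents the models, the defaults and why they are what they
are, what the synthetic phantom does and does not emulate, and the
numerical choices a maintainer would otherwise have to reverse-engineer.

## Coordinate and intensity conventions

Volumes are `(x, y, z)`-ordered arrays of Hounsfield units (HU) with
0-based indices and the affine geometry `world_mm = origin + index *
spacing` per axis. Stored HU are clipped to the representable CT range
[−1024, 3071] and written as 16-bit signed MetaImage. Annotations
(`seriesuid,coordX,coordY,coordZ,diameter_mm`) live in world mm and are
never edited: when a volume is resampled only its geometry changes, so one
set of cue points serves every thickness.

"Slice thickness" is operationalized as z-spacing. That identification is
only valid for contiguous acquisitions (thickness = spacing); inventory
records where the two differ are rejected rather than silently accepted,
because slab averaging would not be a faithful thickness simulation there.

## Slab-averaging thickness simulation

`downsample_slices(vol, ratio)` replaces each group of `ratio` consecutive
slices with their arithmetic mean, computed in double precision. Averaging
post-reconstruction densities gives the same mean density a thicker slab
would have under ideal reconstruction, so HU are preserved without
rescaling. Choices:

* integer ratios only (2, 4, 8 canonical; other integers ≥ 2 accepted with
  a warning) — only coarsening is supported, since slab averaging cannot
  synthesize finer slices;
* trailing slices not filling a complete group are dropped (warned), so
  every output slab represents the same physical thickness;
* the z-origin shifts by `(ratio − 1)/2` input spacings so each slab
  carries the world position of its center — cue points map into the new
  grid purely geometrically;
* integer volumes are re-stored with round-half-to-even (minimal bias);
  float volumes stay float, which is what the conservation contract (mean
  HU preserved to 1e−9 before any integer cast) is stated against. Note
  that the two-stage identity `ds(ds(v,2),2) = ds(v,4)` holds exactly for
  float data but not for integer data, where each stage rounds.

## Synthetic thoracic phantom

One phantom case is: background air (−1000 HU), an elliptical soft-tissue
body cylinder (0 HU), two ellipsoidal lung fields (−850 HU) whose geometry
is proportional to the volume extent, random-walk vessel tubes at +900 HU
above lung with occasional junction bulges, and spherical nodules brighter
than parenchyma. Rendering:

* partial volume by supersampled occupancy — voxels on an object boundary
  get the fraction of a 3×3×3 subgrid (5×5×5 for spheres, whose patches
  are tiny and whose interior fill fraction is the quantity the mean-HU
  contract checks) falling inside the object; objects are
  alpha-composited in paint order;
* Gaussian edge smoothing (σ = 0.7 mm by default, ≈ half the in-plane
  spacing) then additive white Gaussian HU noise (σ = 20 HU default);
* ground-truth lung and nodule masks are the pre-noise, pre-smoothing
  occupancy > 0.5 regions.

Default study conditions for cohorts: volumes of 128×128×64 voxels at
(0.7, 0.7, 1.25) mm — a deliberately small thorax that keeps a 20-case
end-to-end run in minutes while leaving room for 12-mm nodules inside the
lung fields; 1–3 nodules per case, diameters uniform in 4–12 mm (all above
the 3-mm annotation floor), contrasts uniform in 300–600 HU; 6 vessels per
case whose bulges (radius 2.2–3.2 mm, ~8% of walk steps) are the main
false-positive source. Vessel sphere centers keep at least one nodule
diameter away from every nodule center so distractors can never contaminate
ground truth. Per-case seeds are spawned from the master seed; cohorts are
byte-reproducible.

What the phantom does **not** emulate: airway trees, pleural attachment and
juxta-vascular nodules, reconstruction kernels, dose-dependent noise
spectra, and anatomical intensity texture. Passing phantom contracts
therefore demonstrates the pipeline's mechanics (geometry, partial volume,
ranking, scoring) — not clinical-grade sensitivity on real screening data.

## Lung segmentation

Air-range voxels (HU < −300) are labeled with 26-connectivity; components
touching the lateral (x/y) volume border are discarded as outside-body air;
the two largest remaining cavities are kept; vessel holes are closed with a
3-mm Euclidean ball. This is a standard cavity-based approach chosen to
meet a Dice ≥ 0.9 contract against phantom truth; it is not a clinical
segmentation (no airway removal, no pleural refinement).

## Candidate detector

For each of 15 thresholds (uniform over [−700, 0] HU) the lung-masked
exceedance mask is opened with a Euclidean ball whose radius falls linearly
from 2.0 mm at the lowest threshold to 0.25 mm at the highest; each
intermediate mask's components pass a size filter (volume within
[4, 50000] mm³, i.e. roughly 2–45 mm equivalent diameter) and a compactness
filter (volume / axis-aligned bounding-box volume ≥ 0.15, a cheap
scale-aware definition); survivors are OR-fused and 26-connected components
of the fusion become candidates.

Numerical/calibration notes:

* openings are implemented with two anisotropic distance transforms
  (erode at `d > r`, dilate at `d ≤ r`) after padding with one background
  layer; this is exactly erosion/dilation by the rasterized closed ball and
  about an order of magnitude faster at millimeter radii;
* the starting opening radius matters: with 0.7-mm edge smoothing, a 4-mm
  nodule thresholded near its base level retains a core of only ≈ 2.3 mm, so
  start radii near 3 mm silently erase everything below ≈ 6.5 mm. The 2.0-mm
  default keeps the whole >3-mm regime detectable while still removing
  speckle and thin vessels; the full ladder is a plain config field for
  users who want a stricter or looser detector;
* structuring radii are specified in mm and rasterized per volume spacing,
  so behavior is consistent across thicknesses (at 10-mm slabs the ball
  degenerates to in-plane opening, which is the physically sensible limit).

## Feature catalog

61 named features per candidate, identical order for every candidate of a
run. Substrates: raw HU plus two local-contrast-enhanced (LCE) images,
`(v − mean)/(std + 1 HU)` over in-plane windows 11 and 51. Regions: the
candidate mask, its one-voxel boundary ("perimeter"), and a shell
(3-voxel dilation band minus the mask, clipped to the lung; if empty, shell
features are zeroed and flagged). Families:

* geometric — slice count, equivalent diameter `(6V/π)^(1/3)`, circularity
  `4πA/P²` of the largest axial cross-section, elongation (extreme
  principal-axis ratio of the voxel-position covariance), bounding-box
  compactness, shell area, periapsis (distance from the centroid to the
  lung boundary — a named, overridable definition);
* intensity — mean/std/min/max inside, mean/std over the shell, contrast
  (μ_in − μ_out), std separation (σ_in − σ_out), Fisher ratio
  `(μ_in − μ_out)²/(σ²_in + σ²_out + 1e−6)`, each per substrate; plus
  eroded/dilated mask variants of the raw Fisher ratio and std separation,
  probing how sharply the statistics change across the rim;
* gradient — central differences in mm; gradient-magnitude means inside/
  over the shell, surface gradient (boundary mean, raw and LCE1), radial
  gradient (projection on the unit vector from the centroid) and radial
  deviation (angle in degrees between gradient and radial direction),
  mean/std over inside, perimeter and shell;
* positional — in-plane distance from candidate centroid to the lung
  centroid, centroid x normalized within the lung bounding box, bottom
  shadow fraction (fraction of lung voxels in the 30-mm column below the
  candidate, +y taken as "down", above −500 HU), std of the below-column
  (raw and LCE1), and z-profile contrast/Fisher ratio through the centroid.

Degenerate denominators are floored (LCE ε = 1 HU, Fisher ε = 1e−6,
standardization σ floor 1e−6) so every feature is finite by construction.
Note the Fisher ratio is scale-invariant only up to its ε: on data whose
variances vanish, the floor dominates and invariance breaks — the test
suite asserts invariance at 1e−3 only for non-degenerate samples.

## Shortlist, SFS, FLD

* Shortlisting ranks every feature by the orientation-folded Mann–Whitney
  AUC (ties = 0.5 via midranks) and keeps the top k (default 300; on this
  catalog that keeps everything, but the operation matters on larger
  catalogs and per fold). Ties break by catalog order, so results are
  deterministic.
* SFS adds one feature at a time; the merit of a tentative set is the
  training-set FROC AUC(0–10) after refitting the FLD — resubstitution on
  the training cases, with an internal split deliberately not used by
  default. The stopping size is the smallest prefix whose merit is within
  0.05 of the best merit along the trace (a deterministic plateau rule),
  capped at 20 features. Greedy merit is not asserted to be monotone — it
  genuinely is not.
* The FLD standardizes features with training means/stds, computes the
  pooled within-class covariance, and solves `(S_w + λI) w = μ₁ − μ₀` with
  ridge λ = 1e−3 by default; hundreds of features on few cases is otherwise
  singular. λ = 0 on a singular system raises a fit error rather than
  returning noise (condition-number guard at 1e12). All hit candidates are
  positives, everything else negative; no subsampling.

## FROC, AUC(0–10), ANODE, confidence intervals

Redundant markings merge when each center lies within the other's radius
(union–find; merged center = member mean, diameter = member max). A
candidate hits a target when `distance < diameter/2` (strictly — a
candidate exactly on the boundary misses); multiple hits count once and
never as false positives. Thresholds sweep the distinct scores descending
with tied scores entering together; cases with zero candidates still count
in the FP denominator. The curve is read as a right-continuous step
function: AUC integrates it over [0, 10] FP/case, extending the final
sensitivity to 10; the ANODE score averages the step reads at the seven
reference rates, with sensitivity 0 below the first achieved rate.
Confidence intervals split the test cases into 10 near-equal seeded
subsets and report `mean ± 1.96 · std/√10` (sample std) of the per-subset
metric — an explicit design choice, as is the whole subset scheme.

## Study harness

Training compositions are pure functions of the case inventory. The
homogeneous regime fails loudly (documented failure row in reports) when
no training case matches the test thickness. The common-thickness regime
(default 2.5 mm, the best performer in the studies this package supports)
resamples every case whose native spacing divides the target — including
test cases when their native thickness differs — and excludes, with a
warning, cases whose spacing does not divide it. Test ids never appear in
a composition (asserted machine-readably).

The thickness study reuses one seeded train/test split at every ratio, so
curves across 1.25/2.5/5/10 mm compare the same cases and the same world-mm
cue points. Benchmarks used by tests and the acceptance script run at
problem sizes chosen to keep a full pass in minutes on one CPU: 20-case
default cohorts (5 held out) for the end-to-end benchmark, 12-case
small-nodule cohorts (4–5 mm, 400–600 HU) for the degradation check. The
permuted-score baseline re-scores the identical held-out candidates with
randomly permuted scores (20 permutations, mean AUC) — the no-information
reference a trained ranking must beat.

## Known limitations

* The feature catalog is a representative implementation of the named
  families, not a bit-faithful reproduction of any historical 503-feature
  suite; numbered variants are realized as eroded/original/dilated mask
  statistics by explicit convention.
* The phantom's false-positive population (vessel bulges) is far easier to
  reject than real juxta-vascular or pleural mimics; absolute AUC/ANODE
  values on phantoms are optimistic and only orderings/contracts are
  meaningful.
* Only integer slab-averaging is supported for thickness changes; there is
  no interpolation-based resampling to arbitrary spacings.
* Lung segmentation assumes the lungs do not touch the lateral volume
  border and that the body is surrounded by air.
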