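# Methods

This note records the models, conventions, numerical choices and known
limitations of the toolkit, module by module.

## Spatial conventions

All volumes live on a `VoxelGrid` with 0-based voxel indices, a 4×4 affine
mapping indices to world millimetres, and the voxel-centre convention: the
world position of voxel *(i, j, k)* is the affine image of *(i, j, k)*, and
a world point belongs to the voxel with the nearest centre (round-to-nearest
index). Volumes are read and written as NIfTI-1 through nibabel with
affines honoured in both directions. Downsampling is block-mean by an
integer factor only; non-integer ratios are rejected rather than
interpolated so that mass accounting in tests stays exact (block mean
conserves total mass × voxel-volume ratio, with edge-replicated padding for
partial blocks). The interpolation used by the original analyses for
downsampling is not documented there; block-mean is this package's choice,
with `subsample` available as an alternative flag.

## Fibre model and streamline propagation

A `FibreField` stores up to three fibre populations per voxel — axial unit
mean orientation, volume fraction *f* ∈ [0, 1] (0 = absent), and an angular
dispersion SD in degrees. This mirrors crossing-fibre orientation models
estimated from diffusion MRI, but here the fields are constructed
analytically by the phantom module rather than fitted from data; posterior
estimation of fibre models from raw diffusion signal is out of scope.

Propagation parameters and defaults (all exposed on `TrackingParams`):

| parameter | default | meaning |
|---|---|---|
| `step_size` | 0.5 mm | advance per step (human-scale; 0.2 mm is the macaque-scale choice) |
| `curvature_threshold` | 80° | maximum angle between consecutive steps |
| `max_steps` | 2000 | step budget per half-streamline |
| `volume_fraction_threshold` | 0.01 | subsidiary populations below 1% are ignored |
| `streamlines_per_seed_voxel` | 1000 | samples per seed voxel |

Design choices the underlying method leaves open, fixed here and documented:

- **Orientation lookup** is nearest-voxel; orientations are not
  interpolated between voxels (common probabilistic-tracking practice).
- **Population choice**: with a previous direction, the supra-threshold
  population with maximal |dot| alignment is followed; at the seed (no
  previous direction) a population is drawn with probability proportional
  to its volume fraction.
- **Dispersion sampling** rotates the mean by an angle drawn from a
  zero-mean normal with the stated SD about a random perpendicular axis — a
  simple, documented stand-in for the external fibre model's orientation
  posterior. Samples are sign-disambiguated so the dot product with the
  previous direction is non-negative; the curvature check applies after
  that disambiguation, and a rejected step terminates the streamline.
- **Seed jitter** is uniform within the seed voxel, drawn from the
  streamline's own substream (`default_rng([root_seed, stream_index])`), so
  any single streamline is reproducible in isolation and whole runs are
  bit-identical for a fixed seed.
- **Two half-streamlines** start from the seed in opposite signs of the
  seed-voxel sample and are concatenated; each half has its own step budget
  and termination reason (left-field / no-fibre / curvature / max-steps /
  stop-mask / exclusion).

Protocol semantics: a streamline is **valid** iff its visited voxel set
intersects every target mask (unordered conjunction) and never touches an
exclusion mask. Entering a stop mask truncates propagation, but the
truncated streamline still counts if the targets were already visited —
mask order within the path does not matter. Entering an exclusion mask
invalidates the whole streamline (both halves). The path distribution
counts *distinct* valid streamlines per voxel (not per-step visits) so that
after division by the number of valid streamlines the values are visitation
probabilities in [0, 1]. When zero streamlines are valid the normalised map
is all-zero and a warning is logged; this edge case is a deliberate,
documented choice since the original description does not discuss it.
Symmetric (flip-and-average) protocols — the anterior-commissure style —
run the protocol a second time with seed and final target swapped and
average the two normalised maps voxelwise.

## Protocols and the roster

Protocol files are YAML with keys `{name, laterality, seed, targets[],
stop?, exclusions[], symmetric}`, mask paths relative to the protocol file.
Validation rejects empty seeds, seeds overlapping an exclusion, grid
mismatches, and unknown keys. The shipped roster
(`data/subcortical_manifest.yaml`) lists the twelve cortico-subcortical
protocols — AMF, UF, FX, MB, the four striatal-bundle parts, the three
extreme-capsule parts, and the commissural AC — and expands to 23 tract
instances (11 bilateral × 2 + 1 commissural). Bilateral instantiation is by
`_L`/`_R` name suffix; geometric reflection of real atlas masks is out of
scope, as are the anatomical mask volumes themselves, which are external
inputs in template space.

## Connectivity blueprints

Cortical rows: a GM×WM matrix is built by seeding unconstrained streamlines
at labelled grey-matter boundary locations and counting distinct-streamline
visits over a white-matter mask; multiplying by the WM×Tracts matrix of
collated normalised path distributions gives GM×Tracts. The GM×WM rows
enter the product as raw counts; normalisation is deferred to assembly
(whether the original construction count-normalises first is not stated —
deferring changes nothing after row normalisation since the product is
linear in each row).

Subcortical rows intersect each tract's normalised path distribution
directly with binary nucleus masks: downsample (block-mean) **then**
threshold — values below 0.1% of valid streamlines are zeroed — then
multiply by each mask. The threshold is an absolute cut on the normalised
map, not a percentile, consistent with valid-streamline normalisation.
Assembly stacks cortical then subcortical rows and row-sum-normalises;
zero-mass rows stay zero and are reported on the result. On crossing-bundle
phantoms the direct construction is strictly more nucleus-specific than the
intermediary one (specificity ratio > 1), because boundary-seeded
streamlines from one nucleus traverse crossing voxels that carry the other
bundle's path mass — the motivation for using the direct method in
subcortex, reproduced here as a tested property.

## Divergence and homologue matching

`symmetric_kl` evaluates the two-way KL sum in bits after shifting both
rows elementwise by δ = 10⁻⁶. The shift is **not** followed by
renormalisation — the shifted rows sum to 1 + Tδ — matching the stated
procedure literally; the discrepancy is O(δ) and documented. Divergence of
identical rows is exactly 0; the opposed indicator pair (1,0)/(0,1) gives
2[(1+δ)log₂((1+δ)/δ) + δlog₂(δ/(1+δ))] ≈ 39.863 bits, used as a frozen
oracle. When a tract subset (cortico-cortical / cortico-subcortical) is
selected, both the reference pattern and each row are restricted to the
subset columns and renormalised before comparison so the divergence
operates on comparable masses; the original description is silent on this
and the choice is recorded here. `best_match_region` thresholds a
divergence map at the 7th percentile (numpy linear-interpolation
percentile; a constant map returns the empty set with a warning).

## Similarity and group statistics

`tract_pearson` zeroes values below 0.5% of valid streamlines in each map
and correlates over the union of supra-threshold voxels (the support choice
is this package's; the threshold is the standard one). Correlations over
fewer than 3 voxels, or with a constant map, are flagged missing (NaN) and
excluded from per-pair means with a logged count. The whole grid is used
rather than a brain mask (phantoms have no brain mask).

The exact Mann–Whitney mode enumerates all C(n+m, n) assignments of the
pooled mid-ranks (feasible for n+m ≤ 12; enforced) and reports the
two-sided p as min(1, 2·min(P(U ≤ u), P(U ≥ u))); the normal approximation
uses the tie-corrected variance with a continuity correction and agrees
with the exact computation to well within 0.02 at n = m = 20 on untied
data. Bonferroni correction flags p < α/n. Representative-subject selection
ranks subjects by mean-over-tracts correlation to the group average and
returns the nearest-rank percentile subject, ties broken by lowest id.

## Tracer termination maps

Terminations are binned to nucleus-mask voxels by nearest voxel centre;
out-of-mask terminations are dropped and counted in a report. Per
injection-ROI label, counts are divided by the label's total in-mask
terminations, so each unsmoothed map sums to exactly 1. Smoothing convolves
each label volume separably with a cubic B-spline kernel sampled at integer
voxel offsets (support ±2 scale units; the scale is exposed in mm, default
one voxel — the original analysis states spline smoothing without
parameters), then restricts to the mask and renormalises, conserving
per-label mass to 1e-9. As the scale shrinks below half a voxel the kernel
degenerates to the identity. The dominant-label volume takes the per-voxel
argmax over labels in a declared order (ties go to the first label);
analyses comparing layer topographies should restrict to voxels where at
least one label has positive mass, since void voxels trivially fall to the
first label under the tie rule.

## Phantoms: what they emulate and what they do not

`make_scene` voxelises tubular bundles around polyline centrelines: every
voxel whose centre lies within the radius carries the bundle's local
tangent as a population; overlaps carry one population per bundle, capped
at three. Endpoint protocols put seed and target caps at the first and last
1.5 mm of arclength. The phantoms emulate the *geometric and statistical
structure* the analyses assume — crossing regions, protocol masks with
known ground truth, stratified terminal fields — but not diffusion signal
formation, scanner noise, registration error, or anatomical variability of
real brains; passing tests demonstrate correctness of the analysis chain,
not performance on real data.

`make_matched_blueprints` draws one tract profile per region from a
Dirichlet(concentration) simplex distribution (default concentration 0.5,
giving sparse, well-separated profiles) and scatters both species' rows
around it with multiplicative log-normal noise (default SD 0.1, small
relative to between-region differences). With `n_cortical > 0`, the
cortico-cortical block of every region scatters (SD 0.1) around one shared
base pattern while the cortico-subcortical block stays region-specific —
the regime in which subcortical tracts add matching information, used by
the contrast analyses with 5 regions × 12 tracts (6 + 6).

`make_family_cohort` gives each pair a latent bundle-geometry vector
(mid-course lateral offset, SD 1.5 mm across pairs) perturbed per member by
the group's within-pair SD — defaults 0.1 mm for monozygotic twins, 0.5 mm
for dizygotic twins and non-twin siblings (equal by construction), and
independent draws for unrelated pairs, encoding the expected heritability
ordering. Subject bundles carry 4° dispersion so tracking itself is
stochastic. The shipped analyses use 10 pairs per group — a deliberately
small cohort that still separates the groups — with 20 streamlines per seed
voxel.

## Problem sizes and determinism

All shipped analyses run on grids of 20³–32³ voxels with 8–100 streamlines
per seed voxel, chosen so the full pipeline (tests plus the acceptance
script) completes in about a minute and a half on one CPU while leaving
every statistical conclusion stable across seeds. Every random draw in the
package derives from explicit integer seed lists
(`default_rng([root, *indices])`); there is no global random state, and
identical inputs give bit-identical outputs.

## Known limitations

- Orientation fields are analytic; no fitting from diffusion data.
- No nonlinear registration or template spaces; all comparisons happen on
  shared grids.
- Surface (GIFTI/CIFTI) containers at real scale are not implemented;
  grey-matter boundary locations are labelled points.
- The exact Mann–Whitney mode is combinatorial and intentionally refuses
  n+m > 12; use the normal approximation there.
- Blueprint construction assumes all path distributions share one grid.
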