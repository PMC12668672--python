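# subtract

A desk-scale toolkit for **standardised cortico-subcortical tractography**:
protocol-constrained probabilistic streamline tracking on multi-fibre
orientation fields, connectivity-blueprint construction for cortex and
subcortex, symmetric Kullback–Leibler homologue matching across species,
tract-similarity statistics, and anterograde-tracer termination-probability
maps. Everything is testable end to end on synthetic fibre phantoms with
known ground truth — no imaging data downloads are required.

The intended users are researchers developing or validating tractography
protocols and cross-species connectivity analyses who need a transparent,
fully seeded reference implementation of the analysis chain at phantom scale.

## The methods in brief

**Tracking.** Each voxel of a `FibreField` carries up to three fibre
populations (axial mean orientation, volume fraction *f*, angular
dispersion). From each seed-voxel streamline start (jittered uniformly
within the voxel), two half-streamlines propagate in opposite signs:
populations with *f* below a 1% threshold are ignored, the surviving
population best aligned with the previous direction is followed, a dispersed
sample is drawn about its mean, and the step (default 0.5 mm) is rejected —
terminating the streamline — if it bends more than the curvature threshold
(80°). Propagation also ends on leaving the field, finding no fibre,
entering a stop or exclusion mask, or after 2000 steps per half. A
streamline is **valid** iff it visits every target mask and never enters an
exclusion mask. The tract's path distribution counts, per voxel, distinct
valid streamlines, normalised by the number of valid streamlines.

**Blueprints.** A connectivity blueprint is a row-stochastic GM×Tracts
matrix. Cortical rows are formed through an intermediary product
(GM×WM)·(WM×Tracts) — boundary-seeded visitation counts times collated
path distributions — to sidestep gyral bias; subcortical rows intersect each
tract map directly with binary nucleus masks after downsampling and a 0.1%
threshold, which is demonstrably more specific in the subcortex.

**Matching.** Rows *m* and *h* of two blueprints are compared with the
symmetric KL divergence in bits,

```
D = Σ_k m_k log2(m_k / h_k) + Σ_k h_k log2(h_k / m_k)
```

after shifting both rows elementwise by δ = 10⁻⁶ (no renormalisation) to
avoid zero-induced degeneracies. The homologue of a reference region is the
minimum-divergence region in the other blueprint; divergence maps can be
thresholded at the 7th percentile to outline the best-matching territory.

**Statistics.** Pairwise subject similarity is the Pearson correlation of
path distributions thresholded at 0.5%, averaged across tracts per pair;
group differences use two-sided Mann–Whitney U tests (exact enumeration for
n+m ≤ 12, tie-corrected normal approximation otherwise) with Bonferroni
correction. Tracer termination tables are binned to a nucleus mask and
converted to per-injection-ROI probability maps, smoothed with a cubic
B-spline kernel and renormalised.

## Worked example

```python
import numpy as np
from subtract import (
    BundleSpec, VoxelGrid, TrackingParams, make_scene,
    make_protocol_for_bundle, track_protocol, normalise,
    symmetric_kl, make_matched_blueprints, match_structures,
)

# a straight zero-dispersion tube on a 32^3 mm grid
grid = VoxelGrid.isotropic((32, 32, 32), 1.0)
tube = BundleSpec.straight("tube", (3, 16, 16), (28, 16, 16), radius=2.0)
scene = make_scene([tube], grid)
protocol = make_protocol_for_bundle(scene, "tube")     # seed & target caps
params = TrackingParams(streamlines_per_seed_voxel=100, rng_seed=0)
pd_map = normalise(track_protocol(scene.field, protocol, params))
print(pd_map.valid_fraction)          # 1.0    — every streamline hits the target
print(round(pd_map.values.max(), 3))  # 0.111  — peak visitation probability

# symmetric KL of two opposed connection patterns
print(round(symmetric_kl([1, 0], [0, 1]), 3))   # 39.863 bits

# homologue matching on matched two-species blueprints
bp_a, bp_b, _ = make_matched_blueprints(
    5, 12, locations_per_region=8, noise=0.1, rng_seed=7, n_cortical=6)
rois = lambda bp: {r: [i for i in bp.row_ids if f"_{r}_" in f"{i}_"]
                   for r in {"_".join(i.split("_")[1:-1]) for i in bp.row_ids}}
_, assignment = match_structures(bp_a, bp_b, rois(bp_a), rois(bp_b))
print(sum(k == v for k, v in assignment.items()))   # 5 — all five recovered
```

A zero-dispersion tube yields a valid fraction of exactly 1.0, with the
peak voxel visited by 11.1% of the valid streamlines (zero-dispersion
streamlines stay in their seeded lane, so no single voxel collects them
all); the opposed indicator patterns give
the analytic 39.863-bit divergence; and five matched synthetic regions are
all re-identified by minimum divergence.

The same pipeline is scriptable from the shell:

```bash
subtract demo --seed 0 --out demo/          # end-to-end phantom pipeline
subtract phantom --kind crossing --out scene/
subtract track --scene scene/ --bundle tx --nseeds 100 --out tx.nii.gz
subtract blueprint --scene scene/ --out bp.h5
```

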