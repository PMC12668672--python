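"""Synthetic fibre phantoms and matched synthetic cohorts.

The generators here provide ground-truth test beds for every analysis in the
package without any external data:

* tube phantoms — straight, curved, or crossing fibre bundles voxelised onto
  a grid, each voxel inside a bundle carrying that bundle's local tangent as
  a fibre population (up to three populations per voxel, as in crossing-fibre
  orientation models);
* endpoint protocols for those bundles (seed at one cap, target at the
  other, optional stop/exclusion masks) mirroring how anatomical protocols
  constrain tracking;
* matched "two-species" connectivity blueprints — each region draws one
  tract profile from a Dirichlet simplex distribution, and both species'
  rows scatter around that shared profile with independent multiplicative
  noise, emulating homologous regions that share a connection pattern;
* family-structured cohorts — each pair of subjects shares a latent bundle
  geometry perturbed by a group-specific within-pair spread (monozygotic
  twins tightest, unrelated pairs independent), emulating heritable tract
  geometry.

All generators are pure functions of (specification, seed); per-object
substreams are derived as ``default_rng([root_seed, *indices])`` so any
single object is reproducible in isolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .blueprint import ConnectivityBlueprint
from .protocols import Protocol
from .tracking import MAX_POPULATIONS, FibreField
from .volumes import (
    BinaryMask,
    ScalarVolume,
    VoxelGrid,
    read_mask,
    read_volume,
    write_mask,
    write_volume,
)

__all__ = [
    "BundleSpec",
    "PhantomScene",
    "make_scene",
    "load_scene",
    "make_protocol_for_bundle",
    "bisecting_exclusion",
    "box_mask",
    "make_matched_blueprints",
    "make_family_cohort",
    "family_scene",
    "make_crossing_scene",
    "make_stratified_scene",
    "ground_truth_terminations",
]


@dataclass
class BundleSpec:
    """A tubular fibre bundle around a polyline centreline (world mm)."""

    name: str
    centreline: np.ndarray  # (n_points, 3) polyline vertices
    radius: float = 2.0
    volume_fraction: float = 0.8
    dispersion_deg: float = 0.0

    def __post_init__(self) -> None:
        self.centreline = np.asarray(self.centreline, dtype=float)
        if self.centreline.ndim != 2 or self.centreline.shape[1] != 3 or len(self.centreline) < 2:
            raise ValueError("centreline must be an (n>=2, 3) array of world points")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if not 0 < self.volume_fraction <= 1:
            raise ValueError("volume fraction must be in (0, 1]")
        if self.dispersion_deg < 0:
            raise ValueError("dispersion must be >= 0")

    @classmethod
    def straight(cls, name, start, end, **kw) -> "BundleSpec":
        return cls(name=name, centreline=np.array([start, end], dtype=float), **kw)

    @classmethod
    def arc(cls, name, centre, radius_mm, start_deg, end_deg, n=33, plane="xy", **kw) -> "BundleSpec":
        """Circular-arc centreline in an axis-aligned plane."""
        ang = np.radians(np.linspace(start_deg, end_deg, n))
        c = np.asarray(centre, dtype=float)
        pts = np.tile(c, (n, 1))
        axes = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}[plane]
        pts[:, axes[0]] += radius_mm * np.cos(ang)
        pts[:, axes[1]] += radius_mm * np.sin(ang)
        return cls(name=name, centreline=pts, **kw)

    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.centreline, axis=0), axis=1).sum())


@dataclass
class PhantomScene:
    grid: VoxelGrid
    bundles: list[BundleSpec]
    field: FibreField
    ground_truth_masks: dict[str, BinaryMask]
    gm_locations: list[tuple[str, np.ndarray]] = field(default_factory=list)
    subcortical_masks: dict[str, BinaryMask] = field(default_factory=dict)

    def bundle(self, name: str) -> BundleSpec:
        for b in self.bundles:
            if b.name == name:
                return b
        raise KeyError(name)

    def wm_mask(self) -> BinaryMask:
        """Union of all bundle ground-truth masks."""
        m = np.zeros(self.grid.shape, dtype=bool)
        for bm in self.ground_truth_masks.values():
            m |= bm.membership
        return BinaryMask(self.grid, m)

    def save(self, out_dir) -> None:
        """NIfTI volumes for field components and masks + a JSON sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        f = self.field
        for p in range(MAX_POPULATIONS):
            write_volume(ScalarVolume(self.grid, f.fractions[..., p]), out / f"f{p}.nii.gz")
            write_volume(ScalarVolume(self.grid, f.dispersions[..., p]), out / f"disp{p}.nii.gz")
            for axis, ax_name in enumerate("xyz"):
                write_volume(
                    ScalarVolume(self.grid, f.orientations[..., p, axis]),
                    out / f"dir{p}_{ax_name}.nii.gz",
                )
        for name, mask in self.ground_truth_masks.items():
            write_mask(mask, out / f"mask_{name}.nii.gz")
        for name, mask in self.subcortical_masks.items():
            write_mask(mask, out / f"nucleus_{name}.nii.gz")
        sidecar = {
            "bundles": [
                {
                    "name": b.name,
                    "centreline": b.centreline.tolist(),
                    "radius": b.radius,
                    "volume_fraction": b.volume_fraction,
                    "dispersion_deg": b.dispersion_deg,
                }
                for b in self.bundles
            ],
            "gm_locations": [[lab, list(map(float, pt))] for lab, pt in self.gm_locations],
            "nuclei": sorted(self.subcortical_masks),
        }
        (out / "scene.json").write_text(json.dumps(sidecar, indent=2))


def load_scene(in_dir) -> PhantomScene:
    """Rebuild a scene from the NIfTI volumes and JSON sidecar of
    :meth:`PhantomScene.save`."""
    src = Path(in_dir)
    sidecar = json.loads((src / "scene.json").read_text())
    bundles = [
        BundleSpec(
            name=b["name"],
            centreline=np.asarray(b["centreline"]),
            radius=b["radius"],
            volume_fraction=b["volume_fraction"],
            dispersion_deg=b["dispersion_deg"],
        )
        for b in sidecar["bundles"]
    ]
    f0 = read_volume(src / "f0.nii.gz")
    grid = f0.grid
    nx, ny, nz = grid.shape
    fractions = np.zeros((nx, ny, nz, MAX_POPULATIONS))
    dispersions = np.zeros_like(fractions)
    orientations = np.zeros((nx, ny, nz, MAX_POPULATIONS, 3))
    for p in range(MAX_POPULATIONS):
        fractions[..., p] = read_volume(src / f"f{p}.nii.gz").values
        dispersions[..., p] = read_volume(src / f"disp{p}.nii.gz").values
        for axis, ax_name in enumerate("xyz"):
            orientations[..., p, axis] = read_volume(src / f"dir{p}_{ax_name}.nii.gz").values
    field_obj = FibreField(
        grid=grid, orientations=orientations, fractions=fractions, dispersions=dispersions
    )
    masks = {b.name: read_mask(src / f"mask_{b.name}.nii.gz") for b in bundles}
    nuclei = {n: read_mask(src / f"nucleus_{n}.nii.gz") for n in sidecar.get("nuclei", [])}
    gm_locations = [(lab, np.asarray(pt, dtype=float)) for lab, pt in sidecar["gm_locations"]]
    return PhantomScene(
        grid=grid,
        bundles=bundles,
        field=field_obj,
        ground_truth_masks=masks,
        gm_locations=gm_locations,
        subcortical_masks=nuclei,
    )


# ---------------------------------------------------------------------------
# geometry helpers


def _polyline_geometry(points: np.ndarray, polyline: np.ndarray):
    """Distance, local tangent, and arclength of the closest point on a
    polyline, for each query point."""
    starts, ends = polyline[:-1], polyline[1:]
    seg = ends - starts
    seg_len = np.linalg.norm(seg, axis=1)
    seg_dir = seg / seg_len[:, None]
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])

    best_d = np.full(len(points), np.inf)
    best_t = np.zeros((len(points), 3))
    best_s = np.zeros(len(points))
    for i in range(len(starts)):
        rel = points - starts[i]
        t = np.clip(rel @ seg_dir[i], 0.0, seg_len[i])
        closest = starts[i] + t[:, None] * seg_dir[i]
        d = np.linalg.norm(points - closest, axis=1)
        upd = d < best_d
        best_d[upd] = d[upd]
        best_t[upd] = seg_dir[i]
        best_s[upd] = cum[i] + t[upd]
    return best_d, best_t, best_s


def box_mask(grid: VoxelGrid, lo_idx, hi_idx) -> BinaryMask:
    """Axis-aligned box of voxels with indices in [lo_idx, hi_idx] inclusive."""
    m = np.zeros(grid.shape, dtype=bool)
    lo = np.maximum(np.asarray(lo_idx, dtype=int), 0)
    hi = np.minimum(np.asarray(hi_idx, dtype=int), np.asarray(grid.shape) - 1)
    m[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = True
    return BinaryMask(grid, m)


# ---------------------------------------------------------------------------
# scenes


def make_scene(
    specs: list[BundleSpec],
    grid: VoxelGrid,
    rng_seed: int = 0,
    nuclei: Optional[dict[str, BinaryMask]] = None,
) -> PhantomScene:
    """Voxelise bundles onto the grid: every voxel whose centre lies within
    ``radius`` of a centreline carries that bundle's local tangent as a fibre
    population; overlap voxels carry one population per bundle (crossing).
    Deterministic given (specs, grid, rng_seed)."""
    names = [b.name for b in specs]
    if len(set(names)) != len(names):
        raise ValueError("bundle names must be unique")
    nx, ny, nz = grid.shape
    idx = np.indices(grid.shape).reshape(3, -1).T
    centres = grid.voxel_to_world(idx)

    field_obj = FibreField.empty(grid)
    pop_count = np.zeros(grid.shape, dtype=int)
    masks: dict[str, BinaryMask] = {}
    gm_locations: list[tuple[str, np.ndarray]] = []
    for b in specs:
        if not np.all(grid.inside(grid.world_to_index(b.centreline))):
            raise ValueError(f"bundle {b.name!r} centreline leaves the grid")
        d, tangents, _ = _polyline_geometry(centres, b.centreline)
        member = d <= b.radius
        if not member.any():
            raise ValueError(f"bundle {b.name!r} occupies no voxels")
        masks[b.name] = BinaryMask(grid, member.reshape(grid.shape))
        for flat in np.flatnonzero(member):
            i, j, k = idx[flat]
            p = pop_count[i, j, k]
            if p >= MAX_POPULATIONS:
                raise ValueError(
                    f"more than {MAX_POPULATIONS} bundles overlap at voxel {(i, j, k)}"
                )
            field_obj.orientations[i, j, k, p] = tangents[flat]
            field_obj.fractions[i, j, k, p] = b.volume_fraction
            field_obj.dispersions[i, j, k, p] = b.dispersion_deg
            pop_count[i, j, k] = p + 1
        gm_locations.append((f"{b.name}_start", b.centreline[0].copy()))
        gm_locations.append((f"{b.name}_end", b.centreline[-1].copy()))
    return PhantomScene(
        grid=grid,
        bundles=list(specs),
        field=field_obj,
        ground_truth_masks=masks,
        gm_locations=gm_locations,
        subcortical_masks=dict(nuclei or {}),
    )


def _cap_masks(scene: PhantomScene, bundle: BundleSpec, cap_depth_mm: float):
    grid = scene.grid
    mask = scene.ground_truth_masks[bundle.name]
    vox = mask.indices()
    centres = grid.voxel_to_world(vox)
    _, _, s = _polyline_geometry(centres, bundle.centreline)
    length = bundle.length()
    if length <= 2 * cap_depth_mm:
        raise ValueError(f"bundle {bundle.name!r} too short for endpoint caps")
    seed_m = np.zeros(grid.shape, dtype=bool)
    targ_m = np.zeros(grid.shape, dtype=bool)
    near = s <= cap_depth_mm
    far = s >= length - cap_depth_mm
    seed_m[vox[near, 0], vox[near, 1], vox[near, 2]] = True
    targ_m[vox[far, 0], vox[far, 1], vox[far, 2]] = True
    return BinaryMask(grid, seed_m), BinaryMask(grid, targ_m)


def make_protocol_for_bundle(
    scene: PhantomScene, bundle_id: str, style: str = "endpoint", cap_depth_mm: float = 1.5
) -> Protocol:
    """Endpoint protocol for a bundle: seed at one cap, target at the other.

    ``symmetric`` additionally sets the flip-and-average flag; ``with-exclusion``
    adds a one-voxel plane the bundle never touches (a null exclusion).
    """
    bundle = scene.bundle(bundle_id)
    seed, target = _cap_masks(scene, bundle, cap_depth_mm)
    if seed.is_empty or target.is_empty or np.any(seed.membership & target.membership):
        raise ValueError(f"bundle {bundle_id!r} is degenerate for endpoint caps")
    exclusions: list[BinaryMask] = []
    if style == "with-exclusion":
        exclusions = [_null_plane(scene, bundle_id)]
    elif style not in ("endpoint", "symmetric"):
        raise ValueError(f"unknown protocol style {style!r}")
    return Protocol(
        name=f"{bundle_id}_{style}",
        seed=seed,
        targets=[target],
        exclusions=exclusions,
        symmetric=(style == "symmetric"),
        laterality="unilateral",
    )


def _null_plane(scene: PhantomScene, bundle_id: str) -> BinaryMask:
    """An axis-aligned one-voxel plane disjoint from the bundle."""
    gt = scene.ground_truth_masks[bundle_id].membership
    for axis in range(3):
        occupied = gt.any(axis=tuple(a for a in range(3) if a != axis))
        free = np.flatnonzero(~occupied)
        if free.size:
            m = np.zeros(scene.grid.shape, dtype=bool)
            sl = [slice(None)] * 3
            sl[axis] = int(free[0])
            m[tuple(sl)] = True
            return BinaryMask(scene.grid, m)
    raise ValueError("no free plane available for a null exclusion")


def bisecting_exclusion(scene: PhantomScene, bundle_id: str) -> BinaryMask:
    """A one-voxel plane through the bundle's midpoint, perpendicular to its
    local course — blocks every streamline along the bundle."""
    bundle = scene.bundle(bundle_id)
    mid_s = bundle.length() / 2.0
    # walk the polyline to the midpoint
    pts = bundle.centreline
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    i = int(np.searchsorted(cum, mid_s) - 1)
    i = max(0, min(i, len(seg_len) - 1))
    t = (mid_s - cum[i]) / seg_len[i]
    mid_point = pts[i] + t * (pts[i + 1] - pts[i])
    tangent = (pts[i + 1] - pts[i]) / seg_len[i]
    axis = int(np.argmax(np.abs(tangent)))
    plane_idx = int(scene.grid.world_to_index(mid_point)[axis])
    m = np.zeros(scene.grid.shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[axis] = plane_idx
    m[tuple(sl)] = True
    return BinaryMask(scene.grid, m)


# ---------------------------------------------------------------------------
# matched two-species blueprints


def make_matched_blueprints(
    n_regions: int,
    n_tracts: int,
    locations_per_region: int = 10,
    concentration: float = 0.5,
    noise: float = 0.1,
    rng_seed: int = 0,
    n_cortical: int = 0,
    cortical_region_sd: float = 0.1,
) -> tuple[ConnectivityBlueprint, ConnectivityBlueprint, list[str]]:
    """Two 'species' blueprints whose homologous regions share a tract profile.

    Per region one profile is drawn from a Dirichlet simplex distribution;
    both blueprints draw their rows around that shared profile with
    independent multiplicative log-normal noise, then row-normalise. With
    ``n_cortical > 0`` the first ``n_cortical`` tracts are cortico-cortical
    and deliberately uninformative (all regions scatter around one common
    cortico-cortical base pattern with spread ``cortical_region_sd``) while
    the remaining cortico-subcortical tracts carry the region identity —
    the setting in which subcortical tracts improve homologue matching.
    """
    if n_regions < 2 or n_tracts < 2:
        raise ValueError("need at least 2 regions and 2 tracts")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if not 0 <= n_cortical < n_tracts:
        raise ValueError("n_cortical must be in [0, n_tracts)")
    rng = np.random.default_rng([rng_seed, 0])
    n_cs = n_tracts - n_cortical
    if n_cortical:
        tract_names = [f"cc_{i}" for i in range(n_cortical)] + [f"cs_{i}" for i in range(n_cs)]
        classes = {
            t: ("cortico-cortical" if t.startswith("cc_") else "cortico-subcortical")
            for t in tract_names
        }
        cc_base = rng.dirichlet(np.full(n_cortical, 4.0))
    else:
        tract_names = [f"cs_{i}" for i in range(n_tracts)]
        classes = {t: "cortico-subcortical" for t in tract_names}
        cc_base = None

    regions = [f"region_{r}" for r in range(n_regions)]
    profiles = {}
    w_cc = n_cortical / n_tracts
    for r, region in enumerate(regions):
        r_rng = np.random.default_rng([rng_seed, 1, r])
        cs = r_rng.dirichlet(np.full(n_cs, concentration))
        if n_cortical:
            cc = cc_base * np.exp(cortical_region_sd * r_rng.normal(size=n_cortical))
            cc = cc / cc.sum()
            profiles[region] = np.concatenate([w_cc * cc, (1 - w_cc) * cs])
        else:
            profiles[region] = cs

    def _species(tag: str, sub: int) -> ConnectivityBlueprint:
        rows, row_ids = [], []
        for r, region in enumerate(regions):
            for loc in range(locations_per_region):
                s_rng = np.random.default_rng([rng_seed, 2 + sub, r, loc])
                row = profiles[region] * np.exp(noise * s_rng.normal(size=n_tracts))
                rows.append(row / row.sum())
                row_ids.append(f"{tag}_{region}_{loc}")
        return ConnectivityBlueprint(
            row_ids=row_ids,
            tract_names=list(tract_names),
            matrix=np.vstack(rows),
            row_kinds=["cortical"] * len(row_ids),
            row_normalised=True,
            tract_classes=dict(classes),
        )

    labels = [region for region in regions for _ in range(locations_per_region)]
    return _species("A", 0), _species("B", 1), labels


# ---------------------------------------------------------------------------
# family cohorts

DEFAULT_WITHIN_PAIR_SD = {"MZ": 0.1, "DZ": 0.5, "sib": 0.5, "unrelated": None}


def family_scene(theta: np.ndarray, dispersion_deg: float = 4.0) -> PhantomScene:
    """One subject's scene: a single bundle whose mid-course lateral offset
    (dy, dz) is the heritable geometry parameter."""
    grid = VoxelGrid.isotropic((20, 16, 16), 1.0)
    dy, dz = float(np.clip(theta[0], -4, 4)), float(np.clip(theta[1], -4, 4))
    centreline = np.array(
        [[2.0, 8.0, 8.0], [10.0, 8.0 + dy, 8.0 + dz], [18.0, 8.0, 8.0]]
    )
    spec = BundleSpec(
        name="bundle",
        centreline=centreline,
        radius=1.6,
        volume_fraction=0.8,
        dispersion_deg=dispersion_deg,
    )
    return make_scene([spec], grid)


def make_family_cohort(
    n_pairs_per_group: int,
    groups: tuple[str, ...] = ("MZ", "DZ", "sib", "unrelated"),
    heritable_param_sd: float = 1.5,
    within_pair_sd: Optional[dict[str, Optional[float]]] = None,
    rng_seed: int = 0,
    dispersion_deg: float = 4.0,
) -> list[tuple[str, PhantomScene, PhantomScene]]:
    """Cohort of scene pairs: each pair shares a latent bundle-geometry
    vector perturbed by the group's within-pair spread; unrelated pairs draw
    independent geometries. Within-pair spreads must satisfy
    MZ <= DZ, sib (twin-structure ordering)."""
    if not groups:
        raise ValueError("empty group list")
    sds = dict(DEFAULT_WITHIN_PAIR_SD)
    if within_pair_sd:
        sds.update(within_pair_sd)
    for g in groups:
        if g not in sds:
            raise ValueError(f"no within-pair sd for group {g!r}")
    if "MZ" in sds and any(
        sds.get(g) is not None and sds["MZ"] is not None and sds[g] < sds["MZ"]
        for g in ("DZ", "sib")
        if g in groups
    ):
        raise ValueError("within-pair spreads must be ordered MZ <= DZ, sib")

    cohort: list[tuple[str, PhantomScene, PhantomScene]] = []
    for gi, group in enumerate(groups):
        for p in range(n_pairs_per_group):
            rng = np.random.default_rng([rng_seed, gi, p])
            if sds[group] is None:  # unrelated: independent geometries
                th_a = rng.normal(0.0, heritable_param_sd, size=2)
                th_b = rng.normal(0.0, heritable_param_sd, size=2)
            else:
                latent = rng.normal(0.0, heritable_param_sd, size=2)
                th_a = latent + rng.normal(0.0, sds[group], size=2)
                th_b = latent + rng.normal(0.0, sds[group], size=2)
            cohort.append(
                (
                    group,
                    family_scene(th_a, dispersion_deg),
                    family_scene(th_b, dispersion_deg),
                )
            )
    return cohort


# ---------------------------------------------------------------------------
# special-purpose scenes for the subcortical analyses


def make_crossing_scene(rng_seed: int = 0) -> PhantomScene:
    """Two orthogonal bundles crossing mid-grid, each terminating in its own
    nucleus: 'tx' ends in nucleus A, 'ty' in nucleus B. The crossing region
    carries two fibre populations — the configuration under which a direct
    path-distribution intersection stays nucleus-specific while the
    intermediary whole-brain construction leaks across bundles."""
    grid = VoxelGrid.isotropic((32, 32, 32), 1.0)
    tx = BundleSpec.straight("tx", (2.0, 16.0, 16.0), (29.0, 16.0, 16.0), radius=2.0)
    ty = BundleSpec.straight("ty", (16.0, 2.0, 16.0), (16.0, 29.0, 16.0), radius=2.0)
    nuclei = {
        "nucA": box_mask(grid, (26, 13, 13), (29, 19, 19)),
        "nucB": box_mask(grid, (13, 26, 13), (19, 29, 19)),
    }
    return make_scene([tx, ty], grid, rng_seed=rng_seed, nuclei=nuclei)


def make_stratified_scene(
    layer_labels: tuple[str, ...] = ("frontal", "sensorimotor", "parietal", "temporal"),
    rng_seed: int = 0,
) -> PhantomScene:
    """Parallel bundles from distinct 'cortical' sources terminating in
    stratified layers of one nucleus — the topography setting in which the
    dominant-label pattern of tractography should match tracer terminations."""
    n = len(layer_labels)
    grid = VoxelGrid.isotropic((24, 16, 4 + 5 * n), 1.0)
    specs = []
    for li, lab in enumerate(layer_labels):
        z = 4.0 + 5.0 * li
        specs.append(
            BundleSpec.straight(lab, (2.0, 8.0, z), (21.0, 8.0, z), radius=1.5)
        )
    nucleus = box_mask(grid, (16, 5, 2), (21, 11, int(4 + 5 * n) - 3))
    return make_scene(specs, grid, rng_seed=rng_seed, nuclei={"nucleus": nucleus})


def ground_truth_terminations(scene: PhantomScene, nucleus: str = "nucleus"):
    """Tracer-style termination table: one termination per bundle voxel
    inside the nucleus, labelled by the bundle's source."""
    import pandas as pd

    mask = scene.subcortical_masks[nucleus]
    rows = []
    for b in scene.bundles:
        inter = scene.ground_truth_masks[b.name].membership & mask.membership
        for ijk in np.argwhere(inter):
            x, y, z = scene.grid.voxel_to_world(ijk)
            rows.append({"x": x, "y": y, "z": z, "label": b.name, "case": b.name})
    return pd.DataFrame(rows)
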