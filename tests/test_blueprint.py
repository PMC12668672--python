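import numpy as np
import pytest

from subtract import (
    ConnectivityBlueprint,
    TrackingParams,
    assemble,
    box_mask,
    build_gm_wm,
    build_wm_tracts,
    cortical_blueprint,
    make_protocol_for_bundle,
    normalise,
    subcortical_blueprint,
    track_protocol,
    tract_mass_fraction,
)
from subtract.blueprint import GMWMMatrix, WMTractsMatrix
from subtract.phantom import make_crossing_scene
from subtract.tracking import PathDistribution
from subtract.volumes import BinaryMask, VoxelGrid


@pytest.fixture(scope="module")
def crossing_maps():
    """Normalised path distributions for both bundles of the crossing scene."""
    scene = make_crossing_scene()
    params = TrackingParams(streamlines_per_seed_voxel=25, rng_seed=1)
    maps = {}
    for b in scene.bundles:
        prot = make_protocol_for_bundle(scene, b.name)
        maps[b.name] = normalise(track_protocol(scene.field, prot, params))
    return scene, maps


def _pd(grid, values, normalised=True):
    return PathDistribution(grid=grid, values=values, n_valid=1, normalised=normalised)


class TestBuildGmWm:
    def test_tube_cap_row_mass_inside_tube(self, tube_scene):
        params = TrackingParams(streamlines_per_seed_voxel=20, rng_seed=0)
        wm = tube_scene.wm_mask()
        gmwm = build_gm_wm(tube_scene.field, [("cap", np.array([4.0, 16.0, 16.0]))], wm, params)
        row = gmwm.matrix[0]
        assert row.sum() > 0
        # WM columns are the tube itself, so all counted mass is in-tube
        assert (row >= 0).all()
        # most streamline visits fall in tube voxels (the WM mask)
        assert row.sum() >= 0.9 * params.streamlines_per_seed_voxel

    def test_background_location_gives_zero_row(self, tube_scene):
        params = TrackingParams(streamlines_per_seed_voxel=10, rng_seed=0)
        wm = tube_scene.wm_mask()
        gmwm = build_gm_wm(tube_scene.field, [("bg", np.array([16.0, 2.0, 2.0]))], wm, params)
        assert gmwm.matrix[0].sum() == 0

    def test_identical_locations_same_substream_row(self, tube_scene):
        params = TrackingParams(streamlines_per_seed_voxel=10, rng_seed=0)
        wm = tube_scene.wm_mask()
        pt = np.array([4.0, 16.0, 16.0])
        a = build_gm_wm(tube_scene.field, [("p", pt)], wm, params)
        b = build_gm_wm(tube_scene.field, [("p", pt)], wm, params)
        assert np.array_equal(a.matrix, b.matrix)

    def test_empty_wm_mask_rejected(self, tube_scene):
        empty = BinaryMask(tube_scene.grid, np.zeros(tube_scene.grid.shape, dtype=bool))
        with pytest.raises(ValueError, match="empty WM"):
            build_gm_wm(tube_scene.field, [("p", np.array([4.0, 16.0, 16.0]))], empty, TrackingParams())


class TestBuildWmTracts:
    def test_restriction_to_wm_voxels(self):
        grid = VoxelGrid.isotropic((4, 4, 4), 1.0)
        values = np.zeros(grid.shape)
        values[1, 1, 1] = 0.4
        values[3, 3, 3] = 0.7  # outside the WM mask
        wm = np.zeros(grid.shape, dtype=bool)
        wm[1, 1, 1] = True
        wm[2, 2, 2] = True
        wmt = build_wm_tracts({"t": _pd(grid, values)}, BinaryMask(grid, wm))
        assert wmt.matrix.shape == (2, 1)
        assert set(wmt.matrix[:, 0]) == {0.4, 0.0}

    def test_unnormalised_input_rejected(self):
        grid = VoxelGrid.isotropic((3, 3, 3), 1.0)
        wm = BinaryMask(grid, np.ones(grid.shape, dtype=bool))
        raw = PathDistribution(grid=grid, values=np.zeros(grid.shape), n_valid=1, normalised=False)
        with pytest.raises(ValueError, match="not normalised"):
            build_wm_tracts({"t": raw}, wm)

    def test_disjoint_tracts_give_orthogonal_columns(self):
        grid = VoxelGrid.isotropic((4, 4, 4), 1.0)
        a = np.zeros(grid.shape)
        b = np.zeros(grid.shape)
        a[0, 0, 0] = 0.5
        b[1, 1, 1] = 0.5
        wm = BinaryMask(grid, np.ones(grid.shape, dtype=bool))
        wmt = build_wm_tracts({"a": _pd(grid, a), "b": _pd(grid, b)}, wm)
        assert wmt.matrix[:, 0] @ wmt.matrix[:, 1] == 0


class TestCorticalBlueprint:
    def test_unit_row_product(self):
        wm_voxels = np.array([[0, 0, 0], [1, 1, 1]])
        gmwm = GMWMMatrix(row_ids=["g"], wm_voxels=wm_voxels, matrix=np.array([[1.0, 0.0]]))
        wmt = WMTractsMatrix(
            wm_voxels=wm_voxels, tract_names=["t1", "t2"], matrix=np.array([[0.2, 0.8], [0.5, 0.5]])
        )
        bp = cortical_blueprint(gmwm, wmt)
        assert np.allclose(bp.matrix, [[0.2, 0.8]])

    def test_linearity_in_counts(self):
        wm_voxels = np.array([[0, 0, 0], [1, 1, 1]])
        wmt = WMTractsMatrix(
            wm_voxels=wm_voxels, tract_names=["t1", "t2"], matrix=np.array([[0.2, 0.8], [0.5, 0.5]])
        )
        base = np.array([[2.0, 3.0]])
        bp1 = cortical_blueprint(GMWMMatrix(["g"], wm_voxels, base), wmt)
        bp3 = cortical_blueprint(GMWMMatrix(["g"], wm_voxels, 3 * base), wmt)
        assert np.allclose(bp3.matrix, 3 * bp1.matrix)

    def test_id_mismatch_rejected(self):
        gmwm = GMWMMatrix(["g"], np.array([[0, 0, 0]]), np.array([[1.0]]))
        wmt = WMTractsMatrix(np.array([[1, 1, 1]]), ["t"], np.array([[0.5]]))
        with pytest.raises(ValueError, match="do not match"):
            cortical_blueprint(gmwm, wmt)


class TestSubcorticalBlueprint:
    def test_threshold_zeroes_small_values(self):
        grid = VoxelGrid.isotropic((4, 4, 4), 1.0)
        values = np.zeros(grid.shape)
        values[1, 1, 1] = 0.0005  # below the 0.1% cut
        values[2, 2, 2] = 0.3
        mask = np.zeros(grid.shape, dtype=bool)
        mask[1, 1, 1] = mask[2, 2, 2] = True
        bp = subcortical_blueprint({"t": _pd(grid, values)}, {"nuc": BinaryMask(grid, mask)})
        by_row = dict(zip(bp.row_ids, bp.matrix[:, 0]))
        assert by_row["nuc:1,1,1"] == 0.0
        assert by_row["nuc:2,2,2"] == pytest.approx(0.3)

    def test_rows_only_for_mask_voxels(self):
        grid = VoxelGrid.isotropic((4, 4, 4), 1.0)
        mask = np.zeros(grid.shape, dtype=bool)
        mask[0, 0, 0] = True
        bp = subcortical_blueprint(
            {"t": _pd(grid, np.zeros(grid.shape))}, {"nuc": BinaryMask(grid, mask)}
        )
        assert bp.row_ids == ["nuc:0,0,0"]

    def test_downsample_then_threshold_order(self):
        # a 0.002 value diluted by block-mean over 8 voxels falls below the
        # threshold only if downsampling happens first
        grid = VoxelGrid.isotropic((4, 4, 4), 1.0)
        values = np.zeros(grid.shape)
        values[0, 0, 0] = 0.002
        mask2 = np.ones((2, 2, 2), dtype=bool)
        from subtract.volumes import downsample as ds, ScalarVolume

        coarse_grid = ds(ScalarVolume(grid, values), 2.0).grid
        bp = subcortical_blueprint(
            {"t": _pd(grid, values)},
            {"nuc": BinaryMask(coarse_grid, mask2)},
            threshold=0.001,
            target_voxel_mm=2.0,
        )
        assert bp.matrix.sum() == 0.0

    def test_empty_mask_set_rejected(self):
        grid = VoxelGrid.isotropic((3, 3, 3), 1.0)
        with pytest.raises(ValueError):
            subcortical_blueprint({"t": _pd(grid, np.zeros(grid.shape))}, {})


class TestAssemble:
    def _bp(self, rows, ids, kind):
        return ConnectivityBlueprint(
            row_ids=ids, tract_names=["t1", "t2", "t3"], matrix=np.asarray(rows, dtype=float),
            row_kinds=[kind] * len(ids),
        )

    def test_sum_normalisation(self):
        out = assemble(self._bp([[2, 2, 4]], ["c"], "cortical"), self._bp([[1, 1, 0]], ["s"], "subcortical"))
        assert np.allclose(out.matrix[0], [0.25, 0.25, 0.5])
        assert np.allclose(out.matrix[1], [0.5, 0.5, 0.0])
        assert out.row_normalised

    def test_idempotent_on_normalised_rows(self):
        bp = self._bp([[0.25, 0.25, 0.5]], ["c"], "cortical")
        out = assemble(bp, self._bp([[1, 0, 0]], ["s"], "subcortical"))
        assert np.allclose(out.matrix[0], [0.25, 0.25, 0.5])

    def test_zero_rows_reported(self):
        out = assemble(self._bp([[0, 0, 0]], ["c"], "cortical"), self._bp([[1, 0, 0]], ["s"], "subcortical"))
        assert out.zero_rows == ["c"]
        assert np.allclose(out.matrix[0], 0)

    def test_column_mismatch_rejected(self):
        a = self._bp([[1, 0, 0]], ["c"], "cortical")
        b = ConnectivityBlueprint(
            row_ids=["s"], tract_names=["x", "y", "z"], matrix=np.array([[1.0, 0, 0]]),
            row_kinds=["subcortical"],
        )
        with pytest.raises(ValueError, match="columns differ"):
            assemble(a, b)


class TestSpecificity:
    def test_direct_intersection_more_specific_than_intermediary(self, crossing_maps):
        scene, maps = crossing_maps
        direct = subcortical_blueprint(maps, scene.subcortical_masks, threshold=0.001).normalised()

        wm = scene.wm_mask()
        gm_locs = [
            (f"{lab}:{i},{j},{k}", scene.grid.voxel_to_world((i, j, k)))
            for lab, mask in scene.subcortical_masks.items()
            for i, j, k in mask.indices()
        ]
        params = TrackingParams(streamlines_per_seed_voxel=8, rng_seed=2)
        gmwm = build_gm_wm(scene.field, gm_locs, wm, params)
        wmt = build_wm_tracts(maps, wm)
        intermediary = cortical_blueprint(gmwm, wmt).normalised()

        frac_direct = tract_mass_fraction(direct, "tx", "nucA")
        frac_inter = tract_mass_fraction(intermediary, "tx", "nucA")
        assert frac_direct / frac_inter > 1.0

    def test_hdf5_round_trip(self, crossing_maps, tmp_path):
        scene, maps = crossing_maps
        bp = subcortical_blueprint(maps, scene.subcortical_masks).normalised()
        bp.tract_classes = {t: "cortico-subcortical" for t in bp.tract_names}
        path = tmp_path / "bp.h5"
        bp.save(path)
        back = ConnectivityBlueprint.load(path)
        assert np.allclose(back.matrix, bp.matrix)
        assert back.row_ids == bp.row_ids
        assert back.tract_names == bp.tract_names
        assert back.tract_classes == bp.tract_classes
        assert back.row_normalised
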