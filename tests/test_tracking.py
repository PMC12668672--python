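import math

import numpy as np
import pytest
from scipy import ndimage

from subtract import (
    BinaryMask,
    BundleSpec,
    FibreField,
    Protocol,
    TrackingParams,
    VoxelGrid,
    make_protocol_for_bundle,
    make_scene,
    normalise,
    propagate,
    run_symmetric,
    sample_direction,
    track_protocol,
)
from subtract.tracking import NO_FIBRE


def single_population_field(direction=(1.0, 0.0, 0.0), f=0.8, dispersion=0.0, shape=(8, 8, 8)):
    grid = VoxelGrid.isotropic(shape, 1.0)
    field = FibreField.empty(grid)
    field.orientations[..., 0, :] = np.asarray(direction) / np.linalg.norm(direction)
    field.fractions[..., 0] = f
    field.dispersions[..., 0] = dispersion
    return field


class TestSampleDirection:
    def test_deterministic_field_returns_mean(self, rng):
        field = single_population_field()
        d = sample_direction(field, (4, 4, 4), np.array([1.0, 0, 0]), TrackingParams(), rng)
        assert np.allclose(d, [1, 0, 0])

    def test_axial_sign_disambiguation(self, rng):
        field = single_population_field()
        d = sample_direction(field, (4, 4, 4), np.array([-1.0, 0, 0]), TrackingParams(), rng)
        assert np.allclose(d, [-1, 0, 0])

    def test_subthreshold_population_is_no_fibre(self, rng):
        # a 0.5% fraction falls below the default 1% volume-fraction threshold
        field = single_population_field(f=0.005)
        d = sample_direction(field, (4, 4, 4), None, TrackingParams(), rng)
        assert d is NO_FIBRE

    def test_best_aligned_population_chosen(self, rng):
        field = single_population_field()
        field.orientations[4, 4, 4, 1] = [0.0, 1.0, 0.0]
        field.fractions[4, 4, 4, 1] = 0.9
        d = sample_direction(field, (4, 4, 4), np.array([1.0, 0, 0]), TrackingParams(), rng)
        assert np.allclose(d, [1, 0, 0])


class TestPropagate:
    def test_straight_tube_spans_and_terminates_at_caps(self, tube_scene):
        params = TrackingParams(rng_seed=0)
        seed = np.array([16.0, 16.0, 16.0])
        sl = propagate(tube_scene.field, seed, params, rng=np.random.default_rng(0))
        assert sl.reasons[0] in ("left-field", "no-fibre")
        assert sl.reasons[1] in ("left-field", "no-fibre")
        xs = sl.points[:, 0]
        assert xs.min() <= 4.0 and xs.max() >= 27.0
        # consecutive points exactly one step apart
        steps = np.linalg.norm(np.diff(sl.points, axis=0), axis=1)
        assert np.allclose(steps, params.step_size, atol=1e-9)

    def test_right_angle_turn_terminates_with_curvature(self):
        # two abutting fields: +x fibres for x<4, +y fibres for x>=4
        grid = VoxelGrid.isotropic((8, 8, 8), 1.0)
        field = FibreField.empty(grid)
        field.orientations[:4, ..., 0, :] = [1.0, 0.0, 0.0]
        field.orientations[4:, ..., 0, :] = [0.0, 1.0, 0.0]
        field.fractions[..., 0] = 0.8
        params = TrackingParams(step_size=1.0)
        sl = propagate(field, np.array([1.0, 4.0, 4.0]), params, rng=np.random.default_rng(0))
        assert "curvature" in sl.reasons  # 90 degrees exceeds the 80-degree threshold

    def test_looping_field_exhausts_max_steps(self):
        # tangential (circular) fibre field around the grid centre
        grid = VoxelGrid.isotropic((16, 16, 3), 1.0)
        field = FibreField.empty(grid)
        idx = np.indices(grid.shape).reshape(3, -1).T
        centres = grid.voxel_to_world(idx) - np.array([7.5, 7.5, 1.0])
        tang = np.stack([-centres[:, 1], centres[:, 0], np.zeros(len(centres))], axis=1)
        norm = np.linalg.norm(tang, axis=1)
        ok = norm > 1e-6
        tang[ok] /= norm[ok, None]
        for flat, t in zip(range(len(idx)), tang):
            i, j, k = idx[flat]
            if ok[flat]:
                field.orientations[i, j, k, 0] = t
                field.fractions[i, j, k, 0] = 0.8
        params = TrackingParams(step_size=0.5, max_steps=40)
        sl = propagate(field, np.array([7.5, 2.5, 1.0]), params, rng=np.random.default_rng(0))
        assert "max-steps" in sl.reasons

    def test_seed_outside_grid_rejected(self, tube_scene):
        with pytest.raises(ValueError):
            propagate(tube_scene.field, np.array([-5.0, 0.0, 0.0]), TrackingParams())


class TestTrackProtocol:
    def test_zero_dispersion_tube_valid_fraction_is_one(self, tube_distribution):
        assert tube_distribution.valid_fraction == 1.0

    def test_mass_confined_to_dilated_tube(self, tube_scene, tube_distribution):
        gt = tube_scene.ground_truth_masks["tube"].membership
        dilated = ndimage.binary_dilation(gt, iterations=1)
        total = tube_distribution.values.sum()
        assert tube_distribution.values[dilated].sum() / total >= 0.99

    def test_bisecting_exclusion_invalidates_everything(self, tube_scene, tube_protocol, fast_params):
        from subtract import bisecting_exclusion

        prot = Protocol(
            name="cut",
            seed=tube_protocol.seed,
            targets=list(tube_protocol.targets),
            exclusions=[bisecting_exclusion(tube_scene, "tube")],
        )
        pd_map = track_protocol(tube_scene.field, prot, fast_params)
        assert pd_map.n_valid == 0
        assert pd_map.values.sum() == 0

    def test_no_mass_beyond_stop_mask(self, tube_scene, tube_protocol, fast_params):
        grid = tube_scene.grid
        stop = np.zeros(grid.shape, dtype=bool)
        stop[24, :, :] = True  # plane before the target cap would kill validity,
        prot = Protocol(  # so put the target before the stop plane
            name="stopped",
            seed=tube_protocol.seed,
            targets=[BinaryMask(grid, _plane(grid, x=20))],
            stop=BinaryMask(grid, stop),
        )
        pd_map = track_protocol(tube_scene.field, prot, fast_params)
        assert pd_map.n_valid > 0
        assert pd_map.values[25:, :, :].sum() == 0

    def test_reproducible_bit_identical(self, tube_scene, tube_protocol):
        params = TrackingParams(streamlines_per_seed_voxel=5, rng_seed=42)
        a = track_protocol(tube_scene.field, tube_protocol, params)
        b = track_protocol(tube_scene.field, tube_protocol, params)
        assert np.array_equal(a.values, b.values)
        assert a.n_valid == b.n_valid

    def test_normalised_values_are_probabilities(self, tube_distribution):
        assert tube_distribution.normalised
        assert tube_distribution.values.max() <= 1.0
        assert tube_distribution.values.min() >= 0.0


def _plane(grid, x):
    m = np.zeros(grid.shape, dtype=bool)
    m[x, :, :] = True
    return m


class TestCurvatureContract:
    def test_retained_direction_pairs_respect_threshold(self):
        # dispersed field: every retained consecutive step must stay within 80 deg
        grid = VoxelGrid.isotropic((20, 20, 20), 1.0)
        spec = BundleSpec.straight(
            "b", (2.0, 10.0, 10.0), (17.0, 10.0, 10.0), radius=3.0, dispersion_deg=25.0
        )
        scene = make_scene([spec], grid)
        params = TrackingParams(step_size=1.0, rng_seed=7)
        cos_thr = math.cos(math.radians(params.curvature_threshold))
        for s in range(20):
            sl = propagate(
                scene.field,
                np.array([10.0, 10.0, 10.0]),
                params,
                rng=np.random.default_rng([7, s]),
            )
            d = np.diff(sl.points, axis=0)
            d /= np.linalg.norm(d, axis=1)[:, None]
            dots = (d[:-1] * d[1:]).sum(axis=1)
            assert (dots >= cos_thr - 1e-9).all()


class TestNormalise:
    def test_count_arithmetic(self, tube_scene):
        from subtract.tracking import PathDistribution

        values = np.zeros(tube_scene.grid.shape)
        values[0, 0, 0] = 2.0
        values[1, 0, 0] = 4.0
        pd_map = PathDistribution(grid=tube_scene.grid, values=values, n_valid=4)
        out = normalise(pd_map)
        assert out.values[0, 0, 0] == pytest.approx(0.5)
        assert out.values[1, 0, 0] == pytest.approx(1.0)

    def test_zero_valid_returns_zero_map(self, tube_scene, caplog):
        from subtract.tracking import PathDistribution

        pd_map = PathDistribution(grid=tube_scene.grid, values=np.zeros(tube_scene.grid.shape), n_valid=0)
        with caplog.at_level("WARNING"):
            out = normalise(pd_map)
        assert out.values.sum() == 0
        assert any("zero valid" in r.message for r in caplog.records)

    def test_double_normalisation_rejected(self, tube_distribution):
        with pytest.raises(ValueError):
            normalise(tube_distribution)


class TestRunSymmetric:
    def test_symmetric_average_of_identical_runs(self, tube_scene):
        prot = make_protocol_for_bundle(tube_scene, "tube", style="symmetric")
        params = TrackingParams(streamlines_per_seed_voxel=10, rng_seed=3)
        avg = run_symmetric(tube_scene.field, prot, params)
        fwd = normalise(track_protocol(tube_scene.field, prot, params))
        # tube is symmetric under seed<->target swap: averaged map stays a
        # probability map supported on the same voxels
        assert avg.normalised
        assert set(map(tuple, np.argwhere(avg.values > 0.5))) == set(
            map(tuple, np.argwhere(fwd.values > 0.5))
        )

    def test_requires_flag(self, tube_scene, tube_protocol, fast_params):
        with pytest.raises(ValueError):
            run_symmetric(tube_scene.field, tube_protocol, fast_params)

    def test_one_way_passable_field_averages_to_half(self):
        # target sits in fibre-free space just beyond the tube cap: the
        # forward run exits the tube into it (valid), the flipped run seeds
        # in no-fibre space and yields zero valid streamlines -> average A/2
        grid = VoxelGrid.isotropic((24, 12, 12), 1.0)
        spec = BundleSpec.straight("b", (2.0, 6.0, 6.0), (16.0, 6.0, 6.0), radius=1.5)
        scene = make_scene([spec], grid)
        prot = make_protocol_for_bundle(scene, "b", style="symmetric")
        beyond_cap = np.zeros(grid.shape, dtype=bool)
        beyond_cap[18:20, 4:9, 4:9] = True
        prot_one_way = Protocol(
            name="oneway",
            seed=prot.seed,
            targets=[BinaryMask(grid, beyond_cap)],
            symmetric=True,
        )
        params = TrackingParams(streamlines_per_seed_voxel=5, rng_seed=1)
        avg = run_symmetric(scene.field, prot_one_way, params)
        fwd = normalise(track_protocol(scene.field, prot_one_way, params))
        assert fwd.n_valid > 0
        assert avg.n_valid == fwd.n_valid  # reverse run contributed nothing
        assert np.allclose(avg.values, fwd.values / 2.0)
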