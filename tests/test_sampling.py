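"""Oracles and property tests for the five down-sampling strategies."""

import itertools

import numpy as np
import pytest
from scipy import stats

from plantcloud import (
    LabeledPointCloud,
    VoxelSpec,
    auto_voxel_size,
    fps,
    rs,
    rs_then_fps,
    sample,
    sbf,
    threedeps,
    uvs,
    vfps,
    voxelize,
)
from plantcloud.sampling import fps_indices, rs_indices

from conftest import random_cloud


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def fps_oracle(coords, n, start):
    """Brute-force greedy max-min selection recomputing all distances."""
    coords = np.asarray(coords, dtype=float)
    selected = [start]
    while len(selected) < n:
        best, best_d = None, -1.0
        for i in range(len(coords)):
            if i in selected:
                continue
            d = min(np.linalg.norm(coords[i] - coords[j]) for j in selected)
            if d > best_d:
                best, best_d = i, d
        selected.append(best)
    return selected


class TestFPS:
    def test_collinear_hand_example(self):
        # points at x = 0, 1, 4, 9, 10: from 0 the farthest is 10, then the
        # max-min point is 4 (min distance 4 beats 1's 1 and 9's 1)
        coords = np.array([[0, 0, 0], [1, 0, 0], [4, 0, 0],
                           [9, 0, 0], [10, 0, 0]], dtype=float)
        idx = fps_indices(coords, 3, start=0)
        assert idx.tolist() == [0, 4, 2]

    def test_n_equals_N_is_permutation(self, rng):
        coords = rng.normal(size=(30, 3))
        idx = fps_indices(coords, 30, seed=5)
        assert sorted(idx.tolist()) == list(range(30))

    def test_n_one_returns_start(self, rng):
        coords = rng.normal(size=(10, 3))
        assert fps_indices(coords, 1, start=7).tolist() == [7]

    @pytest.mark.parametrize("N", [8, 15, 30, 50])
    def test_matches_bruteforce_oracle_all_starts(self, N):
        rng = np.random.default_rng(N)
        coords = rng.normal(size=(N, 3))
        n = max(2, N // 2)
        for start in range(N):
            fast = fps_indices(coords, n, start=start)
            assert fast.tolist() == fps_oracle(coords, n, start)

    def test_minmax_distance_nonincreasing_in_n(self, rng):
        coords = rng.normal(size=(60, 3))
        prev = np.inf
        for n in range(2, 30):
            idx = fps_indices(coords, n, start=0)
            pts = coords[idx]
            dmin = min(
                np.linalg.norm(pts[i] - pts[j])
                for i, j in itertools.combinations(range(n), 2)
            )
            assert dmin <= prev + 1e-12
            prev = dmin

    def test_out_of_range_targets_rejected(self, rng):
        coords = rng.normal(size=(5, 3))
        for bad in (0, 6):
            with pytest.raises(ValueError):
                fps_indices(coords, bad)

    def test_carries_labels(self, rng):
        cloud = random_cloud(rng, 40, labeled=True)
        res = fps(cloud, 10, seed=3)
        assert np.array_equal(res.sem, cloud.sem[res.indices])
        assert np.array_equal(res.ins, cloud.ins[res.indices])


class TestRS:
    def test_n_equals_N_takes_everything(self):
        assert rs_indices(7, 7, seed=0).tolist() == list(range(7))

    @pytest.mark.parametrize("seed", range(30))
    def test_strictly_increasing_exact_count(self, seed):
        idx = rs_indices(100, 37, seed=seed)
        assert len(idx) == 37
        assert (np.diff(idx) > 0).all()
        assert 0 <= idx[0] and idx[-1] < 100

    def test_uniform_without_replacement_chisquare(self):
        """Every 3-subset of 6 points appears with frequency 1/20."""
        subsets = list(itertools.combinations(range(6), 3))
        lookup = {s: i for i, s in enumerate(subsets)}
        counts = np.zeros(len(subsets))
        n_draws = 20_000
        for seed in range(n_draws):
            drawn = tuple(rs_indices(6, 3, seed=seed).tolist())
            counts[lookup[drawn]] += 1
        result = stats.chisquare(counts)
        assert result.pvalue > 0.01

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rs_indices(5, 6)


class TestVoxelize:
    def test_giant_voxel_holds_all(self, rng):
        coords = rng.uniform(size=(50, 3))
        vox = voxelize(coords, VoxelSpec(10, 10, 10))
        assert len(vox) == 1
        (members,) = vox.values()
        assert sorted(members.tolist()) == list(range(50))

    def test_floor_convention(self):
        coords = np.array([[0.1, 0, 0], [1.1, 0, 0]])
        vox = voxelize(coords, VoxelSpec(1, 1, 1, origin=(0, 0, 0)))
        assert set(vox) == {(0, 0, 0), (1, 0, 0)}

    def test_partition_property(self, rng):
        coords = rng.normal(size=(200, 3))
        vox = voxelize(coords, VoxelSpec(0.7, 0.9, 1.1))
        all_members = np.concatenate(list(vox.values()))
        assert sorted(all_members.tolist()) == list(range(200))

    def test_nonpositive_edge_rejected(self):
        with pytest.raises(ValueError):
            VoxelSpec(0, 1, 1)


class TestUVS:
    def test_identity_when_one_point_per_voxel(self, rng):
        coords = np.array([[i, 0, 0] for i in range(10)], dtype=float)
        res = uvs(LabeledPointCloud(coords=coords), 10,
                  VoxelSpec(1, 1, 1), seed=0)
        assert sorted(res.indices.tolist()) == list(range(10))

    def test_nearest_to_center_survives(self):
        # one voxel [0,1)^3 with centre (0.5, 0.5, 0.5)
        coords = np.array([[0.4, 0.5, 0.5], [0.9, 0.5, 0.5], [0.5, 0.9, 0.9]])
        res = uvs(LabeledPointCloud(coords=coords), 1,
                  VoxelSpec(1, 1, 1, origin=(0, 0, 0)), seed=0)
        assert res.indices.tolist() == [0]

    def test_voxel_stage_matches_bruteforce(self, rng):
        coords = rng.normal(size=(300, 3))
        spec = VoxelSpec(0.8, 0.8, 0.8)
        vox = voxelize(coords, spec)
        origin = coords.min(axis=0)
        expected = set()
        for key, members in vox.items():
            center = origin + (np.array(key) + 0.5) * spec.edges
            d = np.linalg.norm(coords[members] - center, axis=1)
            expected.add(int(members[np.argmin(d)]))
        res = uvs(LabeledPointCloud(coords=coords), len(vox), spec, seed=0)
        assert set(res.indices.tolist()) == expected

    def test_too_few_voxels_is_an_error(self, rng):
        coords = rng.uniform(size=(50, 3))
        with pytest.raises(ValueError, match="auto_voxel_size"):
            uvs(LabeledPointCloud(coords=coords), 50, VoxelSpec(10, 10, 10))


class TestVFPS:
    def test_centroid_of_two_points(self):
        coords = np.array([[0.0, 0.1, 0.1], [1.0, 0.1, 0.1],
                           [5.0, 0.1, 0.1]])
        spec = VoxelSpec(2, 2, 2, origin=(0, 0, 0))
        res = vfps(LabeledPointCloud(coords=coords), 2, spec, seed=0)
        got = {tuple(np.round(c, 6)) for c in res.coords}
        assert (0.5, 0.1, 0.1) in got

    def test_centroids_inside_their_cells(self, rng):
        coords = rng.normal(size=(400, 3))
        spec = VoxelSpec(0.9, 0.7, 1.2, origin=tuple(coords.min(axis=0)))
        vox = voxelize(coords, spec)
        res = vfps(LabeledPointCloud(coords=coords), len(vox), spec, seed=0)
        origin = coords.min(axis=0)
        cells = np.floor((res.coords - origin) / spec.edges)
        # each centroid's own cell must be an occupied cell
        occupied = set(vox)
        for cell in cells.astype(int):
            assert tuple(cell) in occupied

    def test_voxel_stage_matches_groupby_mean(self, rng):
        coords = rng.normal(size=(300, 3))
        spec = VoxelSpec(0.8, 0.8, 0.8)
        vox = voxelize(coords, spec)
        expected = {
            tuple(np.round(coords[m].mean(axis=0), 9)) for m in vox.values()
        }
        res = vfps(LabeledPointCloud(coords=coords), len(vox), spec, seed=0)
        got = {tuple(np.round(c, 9)) for c in res.coords}
        assert got == expected

    def test_majority_label_transfer(self):
        coords = np.array([[0.1, 0, 0], [0.2, 0, 0], [0.3, 0, 0]])
        cloud = LabeledPointCloud(coords=coords, sem=[1, 1, 0],
                                  ins=[0, 0, -1], n_classes=2)
        res = vfps(cloud, 1, VoxelSpec(1, 1, 1, origin=(0, 0, 0)), seed=0)
        assert res.indices is None
        assert res.sem.tolist() == [1]
        assert res.ins.tolist() == [0]


class TestSBF:
    def test_planar_grid_interior_not_edge(self):
        xs, ys = np.meshgrid(np.arange(15), np.arange(15))
        coords = np.column_stack(
            [xs.ravel(), ys.ravel(), np.zeros(xs.size)]
        ).astype(float)
        mask = sbf(coords, k=8, tau=0.5)
        center = 7 * 15 + 7
        assert not mask.flags[center]

    def test_segment_endpoint_is_edge(self):
        coords = np.column_stack(
            [np.arange(50, dtype=float), np.zeros(50), np.zeros(50)]
        )
        mask = sbf(coords, k=6, tau=0.5)
        assert mask.flags[0] and mask.flags[49]
        assert not mask.flags[25]

    def test_disk_edges_concentrate_on_rim(self):
        rng = np.random.default_rng(7)
        r = np.sqrt(rng.uniform(size=3000))
        theta = rng.uniform(0, 2 * np.pi, 3000)
        coords = np.column_stack(
            [r * np.cos(theta), r * np.sin(theta), np.zeros(3000)]
        )
        mask = sbf(coords, k=20, tau=0.5)
        assert 0 < mask.flags.sum() < len(coords)
        assert r[mask.flags].mean() > r[~mask.flags].mean()

    def test_partition_of_cloud(self, rng):
        coords = rng.normal(size=(100, 3))
        mask = sbf(coords, k=10)
        union = np.union1d(mask.edge_indices, mask.internal_indices)
        assert np.array_equal(union, np.arange(100))
        assert len(np.intersect1d(mask.edge_indices,
                                  mask.internal_indices)) == 0

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            sbf(rng.normal(size=(10, 3)), k=10)


class Test3DEPS:
    def test_exact_edge_count_when_parts_suffice(self, dicot_plant):
        res = threedeps(dicot_plant, 2000, ratio=0.2, seed=3)
        mask = sbf(dicot_plant.coords, k=20, tau=0.5)
        n_edge_selected = mask.flags[res.indices].sum()
        assert res.n == 2000
        assert len(np.unique(res.indices)) == 2000
        assert n_edge_selected == min(400, mask.flags.sum())

    def test_deficit_spills_to_internal(self, rng):
        # a near-uniform ball has few SBF edge points; force |B| < target
        coords = rng.normal(size=(500, 3))
        mask = sbf(coords, k=20, tau=0.5)
        n_b = int(mask.flags.sum())
        n = min(500, n_b + 450)
        res = threedeps(LabeledPointCloud(coords=coords), n,
                        ratio=0.9, seed=1)
        selected_edges = mask.flags[res.indices].sum()
        expected_edges = min(round(0.9 * n), n_b)
        assert res.n == n
        assert selected_edges == expected_edges

    def test_ratio_zero_selects_internal_first(self, rng):
        coords = rng.normal(size=(300, 3))
        mask = sbf(coords, k=20, tau=0.5)
        n_c = int((~mask.flags).sum())
        n = min(50, n_c)
        res = threedeps(LabeledPointCloud(coords=coords), n,
                        ratio=0.0, seed=2)
        assert mask.flags[res.indices].sum() == 0

    @pytest.mark.parametrize("ratio", [0.1, 0.3, 0.5])
    def test_bookkeeping_across_ratios(self, monocot_plant, ratio):
        n = 1000
        res = threedeps(monocot_plant, n, ratio=ratio, seed=9)
        mask = sbf(monocot_plant.coords, k=20, tau=0.5)
        expected = min(round(ratio * n), int(mask.flags.sum()))
        assert mask.flags[res.indices].sum() == expected


class TestAutoVoxel:
    def test_target_one_trivially_bracketed(self, rng):
        coords = rng.uniform(size=(100, 3))
        spec = auto_voxel_size(coords, 1)
        assert len(voxelize(coords, spec)) <= 2

    def test_regular_lattice(self):
        g = np.arange(10, dtype=float)
        coords = np.array(
            [[x, y, z] for x in g for y in g for z in g]
        )
        spec = auto_voxel_size(coords, 500)
        occ = len(voxelize(coords, spec))
        assert 500 <= occ <= 1000

    @pytest.mark.parametrize("seed", range(5))
    def test_postcondition_bracket_random_clouds(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(2000, 3))
        n_target = int(rng.integers(50, 800))
        spec = auto_voxel_size(coords, n_target)
        occ = len(voxelize(coords, spec))
        assert n_target <= occ <= 2 * n_target

    def test_duplicate_degenerate_cloud_rejected(self):
        coords = np.repeat([[1.0, 2.0, 3.0]], 50, axis=0)
        with pytest.raises(ValueError, match="unique"):
            auto_voxel_size(coords, 10)


class TestRsThenFps:
    def test_skip_stage_equals_fps(self, rng):
        coords = rng.normal(size=(200, 3))
        a = rs_then_fps(LabeledPointCloud(coords=coords), 50,
                        intermediate=200, seed=4)
        b = rs_then_fps(LabeledPointCloud(coords=coords), 50,
                        intermediate=10_000, seed=4)
        assert a.indices.tolist() == b.indices.tolist()

    def test_structural_contract(self, dicot_plant):
        res = rs_then_fps(dicot_plant, 500, intermediate=2000, seed=6)
        assert res.n == 500
        assert len(np.unique(res.indices)) == 500
        assert res.indices.max() < dicot_plant.n_points
        np.testing.assert_array_equal(
            res.coords, dicot_plant.coords[res.indices]
        )

    def test_n_above_intermediate_rejected(self, dicot_plant):
        with pytest.raises(ValueError):
            rs_then_fps(dicot_plant, 3000, intermediate=2000)


class TestStrategyContracts:
    @pytest.mark.parametrize("strategy", ["fps", "rs", "uvs", "vfps",
                                          "3deps", "rsfps"])
    def test_exact_count_unique_indices_determinism(self, dicot_plant,
                                                    strategy):
        kwargs = {}
        if strategy == "rsfps":
            kwargs["intermediate"] = 6000
        res1 = sample(dicot_plant, strategy, 1024, seed=42, **kwargs)
        res2 = sample(dicot_plant, strategy, 1024, seed=42, **kwargs)
        assert res1.n == 1024
        np.testing.assert_array_equal(res1.coords, res2.coords)
        if res1.indices is not None:
            assert len(np.unique(res1.indices)) == 1024
            np.testing.assert_array_equal(res1.indices, res2.indices)
        if dicot_plant.sem is not None and res1.indices is not None:
            np.testing.assert_array_equal(
                res1.sem, dicot_plant.sem[res1.indices]
            )

    @pytest.mark.parametrize("strategy", ["fps", "rs", "uvs", "vfps",
                                          "3deps"])
    def test_different_seeds_differ(self, dicot_plant, strategy):
        res1 = sample(dicot_plant, strategy, 512, seed=1)
        res2 = sample(dicot_plant, strategy, 512, seed=2)
        assert not np.array_equal(res1.coords, res2.coords)
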