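import warnings

import numpy as np
import pytest

from los3d import (
    Clump,
    ClusteringError,
    DegenerateClumpError,
    SamplingPolicy,
    SurfacePointSet,
    cluster_los,
    decompose_clump,
    distance_transform,
    generate_phantom,
    label_surface_points,
    label_voxels,
    optimize_surface_labels,
    sample_pairs,
    select_los,
    surface_points,
    two_ball_spec,
)
from los3d.phantom import _chain_spec
from conftest import digital_ball


class TestSurfacePoints:
    def test_single_voxel(self):
        sps = surface_points(Clump(np.ones((1, 1, 1), bool), (0, 0, 0)))
        np.testing.assert_array_equal(sps.points, [[0, 0, 0]])

    def test_cube_surface_is_all_but_center(self):
        sps = surface_points(Clump(np.ones((3, 3, 3), bool), (0, 0, 0)))
        assert sps.n == 26
        assert [1, 1, 1] not in sps.points.tolist()

    def test_ball_surface_has_unit_edt(self):
        mask = digital_ball(6, pad=0)
        sps = surface_points(Clump(mask, (0, 0, 0)))
        d = distance_transform(Clump(mask, (0, 0, 0)))
        vals = d[sps.points[:, 0], sps.points[:, 1], sps.points[:, 2]]
        np.testing.assert_array_equal(vals, 1.0)

    def test_lexicographic_order(self):
        sps = surface_points(Clump(np.ones((3, 3, 3), bool), (0, 0, 0)))
        assert sps.points.tolist() == sorted(sps.points.tolist())


class TestSamplingPolicy:
    def test_band_rates(self):
        policy = SamplingPolicy()
        assert policy.sample_count(500) == 50
        assert policy.sample_count(50_000) == 1500
        assert policy.sample_count(200_000) == 4000
        # boundary values fall in the middle band
        assert policy.sample_count(1000) == 30
        assert policy.sample_count(100_000) == 3000

    def test_pair_count_for_500_points(self):
        pts = np.argwhere(np.ones((8, 8, 8), bool))[:500]
        sps = SurfacePointSet(points=pts, labels=np.zeros(500, int))
        pairs = sample_pairs(sps, rng_seed=0)
        assert pairs.shape == (50 * 49 // 2, 2, 3)  # 1225 pairs

    def test_minimum_of_two_points(self):
        pts = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2]])
        sps = SurfacePointSet(points=pts, labels=np.zeros(3, int))
        assert len(sample_pairs(sps, rng_seed=0)) >= 1

    def test_degenerate_surface_rejected(self):
        sps = SurfacePointSet(points=np.array([[0, 0, 0]]), labels=np.zeros(1, int))
        with pytest.raises(DegenerateClumpError):
            sample_pairs(sps, rng_seed=0)

    def test_seeded_determinism(self):
        pts = np.argwhere(np.ones((10, 10, 10), bool))[:700]
        sps = SurfacePointSet(points=pts, labels=np.zeros(700, int))
        a = sample_pairs(sps, rng_seed=5)
        b = sample_pairs(sps, rng_seed=5)
        np.testing.assert_array_equal(a, b)


class TestSelectLos:
    def test_nearly_all_pairs_kept_on_convex_ball(self):
        # a continuous ball keeps every chord; a digital ball loses a small
        # fraction of near-tangent chords to voxel rounding at the surface
        mask = digital_ball(6, pad=1)
        clump = Clump(mask, (0, 0, 0))
        sps = surface_points(clump)
        pairs = sample_pairs(sps, rng_seed=1)
        lines = select_los(clump, pairs)
        assert len(lines) >= 0.95 * len(pairs)
        # interior-to-interior chords (both endpoints off-tangent) all survive
        center = np.array(mask.shape) // 2
        deep = np.linalg.norm(pairs.astype(float) - center, axis=2).max(axis=1) < 5
        kept = select_los(clump, pairs[deep])
        assert len(kept) == deep.sum()

    def test_dumbbell_pole_to_pole_rejected(self):
        # two radius-6 balls bridged by a thin 2-voxel-wide neck
        mask = np.zeros((17, 17, 34), bool)
        zz, yy, xx = np.indices(mask.shape)
        mask |= (zz - 8) ** 2 + (yy - 8) ** 2 + (xx - 8) ** 2 <= 36
        mask |= (zz - 8) ** 2 + (yy - 8) ** 2 + (xx - 25) ** 2 <= 36
        bridge = (np.abs(zz - 8) <= 1) & (np.abs(yy - 8) <= 1) & (xx > 8) & (xx < 25)
        mask |= bridge
        poles = np.array([[[8, 8, 2], [8, 8, 31]]])
        assert len(select_los(Clump(mask, (0, 0, 0)), poles)) == 1  # bridge is on-axis
        off_axis = np.array([[[8, 2, 8], [8, 14, 25]]])  # crosses outside the bridge
        assert len(select_los(Clump(mask, (0, 0, 0)), off_axis)) == 0

    def test_adjacent_surface_points_kept(self):
        mask = np.ones((2, 2, 2), bool)
        pair = np.array([[[0, 0, 0], [0, 0, 1]]])
        assert len(select_los(Clump(mask, (0, 0, 0)), pair)) == 1

    def test_canonical_endpoint_order(self):
        mask = np.ones((3, 3, 3), bool)
        pair = np.array([[[2, 2, 2], [0, 0, 0]]])
        lines = select_los(Clump(mask, (0, 0, 0)), pair)
        assert lines[0, 0].tolist() <= lines[0, 1].tolist()

    def test_visibility_sound_under_finer_resampling(self, fused_pair):
        # every emitted line stays foreground when probed 10x more densely,
        # except where the segment merely touches a background voxel's cell
        # corner (chebyshev distance exactly 0.5) without crossing it
        _, truth = fused_pair
        clump = Clump(truth.labels > 0, (0, 0, 0))
        sps = surface_points(clump)
        pairs = sample_pairs(sps, rng_seed=3)
        lines = select_los(clump, pairs, step_fraction=0.001)
        assert_visibility_sound(clump.mask, lines)


def assert_visibility_sound(mask, lines, fine_step=0.0001):
    """Dense re-sampling oracle: a kept line may fail a 10x-finer probe only
    at voxels the continuous segment touches (ℓ∞ distance 0.5 from center)
    without entering — i.e. it never crosses background cell interiors."""
    t = np.arange(0.0, 1.0 + fine_step / 2, fine_step)
    for line in lines:
        a, b = line.astype(float)
        probes = a + t[:, None] * (b - a)
        idx = np.rint(probes).astype(int)
        bad = ~mask[idx[:, 0], idx[:, 1], idx[:, 2]]
        for voxel in np.unique(idx[bad], axis=0):
            dist = np.abs(probes - voxel).max(axis=1).min()
            assert dist >= 0.5 - 1e-6, (
                f"line {line.tolist()} crosses background voxel {voxel.tolist()}"
            )


class TestClusterLos:
    def _lines(self, n, rng):
        pts = rng.integers(0, 20, (n, 2, 3))
        return pts

    def test_k_one_single_label(self, rng):
        labels = cluster_los(self._lines(10, rng), 1)
        assert set(labels) == {1}

    def test_k_equals_n_distinct_labels(self, rng):
        labels = cluster_los(self._lines(7, rng), 7)
        assert sorted(labels) == list(range(1, 8))

    def test_too_few_lines_rejected(self, rng):
        with pytest.raises(ClusteringError):
            cluster_los(self._lines(3, rng), 5)

    def test_two_ball_lines_cluster_by_half_space(self):
        img, truth = generate_phantom(two_ball_spec(6, 6, 1.5))
        clump = Clump(truth.labels > 0, (0, 0, 0))
        sps = surface_points(clump)
        pairs = sample_pairs(sps, rng_seed=2)
        lines = select_los(clump, pairs)
        labels = cluster_los(lines, 2)
        mid = truth.centroids[:, 2].mean()
        in_a = (lines[:, :, 2] < mid).all(axis=1)
        in_b = (lines[:, :, 2] > mid).all(axis=1)
        purity = max(
            np.concatenate([labels[in_a] == 1, labels[in_b] == 2]).mean(),
            np.concatenate([labels[in_a] == 2, labels[in_b] == 1]).mean(),
        )
        assert purity >= 0.8


class TestLabelSurfacePoints:
    def _sps(self):
        pts = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2]])
        return SurfacePointSet(points=pts, labels=np.zeros(3, int))

    def test_majority_wins(self):
        lines = np.array([[[0, 0, 0], [0, 0, 1]], [[0, 0, 0], [0, 0, 2]], [[0, 0, 0], [0, 0, 1]]])
        out = label_surface_points(self._sps(), lines, np.array([1, 1, 2]), rng_seed=0)
        assert out.labels[0] == 1

    def test_tie_drawn_reproducibly(self):
        lines = np.array([[[0, 0, 0], [0, 0, 1]], [[0, 0, 0], [0, 0, 2]]])
        a = label_surface_points(self._sps(), lines, np.array([1, 2]), rng_seed=7)
        b = label_surface_points(self._sps(), lines, np.array([1, 2]), rng_seed=7)
        assert a.labels[0] in (1, 2)
        assert a.labels[0] == b.labels[0]

    def test_point_without_lines_stays_unlabelled(self):
        lines = np.array([[[0, 0, 0], [0, 0, 1]]])
        out = label_surface_points(self._sps(), lines, np.array([1]), rng_seed=0)
        assert out.labels[2] == 0


class TestOptimizeSurfaceLabels:
    def test_uniform_labels_unchanged(self):
        mask = digital_ball(4, pad=1)
        sps = surface_points(Clump(mask, (0, 0, 0)))
        sps = SurfacePointSet(sps.points, np.ones(sps.n, int))
        out = optimize_surface_labels(sps)
        np.testing.assert_array_equal(out.labels, 1)

    def test_single_mislabelled_point_corrected(self):
        sps = surface_points(Clump(np.ones((5, 5, 5), bool), (0, 0, 0)))
        labels = np.ones(sps.n, int)
        labels[10] = 2
        out = optimize_surface_labels(SurfacePointSet(sps.points, labels))
        np.testing.assert_array_equal(out.labels, 1)

    def test_two_patches_preserved_away_from_interface(self):
        img, truth = generate_phantom(two_ball_spec(6, 6, 1.5))
        clump = Clump(truth.labels > 0, (0, 0, 0))
        sps = surface_points(clump)
        # seed labels from the truth half-spaces
        mid = truth.centroids[:, 2].mean()
        labels = np.where(sps.points[:, 2] < mid, 1, 2)
        out = optimize_surface_labels(SurfacePointSet(sps.points, labels))
        away = np.abs(sps.points[:, 2] - mid) > 1
        assert (out.labels[away] == labels[away]).all()

    def test_unlabelled_input_rejected(self):
        sps = surface_points(Clump(np.ones((3, 3, 3), bool), (0, 0, 0)))
        with pytest.raises(Exception):
            optimize_surface_labels(sps)

    def test_resolves_all_points_from_sparse_anchors(self):
        mask = digital_ball(6, pad=1)
        sps = surface_points(Clump(mask, (0, 0, 0)))
        labels = np.zeros(sps.n, int)
        labels[0] = 1
        labels[-1] = 2
        out = optimize_surface_labels(SurfacePointSet(sps.points, labels))
        assert (out.labels > 0).all()


class TestLabelVoxels:
    def test_uniform_surface_labels_everything(self):
        mask = digital_ball(4, pad=1)
        clump = Clump(mask, (0, 0, 0))
        sps = surface_points(clump)
        sps = SurfacePointSet(sps.points, np.ones(sps.n, int))
        out = label_voxels(clump, sps, rng_seed=0)
        assert (out[mask] == 1).all()
        assert (out[~mask] == 0).all()

    def test_partition_covers_clump_exactly(self, fused_pair):
        _, truth = fused_pair
        clump = Clump(truth.labels > 0, (0, 0, 0))
        out = decompose_clump(clump, 2, rng_seed=0)
        assert ((out > 0) == clump.mask).all()


class TestDecomposeClump:
    def test_fused_pair_recovers_centers(self, fused_pair):
        _, truth = fused_pair
        clump = Clump(truth.labels > 0, (0, 0, 0))
        out = decompose_clump(clump, 2, rng_seed=0)
        assert out.max() == 2
        for lab in (1, 2):
            c = np.argwhere(out == lab).mean(axis=0)
            err = np.linalg.norm(truth.centroids - c, axis=1).min()
            assert err < 2.0

    def test_three_chain_volumes(self):
        _, truth = generate_phantom(_chain_spec([8, 8, 8], spacing=12))
        clump = Clump(truth.labels > 0, (0, 0, 0))
        out = decompose_clump(clump, 3, rng_seed=0)
        assert out.max() == 3
        single = digital_ball(8).sum()
        for lab in (1, 2, 3):
            vol = (out == lab).sum()
            assert abs(vol - single) / single < 0.25

    def test_unequal_pair_smaller_and_larger(self):
        _, truth = generate_phantom(two_ball_spec(6, 10, 1.4))
        clump = Clump(truth.labels > 0, (0, 0, 0))
        out = decompose_clump(clump, 2, rng_seed=0)
        vols = sorted((out == lab).sum() for lab in (1, 2))
        assert out.max() == 2
        assert vols[0] < vols[1]

    def test_conservation_of_foreground(self, fused_pair):
        _, truth = fused_pair
        clump = Clump(truth.labels > 0, (0, 0, 0))
        out = decompose_clump(clump, 2, rng_seed=1)
        assert (out > 0).sum() == clump.voxel_count

    def test_seeded_determinism(self, fused_pair):
        _, truth = fused_pair
        clump = Clump(truth.labels > 0, (0, 0, 0))
        a = decompose_clump(clump, 2, rng_seed=9)
        b = decompose_clump(clump, 2, rng_seed=9)
        np.testing.assert_array_equal(a, b)

    def test_degenerate_clump_returned_unsplit(self):
        clump = Clump(np.ones((1, 1, 1), bool), (0, 0, 0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = decompose_clump(clump, 2, rng_seed=0)
        assert out[0, 0, 0] == 1
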