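"""Registration, linking, track assembly and growth curves."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roottrack import (
    ImageFrame,
    Roi,
    build_tracks,
    cumulative_growth,
    growth_magnitude,
    link_rois,
    register_frames,
)
from roottrack.model import IntegrityError

RES = (3.33, 0.23, 0.23)
ISO = (1.0, 1.0, 1.0)


def _bright(voxels, n=0, resolution=RES):
    return ImageFrame(np.asarray(voxels, np.float32), resolution, n, "brightfield")


def _roi(label, n, centroid):
    return Roi(
        label=label,
        timestamp_index=n,
        voxel_coords=np.array([[0, 0, 0]]),
        centroid_um=np.asarray(centroid, float),
        volume_voxels=1,
        mean_intensity=1.0,
        max_intensity=1.0,
    )


class TestRegistration:
    def test_identical_frames_give_zero_shift(self, rng):
        vox = rng.normal(size=(4, 16, 16))
        d = register_frames(_bright(vox, 0), _bright(vox, 1))
        np.testing.assert_array_equal(d, [0, 0, 0])

    @pytest.mark.parametrize("shift", [(0, 3, 0), (1, 0, -2), (0, -4, 1)])
    def test_circular_shift_recovered_exactly(self, rng, shift):
        vox = rng.normal(size=(6, 24, 20))
        moved = np.roll(vox, shift, axis=(0, 1, 2))
        d = register_frames(_bright(vox, 0), _bright(moved, 1))
        np.testing.assert_array_equal(d, shift)

    def test_phantom_drift_recovered(self, small_scene):
        _, bright, truth = small_scene
        for n in range(len(bright) - 1):
            d = register_frames(bright[n], bright[n + 1])
            assert np.all(np.abs(d - truth.drift_voxels[n]) <= 0.5)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            register_frames(_bright(rng.normal(size=(2, 4, 4))), _bright(rng.normal(size=(2, 4, 5))))


class TestGrowthMagnitude:
    def test_zero_displacement(self):
        assert growth_magnitude([0, 0, 0], RES) == 0.0

    def test_lateral_displacement_uses_lateral_resolution(self):
        assert growth_magnitude([0, 10, 0], RES) == pytest.approx(2.3)

    def test_axial_displacement_uses_axial_resolution(self):
        assert growth_magnitude([1, 0, 0], RES) == pytest.approx(3.33)

    def test_mixed_axes_combine_anisotropically(self):
        expected = np.sqrt(3.33**2 + (5 * 0.23) ** 2)
        assert growth_magnitude([1, 5, 0], RES) == pytest.approx(expected)


class TestCumulativeGrowth:
    def test_prefix_sum(self):
        curve = cumulative_growth([1.0, 2.0, 3.0])
        np.testing.assert_allclose(curve.cumulative_um, [0, 1, 3, 6])

    def test_all_zero(self):
        np.testing.assert_array_equal(cumulative_growth([0, 0]).cumulative_um, [0, 0, 0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cumulative_growth([1.0, -0.5])

    def test_cumulative_is_non_decreasing(self, rng):
        curve = cumulative_growth(rng.uniform(0, 3, size=50))
        assert np.all(np.diff(curve.cumulative_um) >= 0)


class TestLinkRois:
    def test_drift_corrected_match(self):
        a = [_roi(1, 0, [0, 10, 0])]
        b = [_roi(1, 1, [0, 11.15, 0])]  # 5 lateral voxels further along y
        pairs = link_rois(a, b, [0, 5, 0], RES, max_link_distance_um=1.0)
        assert pairs == [(0, 0)]

    def test_unmatched_when_next_frame_empty(self):
        assert link_rois([_roi(1, 0, [0, 0, 0])], [], [0, 0, 0], RES) == []

    def test_gate_excludes_distant_pairs(self):
        a = [_roi(1, 0, [0, 0, 0])]
        b = [_roi(1, 1, [0, 30, 0])]
        assert link_rois(a, b, [0, 0, 0], ISO, max_link_distance_um=5.0) == []

    def test_one_to_one_even_with_shared_nearest(self):
        a = [_roi(1, 0, [0, 0, 0]), _roi(2, 0, [0, 4, 0])]
        b = [_roi(1, 1, [0, 1, 0])]
        pairs = link_rois(a, b, [0, 0, 0], ISO, max_link_distance_um=10.0)
        assert pairs == [(0, 0)]

    def _brute_force_optimal(self, positions_a, positions_b, gate):
        """Minimal-total-distance one-to-one assignment by enumeration."""
        best, best_cost = [], np.inf
        na, nb = len(positions_a), len(positions_b)
        k = min(na, nb)
        for subset_a in itertools.permutations(range(na), k):
            for subset_b in itertools.permutations(range(nb), k):
                pairs = [
                    (i, j)
                    for i, j in zip(subset_a, subset_b)
                    if np.linalg.norm(positions_a[i] - positions_b[j]) <= gate
                ]
                cost = sum(np.linalg.norm(positions_a[i] - positions_b[j]) for i, j in pairs)
                # prefer more matches, then lower cost
                key = (-len(pairs), cost)
                if key < (-len(best), best_cost):
                    best, best_cost = pairs, cost
        return sorted(best)

    def test_well_separated_pair_matches_brute_force(self):
        positions = [np.array([0.0, 0.0, 0.0]), np.array([0.0, 20.0, 0.0])]
        a = [_roi(i + 1, 0, p) for i, p in enumerate(positions)]
        b = [_roi(i + 1, 1, p) for i, p in enumerate(positions)]
        pairs = link_rois(a, b, [0, 0, 0], ISO, max_link_distance_um=5.0)
        assert sorted(pairs) == self._brute_force_optimal(positions, positions, 5.0)
        assert sorted(pairs) == [(0, 0), (1, 1)]

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_greedy_equals_optimal_on_separated_instances(self, seed):
        """When target points sit much closer to their own source than to any
        other, greedy nearest-centroid matching equals the brute-force
        minimal-cost assignment."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 5))
        # sources on a coarse grid (>= 30 apart), targets jittered by <= 1
        grid = rng.choice(np.arange(0, 300, 30), size=n, replace=False).astype(float)
        sources = [np.array([0.0, g, 0.0]) for g in grid]
        targets = [s + rng.uniform(-1, 1, 3) for s in sources]
        order = rng.permutation(n)
        a = [_roi(i + 1, 0, sources[i]) for i in range(n)]
        b = [_roi(j + 1, 1, targets[order[j]]) for j in range(n)]
        pairs = link_rois(a, b, [0, 0, 0], ISO, max_link_distance_um=5.0)
        expected = self._brute_force_optimal(
            [r.centroid_um for r in a], [r.centroid_um for r in b], 5.0
        )
        assert sorted(pairs) == expected
        assert len(pairs) == n


class TestBuildTracks:
    def _chain(self, n_frames, n_rois_per_frame):
        rois = [
            [_roi(k + 1, n, [0.0, 10.0 * k, 0.0]) for k in range(n_rois_per_frame)]
            for n in range(n_frames)
        ]
        assignments = [[(k, k) for k in range(n_rois_per_frame)] for _ in range(n_frames - 1)]
        return rois, assignments

    def test_nine_sample_chain_has_three_hour_persistency(self):
        rois, assignments = self._chain(9, 1)
        tracks = build_tracks(rois, assignments, dt_hours=1 / 3)
        assert len(tracks) == 1
        assert tracks[0].persistency_h == pytest.approx(3.0)

    def test_isolated_roi_persistency_is_one_sample(self):
        tracks = build_tracks([[_roi(1, 0, [0, 0, 0])]], [], dt_hours=1 / 3)
        assert tracks[0].persistency_h == pytest.approx(1 / 3)

    def test_five_parallel_tracks_over_ten_frames(self):
        rois, assignments = self._chain(10, 5)
        tracks = build_tracks(rois, assignments, dt_hours=1 / 3)
        assert len(tracks) == 5
        assert all(t.persistency_h == pytest.approx(10 / 3) for t in tracks)

    def test_every_roi_in_exactly_one_track(self, rng):
        n_frames = 8
        rois = [
            [_roi(k + 1, n, rng.normal(size=3)) for k in range(int(rng.integers(0, 4)))]
            for n in range(n_frames)
        ]
        assignments = []
        for n in range(n_frames - 1):
            k = min(len(rois[n]), len(rois[n + 1]))
            assignments.append([(i, i) for i in range(k)])
        tracks = build_tracks(rois, assignments, dt_hours=0.5)
        assert sum(len(t.rois) for t in tracks) == sum(len(r) for r in rois)

    def test_conflicting_assignment_rejected(self):
        rois = [[_roi(1, 0, [0, 0, 0]), _roi(2, 0, [0, 5, 0])], [_roi(1, 1, [0, 0, 0])]]
        with pytest.raises(IntegrityError):
            build_tracks(rois, [[(0, 0), (1, 0)]], dt_hours=1.0)
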