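"""The ten metric signals, the low-pass filter, replicate averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roottrack import (
    METRIC_NAMES,
    MetricPanel,
    Roi,
    Track,
    average_replicates,
    compute_metric_panel,
    lowpass_filter,
)


def _track(track_id, first, length, dt=1 / 3, tip=None, center=None):
    rois = []
    for i in range(length):
        rois.append(
            Roi(
                label=track_id,
                timestamp_index=first + i,
                voxel_coords=np.array([[0, 0, 0]]),
                centroid_um=np.zeros(3),
                volume_voxels=1,
                tip_distance_um=float("nan") if tip is None else tip,
                center_distance_um=float("nan") if center is None else center,
            )
        )
    return Track(track_id=track_id, rois=rois, dt_hours=dt)


def random_tracks(rng, n_frames):
    tracks = []
    for track_id in range(int(rng.integers(1, 12))):
        length = int(rng.integers(1, n_frames + 1))
        first = int(rng.integers(0, n_frames - length + 1))
        tracks.append(
            _track(track_id, first, length, tip=float(rng.uniform(0, 50)), center=float(rng.uniform(0, 10)))
        )
    return tracks


class TestMetricPanel:
    def test_hand_enumerated_two_track_fixture(self):
        # A spans frames 0-2, B spans 1-3; both persistency 1.0 h at dt=1/3
        tracks = [_track(0, 0, 3), _track(1, 1, 3)]
        panel = compute_metric_panel(tracks, n_frames=4, dt_hours=1 / 3)
        v = panel.values
        k = {name: i for i, name in enumerate(METRIC_NAMES)}
        assert v[k["average_number"], 1] == 2
        assert v[k["new_appearance"], 1] == 1
        assert v[k["track_end"], 1] == 0
        assert v[k["persistency_average"], 1] == pytest.approx(1.0)
        assert v[k["persistency_spread"], 1] == 0.0
        assert v[k["persistency_additive"], 1] == pytest.approx(2.0)
        assert v[k["track_end"], 2] == 1

    def test_no_tracks_gives_zero_counts_and_missing_rest(self):
        panel = compute_metric_panel([], n_frames=5, dt_hours=1 / 3)
        k = {name: i for i, name in enumerate(METRIC_NAMES)}
        for name in ("average_number", "new_appearance", "track_end"):
            np.testing.assert_array_equal(panel.values[k[name]], 0)
        for name in ("persistency_average", "tip_distance_average"):
            assert np.isnan(panel.values[k[name]]).all()

    def test_single_full_span_track_conservation(self):
        panel = compute_metric_panel([_track(0, 0, 6)], n_frames=6, dt_hours=1 / 3)
        k = {name: i for i, name in enumerate(METRIC_NAMES)}
        new, end = panel.values[k["new_appearance"]], panel.values[k["track_end"]]
        assert new[0] == 1 and new[1:].sum() == 0
        assert end[-1] == 1 and end[:-1].sum() == 0

    def test_spread_metrics_zero_for_single_roi(self):
        panel = compute_metric_panel([_track(0, 0, 2, tip=5.0, center=2.0)], n_frames=2, dt_hours=1 / 3)
        k = {name: i for i, name in enumerate(METRIC_NAMES)}
        assert panel.values[k["persistency_spread"], 0] == 0.0
        assert panel.values[k["tip_distance_spread"], 0] == 0.0

    def test_member_beyond_course_rejected(self):
        with pytest.raises(ValueError):
            compute_metric_panel([_track(0, 3, 4)], n_frames=5, dt_hours=1 / 3)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_conservation_on_random_fixtures(self, seed):
        """Appearances and endings both sum to the track count, and the
        additive persistency equals mean x count wherever ROIs are visible."""
        rng = np.random.default_rng(seed)
        n_frames = int(rng.integers(2, 30))
        tracks = random_tracks(rng, n_frames)
        panel = compute_metric_panel(tracks, n_frames=n_frames, dt_hours=1 / 3)
        k = {name: i for i, name in enumerate(METRIC_NAMES)}
        assert panel.values[k["new_appearance"]].sum() == len(tracks)
        assert panel.values[k["track_end"]].sum() == len(tracks)
        x1, x3, x4 = (panel.values[k[n]] for n in ("persistency_average", "persistency_additive", "average_number"))
        visible = x4 > 0
        np.testing.assert_allclose(x3[visible], x1[visible] * x4[visible], atol=1e-9)


class TestLowpassFilter:
    def test_constant_signal_passes_unchanged(self):
        out = lowpass_filter(np.full(30, 7.5))
        np.testing.assert_allclose(out, 7.5)

    def test_impulse_response_is_tenth_over_ten_taps(self):
        signal = np.zeros(72)
        signal[20] = 1.0
        out = lowpass_filter(signal, window=(4, 5))
        np.testing.assert_allclose(out[16:26], 0.1)
        assert out[:16].sum() == 0 and out[26:].sum() == 0

    def test_matches_brute_force_windowed_mean(self, rng):
        signal = rng.normal(size=72)
        out = lowpass_filter(signal, window=(4, 5))
        for n in range(72):
            window = signal[max(n - 5, 0) : min(n + 5, 72)]
            assert out[n] == pytest.approx(window.mean(), abs=1e-12)

    def test_linearity_on_fully_observed_signals(self, rng):
        s1, s2 = rng.normal(size=40), rng.normal(size=40)
        combined = lowpass_filter(2.0 * s1 - 0.5 * s2)
        np.testing.assert_allclose(combined, 2.0 * lowpass_filter(s1) - 0.5 * lowpass_filter(s2), atol=1e-12)

    def test_output_within_signal_range(self, rng):
        signal = rng.uniform(-5, 9, size=50)
        out = lowpass_filter(signal)
        assert out.min() >= signal.min() - 1e-12
        assert out.max() <= signal.max() + 1e-12

    def test_missing_samples_renormalized(self):
        signal = np.array([1.0, np.nan, 3.0, np.nan, np.nan])
        out = lowpass_filter(signal, window=(1, 1))
        assert out[0] == pytest.approx(1.0)
        assert out[1] == pytest.approx(2.0)
        assert np.isnan(out[4])

    def test_all_missing_window_stays_missing(self):
        out = lowpass_filter(np.full(5, np.nan), window=(1, 1))
        assert np.isnan(out).all()


class TestAverageReplicates:
    def _panel(self, values, replicate="r1"):
        return MetricPanel(values=values, condition_id="c", replicate_id=replicate, dt_hours=1 / 3, filtered=True)

    def test_single_replicate_passthrough(self, rng):
        values = rng.normal(size=(10, 12))
        profile = average_replicates([self._panel(values)])
        np.testing.assert_array_equal(profile.profile, values)
        assert profile.n_replicates == 1

    def test_opposite_panels_average_to_zero(self, rng):
        values = rng.normal(size=(10, 8))
        profile = average_replicates([self._panel(values), self._panel(-values, "r2")])
        np.testing.assert_allclose(profile.profile, 0.0, atol=1e-12)

    def test_three_replicates_match_entrywise_mean(self, rng):
        panels = [self._panel(rng.normal(size=(10, 20)), f"r{i}") for i in range(3)]
        profile = average_replicates(panels)
        expected = np.mean([p.values for p in panels], axis=0)
        np.testing.assert_allclose(profile.profile, expected, atol=1e-12)

    def test_missing_entries_ignored_per_cell(self):
        a = np.full((10, 3), 2.0)
        b = np.full((10, 3), 4.0)
        b[0, 1] = np.nan
        a[0, 2] = np.nan
        b[0, 2] = np.nan
        profile = average_replicates([self._panel(a), self._panel(b, "r2")])
        assert profile.profile[0, 0] == pytest.approx(3.0)
        assert profile.profile[0, 1] == pytest.approx(2.0)  # only replicate a observed
        assert np.isnan(profile.profile[0, 2])  # missing everywhere stays missing

    def test_mismatched_length_rejected(self, rng):
        with pytest.raises(ValueError):
            average_replicates([self._panel(rng.normal(size=(10, 5))), self._panel(rng.normal(size=(10, 6)), "r2")])
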