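"""The ten spatiotemporal metric signals, low-pass filtering, averaging.

For every time stamp ``n`` let ``V(n)`` be the set of ROIs visible at
``n``.  The raw metrics are:

==  ========================  =================================================
k   name                      definition over V(n)
==  ========================  =================================================
1   persistency_average       mean persistency (h) of the tracks of V(n)
2   persistency_spread        population SD of those persistencies
3   persistency_additive      sum of those persistencies (= X1 × X4)
4   average_number            |V(n)|
5   new_appearance            number of tracks first seen at n
6   track_end                 number of tracks last seen at n
7   tip_distance_average      mean distance (µm) to the root tip
8   tip_distance_spread       population SD of tip distances
9   center_distance_average   mean perpendicular distance (µm) to the root axis
10  center_distance_spread    population SD of center distances
==  ========================  =================================================

Frames with no visible ROI carry 0 for the counts (X4–X6) and NaN for
the means and spreads.  Each signal is smoothed with a truncated,
renormalized moving average — 10 taps of weight 1/10 in the interior by
default — and filtered replicate signals are averaged entrywise into a
condition profile.
"""

from __future__ import annotations

import numpy as np

from .model import METRIC_NAMES, ConditionProfile, MetricPanel, Track


def compute_metric_panel(
    tracks: list[Track],
    n_frames: int,
    dt_hours: float,
    condition_id: str = "condition",
    replicate_id: str = "r1",
) -> MetricPanel:
    """Raw 10 × N metric panel for one replicate.

    ROI tip/center distances are read from the ROI records (attached by
    :func:`roottrack.geometry.locate_rois`); NaN distances are ignored in
    the distance means and spreads.
    """
    for track in tracks:
        if track.n_last >= n_frames:
            raise ValueError(
                f"track {track.track_id} extends to frame {track.n_last}, "
                f"beyond the {n_frames}-frame course"
            )
    values = np.full((len(METRIC_NAMES), n_frames), np.nan)
    persistency: dict[int, list[float]] = {n: [] for n in range(n_frames)}
    tips: dict[int, list[float]] = {n: [] for n in range(n_frames)}
    centers: dict[int, list[float]] = {n: [] for n in range(n_frames)}
    new_counts = np.zeros(n_frames)
    end_counts = np.zeros(n_frames)
    for track in tracks:
        new_counts[track.n_first] += 1
        end_counts[track.n_last] += 1
        for roi in track.rois:
            n = roi.timestamp_index
            persistency[n].append(track.persistency_h)
            if np.isfinite(roi.tip_distance_um):
                tips[n].append(roi.tip_distance_um)
            if np.isfinite(roi.center_distance_um):
                centers[n].append(roi.center_distance_um)

    for n in range(n_frames):
        pers = np.asarray(persistency[n])
        values[3, n] = len(pers)
        values[4, n] = new_counts[n]
        values[5, n] = end_counts[n]
        if len(pers):
            values[0, n] = pers.mean()
            values[1, n] = pers.std()  # population SD; 0 for a single ROI
            values[2, n] = pers.sum()
        for k_mean, k_sd, data in ((6, 7, tips[n]), (8, 9, centers[n])):
            if data:
                arr = np.asarray(data)
                values[k_mean, n] = arr.mean()
                values[k_sd, n] = arr.std()
    return MetricPanel(
        values=values,
        condition_id=condition_id,
        replicate_id=replicate_id,
        dt_hours=dt_hours,
        filtered=False,
    )


def lowpass_filter(signal, window: tuple[int, int] = (4, 5)) -> np.ndarray:
    """Truncated, renormalized moving average.

    ``window = (4, 5)`` names the kernel taps ``k = -4 .. 5`` of the
    10-tap boxcar of weight 1/10; convolving with it makes the output at
    ``n`` the mean of samples ``n-5 .. n+4`` (a unit impulse at 20 thus
    responds with 0.1 at 16..25).  Near the edges, and at missing (NaN)
    samples, the window truncates and the remaining samples are
    averaged.  A window with no observed sample yields NaN.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be 1D")
    k_min, k_max = window
    if k_min < 0 or k_max < 0:
        raise ValueError("window bounds must be non-negative")
    n_samples = len(signal)
    out = np.full(n_samples, np.nan)
    for n in range(n_samples):
        chunk = signal[max(n - k_max, 0) : min(n + k_min + 1, n_samples)]
        observed = chunk[np.isfinite(chunk)]
        if len(observed):
            out[n] = observed.mean()
    return out


def filter_panel(panel: MetricPanel, window: tuple[int, int] = (4, 5)) -> MetricPanel:
    """Apply the low-pass filter to every metric signal of a panel."""
    filtered = np.vstack([lowpass_filter(row, window) for row in panel.values])
    return MetricPanel(
        values=filtered,
        condition_id=panel.condition_id,
        replicate_id=panel.replicate_id,
        dt_hours=panel.dt_hours,
        filtered=True,
    )


def average_replicates(panels: list[MetricPanel], condition_id: str | None = None) -> ConditionProfile:
    """Entrywise mean of filtered replicate panels into a condition profile.

    Missing entries are ignored per (metric, time stamp); an entry
    missing in every replicate stays missing.
    """
    if not panels:
        raise ValueError("need at least one replicate panel")
    n_frames = panels[0].n_frames
    for panel in panels[1:]:
        if panel.n_frames != n_frames:
            raise ValueError(
                f"replicate panels disagree on length: {panel.n_frames} vs {n_frames}"
            )
    if condition_id is None:
        condition_id = panels[0].condition_id
    stacked = np.stack([p.values for p in panels])
    observed = np.isfinite(stacked)
    counts = observed.sum(axis=0)
    sums = np.where(observed, stacked, 0.0).sum(axis=0)
    profile = np.divide(sums, counts, out=np.full(counts.shape, np.nan), where=counts > 0)
    return ConditionProfile(profile=profile, condition_id=condition_id, n_replicates=len(panels))
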