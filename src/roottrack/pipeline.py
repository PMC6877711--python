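"""End-to-end orchestration: stacks in, tracks / metrics / comparisons out.

These functions wire the per-stage modules together for the common case
— one fluorescence + one brightfield time course per replicate — and are
what the command-line interface and the examples call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry, metrics, segmentation, tracking
from .io import tracks_to_table
from .model import (
    METRIC_NAMES,
    ConditionProfile,
    ExperimentConfig,
    GrowthCurve,
    MetricPanel,
    TimeCourse,
    Track,
)


@dataclass
class ReplicateResult:
    """Everything derived from one replicate's two channels."""

    tracks: list[Track]
    growth: GrowthCurve
    displacements_voxels: np.ndarray
    panel: MetricPanel
    filtered_panel: MetricPanel
    track_table: pd.DataFrame
    thresholds: list[float]
    geometries: list[geometry.RootGeometry]


def segment_timecourse(
    fluorescence: TimeCourse, config: ExperimentConfig
) -> tuple[list[list], list[float]]:
    """Segment every fluorescence frame; returns per-frame ROI lists and
    the resolved thresholds."""
    rois_per_frame, thresholds = [], []
    for frame in fluorescence.frames:
        rois, value = segmentation.segment_frame(
            frame,
            threshold=config.threshold,
            min_volume=config.min_roi_volume_voxels,
            min_seed_separation_um=config.min_seed_separation_um,
        )
        rois_per_frame.append(rois)
        thresholds.append(value)
    return rois_per_frame, thresholds


def estimate_geometries(
    brightfield: TimeCourse, config: ExperimentConfig
) -> list[geometry.RootGeometry]:
    """Root mask, axis and tip for every brightfield frame."""
    geometries = []
    for frame in brightfield.frames:
        mask = geometry.classify_root_voxels(
            frame,
            n_clusters=config.n_clusters,
            seed=config.clustering_seed,
            smooth_um=config.gradient_smooth_um,
        )
        geometries.append(
            geometry.estimate_axis_and_tip(
                mask,
                frame.resolution,
                timestamp_index=frame.timestamp_index,
                tip_side=config.tip_side,
            )
        )
    return geometries


def process_replicate(
    fluorescence: TimeCourse,
    brightfield: TimeCourse,
    config: ExperimentConfig | None = None,
    locate: bool = True,
) -> ReplicateResult:
    """Run segmentation, geometry, tracking and metrics for one replicate."""
    config = config or ExperimentConfig(
        resolution_um=fluorescence.resolution, dt_hours=fluorescence.dt_hours
    )
    rois_per_frame, thresholds = segment_timecourse(fluorescence, config)
    geometries = estimate_geometries(brightfield, config) if locate else []
    if locate:
        for rois, geom in zip(rois_per_frame, geometries):
            geometry.locate_rois(rois, geom)
    tracks, growth, displacements = tracking.track_timecourse(
        rois_per_frame,
        brightfield.frames,
        dt_hours=fluorescence.dt_hours,
        max_link_distance_um=config.max_link_distance_um,
        upsample_factor=config.registration_upsample,
    )
    panel = metrics.compute_metric_panel(
        tracks,
        n_frames=len(fluorescence),
        dt_hours=fluorescence.dt_hours,
        condition_id=fluorescence.condition_id,
        replicate_id=fluorescence.replicate_id,
    )
    filtered = metrics.filter_panel(panel, window=config.filter_window)
    return ReplicateResult(
        tracks=tracks,
        growth=growth,
        displacements_voxels=displacements,
        panel=panel,
        filtered_panel=filtered,
        track_table=tracks_to_table(
            tracks,
            condition_id=fluorescence.condition_id,
            replicate_id=fluorescence.replicate_id,
        ),
        thresholds=thresholds,
        geometries=geometries,
    )


def condition_profile(results: list[ReplicateResult]) -> ConditionProfile:
    """Average the filtered panels of a condition's replicates."""
    return metrics.average_replicates([r.filtered_panel for r in results])


def panel_to_frame(panel: MetricPanel) -> pd.DataFrame:
    """Long-format DataFrame of one panel (raw or filtered)."""
    n = panel.n_frames
    data = {
        "condition": panel.condition_id,
        "replicate": panel.replicate_id,
        "n": np.arange(n),
        "time_h": np.arange(n) * panel.dt_hours,
        "filtered": panel.filtered,
    }
    for k, name in enumerate(METRIC_NAMES):
        data[name] = panel.values[k]
    return pd.DataFrame(data)


def growth_to_frame(
    growth: GrowthCurve, dt_hours: float, condition_id: str = "condition", replicate_id: str = "r1"
) -> pd.DataFrame:
    """Growth curve as a tidy table: g(n) is the step into time stamp n."""
    n = np.arange(len(growth.cumulative_um))
    return pd.DataFrame(
        {
            "condition": condition_id,
            "replicate": replicate_id,
            "n": n,
            "time_h": n * dt_hours,
            "g_um": np.concatenate([[0.0], growth.g_um]),
            "cumulative_growth_um": growth.cumulative_um,
        }
    )
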