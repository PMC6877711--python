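"""Core domain types for 3D two-channel root time-lapse analysis.

Conventions used throughout the package:

* voxel grids are indexed ``(z, y, x)``, 0-based;
* physical coordinates are voxel index times the per-axis resolution in
  micrometres (the axial step is typically much coarser than the lateral
  pixel size, so all distance computations are anisotropy-aware);
* a time course of duration ``D`` hours sampled every ``dt`` hours is
  indexed ``n = 0 .. N-1`` with ``N = D / dt`` (one frame per sampling
  interval) and ``time_h(n) = n * dt``.  A 24-h experiment at one frame
  per 20 min therefore has exactly 72 time stamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

FLUORESCENCE = "fluorescence"
BRIGHTFIELD = "brightfield"
CHANNELS = (FLUORESCENCE, BRIGHTFIELD)

#: Default sampling interval: one frame every 20 minutes.
DEFAULT_DT_HOURS = 1.0 / 3.0

#: Default anisotropic voxel resolution in µm, (axial z, lateral y, lateral x).
DEFAULT_RESOLUTION_UM = (3.33, 0.23, 0.23)


class RoottrackError(Exception):
    """Base class for all package-specific errors."""


class GapError(RoottrackError):
    """A time index is missing from an on-disk frame sequence."""


class ShapeMismatchError(RoottrackError):
    """Frames of one time course differ in grid shape."""


class IntegrityError(RoottrackError):
    """A table or track structure violates an internal invariant."""


class DegenerateInputError(RoottrackError):
    """An input has no usable structure (constant image, empty mask...)."""


class ConfigurationError(RoottrackError):
    """A configuration value is invalid or inconsistent."""


def frame_count(duration_h: float, dt_hours: float) -> int:
    """Number of time stamps for an experiment of ``duration_h`` hours
    sampled every ``dt_hours`` hours (interval-indexed: 24 h at 20-min
    sampling gives 72).

    Raises
    ------
    ConfigurationError
        If the duration is not an integral number of intervals.
    """
    if dt_hours <= 0 or duration_h <= 0:
        raise ConfigurationError("duration and sampling interval must be positive")
    n = duration_h / dt_hours
    n_int = int(round(n))
    if abs(n - n_int) > 1e-9 * max(1.0, n):
        raise ConfigurationError(
            f"duration {duration_h} h is not a whole number of {dt_hours} h intervals"
        )
    return n_int


@dataclass
class ImageFrame:
    """One 3D voxel grid for one channel at one time stamp.

    Attributes
    ----------
    voxels : ndarray, shape (z, y, x)
        Scalar intensity grid.
    resolution : tuple of float
        Physical voxel size in µm per axis, ordered (z, y, x).
    timestamp_index : int
        Position of the frame in its time course, ``n >= 0``.
    channel : str
        ``"fluorescence"`` or ``"brightfield"``.
    """

    voxels: np.ndarray
    resolution: tuple[float, float, float]
    timestamp_index: int
    channel: str

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a 3D grid with size >= 1 on every axis")
        self.resolution = tuple(float(r) for r in self.resolution)  # type: ignore[assignment]
        if len(self.resolution) != 3 or any(r <= 0 for r in self.resolution):
            raise ValueError("resolution must be three positive values (z, y, x)")
        if self.timestamp_index < 0:
            raise ValueError("timestamp_index must be >= 0")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass
class TimeCourse:
    """An ordered single-channel sequence of frames with shared geometry."""

    frames: list[ImageFrame]
    dt_hours: float
    condition_id: str = "condition"
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a time course needs at least one frame")
        if self.dt_hours <= 0:
            raise ValueError("dt_hours must be positive")
        for n, frame in enumerate(self.frames):
            if frame.timestamp_index != n:
                raise GapError(
                    f"frame at position {n} has timestamp_index "
                    f"{frame.timestamp_index}; indices must run 0..N-1 without gaps"
                )
        first = self.frames[0]
        for frame in self.frames[1:]:
            if frame.channel != first.channel:
                raise ValueError("all frames of a time course must share one channel")
            if frame.resolution != first.resolution:
                raise ValueError("all frames must share the same voxel resolution")
            if frame.shape != first.shape:
                raise ShapeMismatchError(
                    f"frame {frame.timestamp_index} has shape {frame.shape}, "
                    f"expected {first.shape}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, n: int) -> ImageFrame:
        return self.frames[n]

    @property
    def resolution(self) -> tuple[float, float, float]:
        return self.frames[0].resolution

    @property
    def channel(self) -> str:
        return self.frames[0].channel

    def time_h(self, n: int) -> float:
        return n * self.dt_hours


@dataclass
class Roi:
    """One segmented connected fluorescent region at one time stamp."""

    label: int
    timestamp_index: int
    voxel_coords: np.ndarray | None  # (n_voxels, 3) int indices (z, y, x); None when
    # the ROI was reconstructed from a table rather than a label image
    centroid_um: np.ndarray  # (3,) intensity-weighted centroid, µm (z, y, x)
    volume_voxels: int
    mean_intensity: float = float("nan")
    max_intensity: float = float("nan")
    tip_distance_um: float = float("nan")
    center_distance_um: float = float("nan")

    def __post_init__(self) -> None:
        self.centroid_um = np.asarray(self.centroid_um, dtype=float)
        if self.voxel_coords is not None:
            self.voxel_coords = np.asarray(self.voxel_coords, dtype=np.int64)
            if self.voxel_coords.ndim != 2 or self.voxel_coords.shape[1] != 3:
                raise ValueError("voxel_coords must have shape (n_voxels, 3)")
            if len(self.voxel_coords) == 0:
                raise ValueError("an ROI must contain at least one voxel")
            if self.volume_voxels != len(self.voxel_coords):
                raise IntegrityError("volume_voxels disagrees with the voxel set size")


@dataclass
class Track:
    """A time-ordered chain of ROIs identified as the same region.

    Persistency is the observed temporal extent of the track in hours,
    ``member count × dt`` — a nine-sample track at 20-min sampling has
    persistency 3 h.
    """

    track_id: int
    rois: list[Roi]
    dt_hours: float

    def __post_init__(self) -> None:
        if not self.rois:
            raise ValueError("a track needs at least one ROI")
        indices = [r.timestamp_index for r in self.rois]
        if any(b - a != 1 for a, b in zip(indices, indices[1:])):
            raise IntegrityError(
                f"track {self.track_id} member timestamps {indices} are not consecutive"
            )
        if self.dt_hours <= 0:
            raise ValueError("dt_hours must be positive")

    @property
    def n_first(self) -> int:
        return self.rois[0].timestamp_index

    @property
    def n_last(self) -> int:
        return self.rois[-1].timestamp_index

    @property
    def persistency_h(self) -> float:
        return len(self.rois) * self.dt_hours


@dataclass
class GrowthCurve:
    """Per-interval root displacement magnitudes and their running sum.

    ``g[n]`` is the µm magnitude of the registration displacement between
    frames ``n`` and ``n+1`` (``n = 0..N-2``, i.e. the interval ending at
    time stamp ``n+1``); ``G[n]`` is the cumulative growth up to time
    stamp ``n`` with ``G[0] = 0``.
    """

    g_um: np.ndarray
    cumulative_um: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.g_um = np.asarray(self.g_um, dtype=float)
        if self.g_um.ndim != 1:
            raise ValueError("g_um must be a 1D series")
        if np.any(self.g_um < 0):
            raise ValueError("growth magnitudes must be non-negative")
        self.cumulative_um = np.concatenate([[0.0], np.cumsum(self.g_um)])

    def __len__(self) -> int:
        return len(self.cumulative_um)


#: Fixed order of the ten spatiotemporal metrics.
METRIC_NAMES = (
    "persistency_average",
    "persistency_spread",
    "persistency_additive",
    "average_number",
    "new_appearance",
    "track_end",
    "tip_distance_average",
    "tip_distance_spread",
    "center_distance_average",
    "center_distance_spread",
)


@dataclass
class MetricPanel:
    """The ten raw (or filtered) metric signals for one replicate.

    ``values`` is a ``(10, N)`` grid in the fixed :data:`METRIC_NAMES`
    order; frames where no ROI was visible carry NaN for the mean/spread
    metrics and 0 for the count metrics.
    """

    values: np.ndarray
    condition_id: str
    replicate_id: str
    dt_hours: float
    filtered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(METRIC_NAMES):
            raise ValueError(f"values must have shape (10, N), got {self.values.shape}")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def metric(self, name: str) -> np.ndarray:
        return self.values[METRIC_NAMES.index(name)]


@dataclass
class ConditionProfile:
    """Replicate-averaged filtered 10 × N metric profile for one condition."""

    profile: np.ndarray
    condition_id: str
    n_replicates: int

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        if self.profile.ndim != 2 or self.profile.shape[0] != len(METRIC_NAMES):
            raise ValueError("profile must have shape (10, N)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def n_frames(self) -> int:
        return self.profile.shape[1]


@dataclass
class ExperimentConfig:
    """Pipeline parameters with the defaults used throughout the package.

    ``threshold`` is either the string ``"otsu"`` (per-frame automatic
    threshold) or a number (absolute intensity threshold).
    """

    resolution_um: tuple[float, float, float] = DEFAULT_RESOLUTION_UM
    dt_hours: float = DEFAULT_DT_HOURS
    threshold: float | str = "otsu"
    min_roi_volume_voxels: int = 8
    min_seed_separation_um: float = 5.0
    max_link_distance_um: float = 10.0
    filter_window: tuple[int, int] = (4, 5)
    gradient_smooth_um: float = 2.0
    n_clusters: int = 2
    clustering_seed: int = 0
    tip_side: str = "positive"  # which end of the principal axis is the tip
    registration_upsample: int = 1
    filter_growth: bool = False

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.resolution_um):
            raise ConfigurationError("resolution components must be positive")
        if self.dt_hours <= 0:
            raise ConfigurationError("dt_hours must be positive")
        if isinstance(self.threshold, str) and self.threshold != "otsu":
            raise ConfigurationError("threshold must be a number or 'otsu'")
        if self.min_roi_volume_voxels < 1:
            raise ConfigurationError("min_roi_volume_voxels must be >= 1")
        if self.max_link_distance_um <= 0 or self.min_seed_separation_um <= 0:
            raise ConfigurationError("distances must be positive")
        before, after = self.filter_window
        if before < 0 or after < 0 or before != int(before) or after != int(after):
            raise ConfigurationError("filter window bounds must be non-negative integers")
        if self.tip_side not in ("positive", "negative"):
            raise ConfigurationError("tip_side must be 'positive' or 'negative'")

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        kwargs = dict(data)
        for key in ("resolution_um", "filter_window"):
            if key in kwargs and isinstance(kwargs[key], Sequence):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "resolution_um": list(self.resolution_um),
            "dt_hours": self.dt_hours,
            "threshold": self.threshold,
            "min_roi_volume_voxels": self.min_roi_volume_voxels,
            "min_seed_separation_um": self.min_seed_separation_um,
            "max_link_distance_um": self.max_link_distance_um,
            "filter_window": list(self.filter_window),
            "gradient_smooth_um": self.gradient_smooth_um,
            "n_clusters": self.n_clusters,
            "clustering_seed": self.clustering_seed,
            "tip_side": self.tip_side,
            "registration_upsample": self.registration_upsample,
            "filter_growth": self.filter_growth,
        }

    def with_overrides(self, **kwargs) -> "ExperimentConfig":
        return replace(self, **kwargs)
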