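"""Synthetic two-channel root time-lapse phantoms with known ground truth.

The generator emulates the geometry of a light-sheet time course of a
growing root expressing a mitosis reporter:

* a brightfield channel showing a textured, round-tipped cylindrical
  root on a smooth background, translating along its own axis by a
  programmed per-interval drift (the "growth" signal);
* a fluorescence channel containing one Gaussian blob per active
  reporter event, riding on the same drift, with programmed onset frames
  and lifetimes (default mean nine frames, i.e. 3 h at 20-min sampling);
* anisotropic voxels (axial step 3.33 µm, lateral pixels 0.23 µm) and
  additive Gaussian noise.

Everything is driven by a single :class:`numpy.random.Generator` seeded
from the caller, so identical (config, seed) pairs give bit-identical
stacks.  The accompanying :class:`SceneTruth` carries the programmed
events, root axis, tip trajectory and drift schedule, and can be
flattened into the standard track-table schema to serve as an oracle
for segmentation, tracking and metric computations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import TRACK_TABLE_COLUMNS
from .model import (
    BRIGHTFIELD,
    DEFAULT_DT_HOURS,
    DEFAULT_RESOLUTION_UM,
    FLUORESCENCE,
    ConfigurationError,
    ImageFrame,
    TimeCourse,
)


@dataclass
class SceneConfig:
    """Parameters of the phantom scene.

    Distances are µm, grids are voxels in (z, y, x) order.  The root is a
    cylinder of radius ``root_radius_um`` whose axis runs along y with a
    hemispherical tip; it enters the grid at y = 0 and its tip starts at
    ``tip_start_y_um``, advancing by ``drift_voxels_per_frame`` each
    sampling interval.  Reporter events are placed in a zone
    ``placement_zone_um`` (min, max distance) behind the frame-0 tip,
    offset at most ``max_center_offset_um`` from the axis, and are kept
    at least ``min_separation_um`` apart from any event whose lifetime
    (dilated by one frame) overlaps theirs, so that segmentation and
    nearest-neighbour linking have an unambiguous truth.
    """

    shape: tuple[int, int, int] = (16, 512, 96)
    resolution_um: tuple[float, float, float] = DEFAULT_RESOLUTION_UM
    n_frames: int = 72
    dt_hours: float = DEFAULT_DT_HOURS
    # reporter events
    n_events: int = 30
    lifetime_mean_frames: float = 9.0
    lifetimes: Sequence[int] | None = None  # explicit override, one per event
    onsets: Sequence[int] | None = None  # explicit override, one per event
    blob_sigma_um: float = 2.5
    blob_peak: float = 100.0
    # root geometry
    root_radius_um: float = 8.0
    tip_start_y_um: float = 90.0
    max_center_offset_um: float = 4.5
    placement_zone_um: tuple[float, float] = (3.0, 85.0)
    min_separation_um: float = 12.0
    # growth drift, integer voxels per interval (z, y, x); scalar schedule
    drift_voxels_per_frame: tuple[int, int, int] = (0, 1, 0)
    # intensities and noise
    background_fluorescence: float = 10.0
    background_brightfield: float = 40.0
    root_base_intensity: float = 100.0
    texture_sigma: float = 25.0
    noise_sigma: float = 2.0
    condition_id: str = "phantom"
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")
        if self.n_events < 0:
            raise ConfigurationError("n_events must be >= 0")
        if any(s < 1 for s in self.shape):
            raise ConfigurationError("grid dimensions must be >= 1")
        if any(r <= 0 for r in self.resolution_um):
            raise ConfigurationError("resolution components must be positive")
        if any(d != int(d) for d in self.drift_voxels_per_frame):
            raise ConfigurationError("drift must be integer voxels per frame")
        lo, hi = self.placement_zone_um
        if not (0 <= lo < hi <= self.tip_start_y_um):
            raise ConfigurationError("placement zone must lie behind the initial tip")
        if self.max_center_offset_um >= self.root_radius_um:
            raise ConfigurationError("event offset must be smaller than the root radius")
        if self.lifetimes is not None and len(self.lifetimes) != self.n_events:
            raise ConfigurationError("lifetimes override must list one value per event")
        if self.onsets is not None and len(self.onsets) != self.n_events:
            raise ConfigurationError("onsets override must list one value per event")

    @property
    def grid_extent_um(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.resolution_um)


@dataclass
class RoiEvent:
    """One programmed reporter occurrence."""

    event_id: int
    onset_frame: int
    lifetime_frames: int
    initial_centroid_um: np.ndarray  # (3,) position at zero cumulative drift
    sigma_um: float
    peak_intensity: float

    @property
    def last_frame(self) -> int:
        return self.onset_frame + self.lifetime_frames - 1

    def active_at(self, n: int) -> bool:
        return self.onset_frame <= n <= self.last_frame


@dataclass
class SceneTruth:
    """Ground truth of a generated scene."""

    config: SceneConfig
    seed: int
    events: list[RoiEvent]
    drift_voxels: np.ndarray  # (n_frames - 1, 3) integer drift per interval
    axis_point_um: np.ndarray  # (3,) a point on the root axis (at y = 0)
    axis_direction: np.ndarray  # (3,) unit vector along the root axis
    tip_positions_um: np.ndarray  # (n_frames, 3) tip point per frame

    def cumulative_drift_voxels(self, n: int) -> np.ndarray:
        """Total drift (voxels) accumulated from frame 0 up to frame n."""
        if n == 0:
            return np.zeros(3, dtype=np.int64)
        return self.drift_voxels[:n].sum(axis=0)

    def cumulative_drift_um(self, n: int) -> np.ndarray:
        return self.cumulative_drift_voxels(n) * np.asarray(self.config.resolution_um)

    def centroid_um(self, event: RoiEvent, n: int) -> np.ndarray:
        return event.initial_centroid_um + self.cumulative_drift_um(n)

    def active_events(self, n: int) -> list[RoiEvent]:
        return [e for e in self.events if e.active_at(n)]

    def root_mask(self, n: int) -> np.ndarray:
        """Render the boolean root mask at frame ``n`` (the IoU oracle)."""
        cfg = self.config
        res = np.asarray(cfg.resolution_um)
        z = np.arange(cfg.shape[0]) * res[0]
        y = np.arange(cfg.shape[1]) * res[1]
        x = np.arange(cfg.shape[2]) * res[2]
        zc, _, xc = self.axis_point_um
        tip_y = self.tip_positions_um[n][1]
        r = cfg.root_radius_um
        # distance to the axis segment ending r behind the tip: round cap
        dy = np.maximum(y - (tip_y - r), 0.0)
        d2 = (
            (z[:, None, None] - zc) ** 2
            + dy[None, :, None] ** 2
            + (x[None, None, :] - xc) ** 2
        )
        return d2 <= r**2


def _sample_events(cfg: SceneConfig, rng: np.random.Generator) -> list[RoiEvent]:
    zc = cfg.shape[0] * cfg.resolution_um[0] / 2.0
    xc = cfg.shape[2] * cfg.resolution_um[2] / 2.0
    lo, hi = cfg.placement_zone_um
    events: list[RoiEvent] = []
    for e in range(cfg.n_events):
        placed = False
        for _ in range(20000):
            if cfg.lifetimes is not None:
                lifetime = int(cfg.lifetimes[e])
            else:
                lifetime = 1 + int(rng.poisson(max(cfg.lifetime_mean_frames - 1, 0)))
            lifetime = min(max(lifetime, 1), cfg.n_frames)
            if cfg.onsets is not None:
                onset = int(cfg.onsets[e])
                if not 0 <= onset <= cfg.n_frames - lifetime:
                    raise ConfigurationError(
                        f"event {e}: onset {onset} + lifetime {lifetime} exceeds "
                        f"the {cfg.n_frames}-frame course"
                    )
            else:
                onset = int(rng.integers(0, cfg.n_frames - lifetime + 1))
            y0 = cfg.tip_start_y_um - rng.uniform(lo, hi)
            radius = cfg.max_center_offset_um * np.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * np.pi)
            centroid = np.array([zc + radius * np.cos(theta), y0, xc + radius * np.sin(theta)])
            # keep concurrent (±1 frame) events separated so truth is unambiguous
            ok = True
            for other in events:
                t_overlap = onset - 1 <= other.last_frame and other.onset_frame - 1 <= onset + lifetime - 1
                if t_overlap and np.linalg.norm(centroid - other.initial_centroid_um) < cfg.min_separation_um:
                    ok = False
                    break
            if ok:
                events.append(
                    RoiEvent(
                        event_id=e,
                        onset_frame=onset,
                        lifetime_frames=lifetime,
                        initial_centroid_um=centroid,
                        sigma_um=cfg.blob_sigma_um,
                        peak_intensity=cfg.blob_peak,
                    )
                )
                placed = True
                break
        if not placed:
            raise ConfigurationError(
                f"could not place event {e} with {cfg.min_separation_um} µm separation; "
                "enlarge the placement zone or reduce event density"
            )
    return events


def _add_blob(img: np.ndarray, centroid_um: np.ndarray, sigma_um: float, peak: float, res: np.ndarray) -> None:
    """Add an isotropic-in-µm Gaussian blob, rendered on a ±4σ window."""
    center_vox = centroid_um / res
    half = np.ceil(4 * sigma_um / res).astype(int)
    lo = np.maximum(np.floor(center_vox).astype(int) - half, 0)
    hi = np.minimum(np.floor(center_vox).astype(int) + half + 1, img.shape)
    if np.any(lo >= hi):
        return
    zz = (np.arange(lo[0], hi[0]) * res[0] - centroid_um[0]) ** 2
    yy = (np.arange(lo[1], hi[1]) * res[1] - centroid_um[1]) ** 2
    xx = (np.arange(lo[2], hi[2]) * res[2] - centroid_um[2]) ** 2
    d2 = zz[:, None, None] + yy[None, :, None] + xx[None, None, :]
    img[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += peak * np.exp(-d2 / (2 * sigma_um**2))


def generate_scene(
    config: SceneConfig | None = None, seed: int = 0
) -> tuple[TimeCourse, TimeCourse, SceneTruth]:
    """Render a phantom time course.

    Returns the fluorescence course, the brightfield course and the
    :class:`SceneTruth` describing exactly what was rendered.

    Raises
    ------
    ConfigurationError
        If the drift schedule would push the root tip outside the grid,
        or the events cannot be placed with the required separation.
    """
    cfg = config if config is not None else SceneConfig()
    rng = np.random.default_rng(seed)
    res = np.asarray(cfg.resolution_um)

    drift = np.tile(np.asarray(cfg.drift_voxels_per_frame, dtype=np.int64), (max(cfg.n_frames - 1, 0), 1))
    cum = np.vstack([np.zeros(3, dtype=np.int64), np.cumsum(drift, axis=0)]) if cfg.n_frames > 1 else np.zeros((1, 3), dtype=np.int64)

    zc = cfg.shape[0] * res[0] / 2.0
    xc = cfg.shape[2] * res[2] / 2.0
    tip0 = np.array([zc, cfg.tip_start_y_um, xc])
    tips = tip0[None, :] + cum * res[None, :]
    extent = cfg.grid_extent_um
    if np.any(tips[-1][1] + res[1] > extent[1]) or np.any(tips[:, [0, 2]] < 0) or np.any(
        tips[:, [0, 2]] > extent[[0, 2]]
    ):
        raise ConfigurationError(
            f"drift schedule pushes the root tip to {tips[-1]} µm, outside the "
            f"{extent} µm grid"
        )

    events = _sample_events(cfg, rng)
    truth = SceneTruth(
        config=cfg,
        seed=seed,
        events=events,
        drift_voxels=drift,
        axis_point_um=np.array([zc, 0.0, xc]),
        axis_direction=np.array([0.0, 1.0, 0.0]),
        tip_positions_um=tips,
    )

    # static texture field, shifted with the root so registration sees a
    # pure translation of the tissue speckle
    pad = np.abs(cum).max(axis=0).astype(int)
    tex_shape = tuple(np.asarray(cfg.shape) + 2 * pad)
    texture = rng.normal(0.0, cfg.texture_sigma, size=tex_shape)

    fluo_frames, bright_frames = [], []
    for n in range(cfg.n_frames):
        fluo = rng.normal(cfg.background_fluorescence, cfg.noise_sigma, size=cfg.shape)
        for event in events:
            if event.active_at(n):
                _add_blob(fluo, truth.centroid_um(event, n), event.sigma_um, event.peak_intensity, res)

        bright = rng.normal(cfg.background_brightfield, cfg.noise_sigma, size=cfg.shape)
        mask = truth.root_mask(n)
        shift = pad - cum[n]
        zi, yi, xi = np.nonzero(mask)
        bright[zi, yi, xi] += cfg.root_base_intensity + texture[
            zi + shift[0], yi + shift[1], xi + shift[2]
        ]

        fluo_frames.append(
            ImageFrame(fluo.astype(np.float32), tuple(res), n, FLUORESCENCE)
        )
        bright_frames.append(
            ImageFrame(bright.astype(np.float32), tuple(res), n, BRIGHTFIELD)
        )

    common = dict(dt_hours=cfg.dt_hours, condition_id=cfg.condition_id, replicate_id=cfg.replicate_id)
    return (
        TimeCourse(frames=fluo_frames, **common),
        TimeCourse(frames=bright_frames, **common),
        truth,
    )


def truth_to_track_table(truth: SceneTruth) -> pd.DataFrame:
    """Flatten the programmed events into the standard track-table schema.

    One row per (event, active frame); the oracle for tracking tests.
    Tip and axis distances are exact closed-form values; the segmentation
    volume is unknown to the truth and set to 0.
    """
    cfg = truth.config
    rows = []
    for event in truth.events:
        persistency = event.lifetime_frames * cfg.dt_hours
        for n in range(event.onset_frame, event.last_frame + 1):
            c = truth.centroid_um(event, n)
            tip = truth.tip_positions_um[n]
            rel = c - truth.axis_point_um
            along = rel @ truth.axis_direction
            center_dist = float(np.linalg.norm(rel - along * truth.axis_direction))
            rows.append(
                {
                    "condition": cfg.condition_id,
                    "replicate": cfg.replicate_id,
                    "track_id": event.event_id,
                    "timestamp_index": n,
                    "time_h": n * cfg.dt_hours,
                    "centroid_z_um": c[0],
                    "centroid_y_um": c[1],
                    "centroid_x_um": c[2],
                    "volume_voxels": 0,
                    "tip_distance_um": float(np.linalg.norm(c - tip)),
                    "center_distance_um": center_dist,
                    "persistency_h": persistency,
                }
            )
    table = pd.DataFrame(rows, columns=TRACK_TABLE_COLUMNS)
    return table.astype({"track_id": np.int64, "timestamp_index": np.int64, "volume_voxels": np.int64})
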