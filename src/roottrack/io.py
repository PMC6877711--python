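"""Readers and writers: TIFF time-course layout, track tables, configs.

On-disk layout for one replicate::

    <replicate_dir>/
        metadata.yaml          # resolution_um, dt_hours, condition_id, replicate_id
        fluorescence/t000.tif  # one multi-page TIFF stack per time stamp
        fluorescence/t001.tif
        brightfield/t000.tif
        ...

The sidecar ``metadata.yaml`` is the metadata authority; embedded TIFF
tags are ignored.  Track tables are plain CSV and round-trip losslessly
through :func:`write_track_table` / :func:`read_track_table`.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .model import (
    CHANNELS,
    GapError,
    ImageFrame,
    IntegrityError,
    RoottrackError,
    TimeCourse,
    Track,
)

_FRAME_RE = re.compile(r"^t(\d+)\.tiff?$")

#: Column schema of the track table, one row per (track, time stamp).
TRACK_TABLE_COLUMNS = [
    "condition",
    "replicate",
    "track_id",
    "timestamp_index",
    "time_h",
    "centroid_z_um",
    "centroid_y_um",
    "centroid_x_um",
    "volume_voxels",
    "tip_distance_um",
    "center_distance_um",
    "persistency_h",
]

_TRACK_TABLE_DTYPES = {
    "condition": str,
    "replicate": str,
    "track_id": np.int64,
    "timestamp_index": np.int64,
    "volume_voxels": np.int64,
}


def read_metadata(replicate_dir: str | Path) -> dict:
    path = Path(replicate_dir) / "metadata.yaml"
    if not path.exists():
        raise RoottrackError(f"missing sidecar metadata file {path}")
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_metadata(replicate_dir: str | Path, metadata: dict) -> Path:
    path = Path(replicate_dir) / "metadata.yaml"
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(metadata, fh)
    return path


def load_timecourse(replicate_dir: str | Path, channel: str) -> TimeCourse:
    """Load one channel of a replicate from the TIFF directory layout.

    Frames are sorted by the zero-padded time index in their filename and
    must form a gapless sequence starting at ``t000``.

    Raises
    ------
    GapError
        If an index is missing from the sequence.
    ShapeMismatchError
        If stacks differ in shape.
    RoottrackError
        If a file cannot be read, or metadata is missing.
    """
    if channel not in CHANNELS:
        raise ValueError(f"channel must be one of {CHANNELS}")
    replicate_dir = Path(replicate_dir)
    meta = read_metadata(replicate_dir)
    resolution = tuple(float(r) for r in meta["resolution_um"])
    dt_hours = float(meta["dt_hours"])

    channel_dir = replicate_dir / channel
    if not channel_dir.is_dir():
        raise RoottrackError(f"channel directory {channel_dir} does not exist")
    indexed: dict[int, Path] = {}
    for entry in channel_dir.iterdir():
        m = _FRAME_RE.match(entry.name)
        if m:
            indexed[int(m.group(1))] = entry
    if not indexed:
        raise RoottrackError(f"no frame files matching t<index>.tif in {channel_dir}")

    n_frames = max(indexed) + 1
    for n in range(n_frames):
        if n not in indexed:
            raise GapError(f"frame index {n} is missing from {channel_dir}")

    frames = []
    for n in range(n_frames):
        try:
            voxels = tifffile.imread(indexed[n])
        except Exception as exc:  # noqa: BLE001 - rewrap with the filename
            raise RoottrackError(f"cannot read {indexed[n]}: {exc}") from exc
        if voxels.ndim == 2:
            voxels = voxels[np.newaxis]
        frames.append(
            ImageFrame(voxels=voxels, resolution=resolution, timestamp_index=n, channel=channel)
        )
    # TimeCourse.__post_init__ raises ShapeMismatchError on inconsistent stacks
    return TimeCourse(
        frames=frames,
        dt_hours=dt_hours,
        condition_id=str(meta.get("condition_id", "condition")),
        replicate_id=str(meta.get("replicate_id", "r1")),
    )


def save_timecourse(timecourse: TimeCourse, replicate_dir: str | Path) -> Path:
    """Write a time course in the layout :func:`load_timecourse` reads."""
    replicate_dir = Path(replicate_dir)
    channel_dir = replicate_dir / timecourse.channel
    channel_dir.mkdir(parents=True, exist_ok=True)
    width = max(3, len(str(len(timecourse) - 1)))
    for frame in timecourse.frames:
        tifffile.imwrite(
            channel_dir / f"t{frame.timestamp_index:0{width}d}.tif",
            np.asarray(frame.voxels),
            photometric="minisblack",
        )
    write_metadata(
        replicate_dir,
        {
            "resolution_um": list(timecourse.resolution),
            "dt_hours": timecourse.dt_hours,
            "condition_id": timecourse.condition_id,
            "replicate_id": timecourse.replicate_id,
        },
    )
    return replicate_dir


def tracks_to_table(
    tracks: list[Track],
    condition_id: str = "condition",
    replicate_id: str = "r1",
) -> pd.DataFrame:
    """Flatten tracks into one row per (track, time stamp).

    ROI locations in root coordinates (tip and axis distance) are taken
    from each ROI's ``tip_distance_um`` / ``center_distance_um`` fields;
    they are NaN when no root geometry was attached.
    """
    rows = []
    for track in tracks:
        for roi in track.rois:
            rows.append(
                {
                    "condition": condition_id,
                    "replicate": replicate_id,
                    "track_id": track.track_id,
                    "timestamp_index": roi.timestamp_index,
                    "time_h": roi.timestamp_index * track.dt_hours,
                    "centroid_z_um": roi.centroid_um[0],
                    "centroid_y_um": roi.centroid_um[1],
                    "centroid_x_um": roi.centroid_um[2],
                    "volume_voxels": roi.volume_voxels,
                    "tip_distance_um": roi.tip_distance_um,
                    "center_distance_um": roi.center_distance_um,
                    "persistency_h": track.persistency_h,
                }
            )
    table = pd.DataFrame(rows, columns=TRACK_TABLE_COLUMNS)
    return table.astype({k: v for k, v in _TRACK_TABLE_DTYPES.items() if k in table})


def _check_track_table(table: pd.DataFrame) -> None:
    missing = [c for c in TRACK_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise IntegrityError(f"track table is missing columns {missing}")
    if len(table):
        dupes = table.duplicated(subset=["condition", "replicate", "track_id", "timestamp_index"])
        if dupes.any():
            pair = table.loc[dupes.idxmax(), ["track_id", "timestamp_index"]]
            raise IntegrityError(
                f"duplicate (track_id, timestamp_index) pair "
                f"({pair['track_id']}, {pair['timestamp_index']})"
            )


def write_track_table(
    tracks: list[Track] | pd.DataFrame,
    path: str | Path,
    condition_id: str = "condition",
    replicate_id: str = "r1",
) -> pd.DataFrame:
    """Serialize tracks (or an already-flattened table) to CSV."""
    if isinstance(tracks, pd.DataFrame):
        table = tracks[TRACK_TABLE_COLUMNS].copy()
    else:
        table = tracks_to_table(tracks, condition_id=condition_id, replicate_id=replicate_id)
    _check_track_table(table)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return table


def read_track_table(path: str | Path) -> pd.DataFrame:
    """Read a track-table CSV written by :func:`write_track_table`."""
    table = pd.read_csv(path, dtype=_TRACK_TABLE_DTYPES, float_precision="round_trip")
    _check_track_table(table)
    return table[TRACK_TABLE_COLUMNS]
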