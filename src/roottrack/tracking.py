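"""Frame registration, ROI linking, track assembly and root growth.

The root moves as a whole between consecutive frames (growth plus any
residual stage drift), so a single translation per interval — found by
cross-correlation of the brightfield channel — both measures root growth
and drift-corrects ROI positions for linking.  Linking is greedy
nearest-centroid in µm after drift correction, one-to-one, with a
configurable gate; the resulting chains become tracks whose persistency
is the observed member count times the sampling interval.
"""

from __future__ import annotations

import numpy as np
from skimage.registration import phase_cross_correlation

from .model import GrowthCurve, ImageFrame, IntegrityError, Roi, Track


def register_frames(
    frame_a: ImageFrame,
    frame_b: ImageFrame,
    upsample_factor: int = 1,
) -> np.ndarray:
    """Translation (voxels, z/y/x) moving the content of ``frame_a`` onto
    ``frame_b``.

    Uses the phase-correlation peak; integer voxels by default, subvoxel
    when ``upsample_factor > 1``.  Deterministic.
    """
    a, b = np.asarray(frame_a.voxels), np.asarray(frame_b.voxels)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    # phase_cross_correlation returns the shift registering b onto a,
    # i.e. minus the displacement of the content from a to b
    shift, _, _ = phase_cross_correlation(
        a, b, upsample_factor=upsample_factor, normalization=None
    )
    return -np.asarray(shift)


def growth_magnitude(
    displacement_voxels: np.ndarray, resolution: tuple[float, float, float]
) -> float:
    """Euclidean µm magnitude of a voxel displacement.

    Each axis is converted with its own resolution before taking the
    norm: the axial step (3.33 µm) and lateral pixel (0.23 µm) differ
    14-fold, so a scalar conversion would misstate distances.
    """
    res = np.asarray(resolution, dtype=float)
    if np.any(res <= 0):
        raise ValueError("resolution components must be positive")
    return float(np.linalg.norm(np.asarray(displacement_voxels, dtype=float) * res))


def cumulative_growth(magnitudes_um) -> GrowthCurve:
    """Growth curve from per-interval displacement magnitudes.

    ``G(n)`` is the prefix sum of ``g`` with ``G(0) = 0``; raises on
    negative input.
    """
    return GrowthCurve(g_um=np.asarray(magnitudes_um, dtype=float))


def link_rois(
    rois_t: list[Roi],
    rois_t1: list[Roi],
    displacement_voxels: np.ndarray,
    resolution: tuple[float, float, float],
    max_link_distance_um: float = 10.0,
) -> list[tuple[int, int]]:
    """One-to-one greedy matching of ROIs between consecutive frames.

    Each ROI centroid at frame ``t`` is advanced by the registration
    displacement (converted to µm) and matched to the nearest unmatched
    centroid at ``t+1``, in ascending distance order, with ties broken by
    the lower ``(label_t, label_t1)`` pair.  Pairs farther apart than
    ``max_link_distance_um`` stay unmatched.

    Returns (index_t, index_t1) pairs into the two input lists.
    """
    if not rois_t or not rois_t1:
        return []
    res = np.asarray(resolution, dtype=float)
    shift_um = np.asarray(displacement_voxels, dtype=float) * res
    predicted = np.stack([r.centroid_um for r in rois_t]) + shift_um
    targets = np.stack([r.centroid_um for r in rois_t1])
    dists = np.linalg.norm(predicted[:, None, :] - targets[None, :, :], axis=2)

    candidates = [
        (dists[i, j], rois_t[i].label, rois_t1[j].label, i, j)
        for i in range(len(rois_t))
        for j in range(len(rois_t1))
        if dists[i, j] <= max_link_distance_um
    ]
    candidates.sort()
    used_t: set[int] = set()
    used_t1: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, _, _, i, j in candidates:
        if i in used_t or j in used_t1:
            continue
        used_t.add(i)
        used_t1.add(j)
        pairs.append((i, j))
    return pairs


def build_tracks(
    rois_per_frame: list[list[Roi]],
    assignments: list[list[tuple[int, int]]],
    dt_hours: float,
) -> list[Track]:
    """Chain per-interval assignments into tracks.

    ``assignments[n]`` links ``rois_per_frame[n]`` to
    ``rois_per_frame[n+1]``.  Every ROI ends up in exactly one track;
    persistency is member count × ``dt_hours``.  Track ids are assigned
    in order of (first frame, label at first frame).
    """
    n_frames = len(rois_per_frame)
    if len(assignments) != max(n_frames - 1, 0):
        raise ValueError("need one assignment list per consecutive frame pair")

    successor: dict[tuple[int, int], tuple[int, int]] = {}
    has_predecessor: set[tuple[int, int]] = set()
    for n, pairs in enumerate(assignments):
        for i, j in pairs:
            key = (n, i)
            if key in successor:
                raise IntegrityError(f"ROI {key} assigned two successors")
            target = (n + 1, j)
            if target in has_predecessor:
                raise IntegrityError(f"ROI {target} assigned two predecessors")
            successor[key] = target
            has_predecessor.add(target)

    tracks: list[Track] = []
    for n, rois in enumerate(rois_per_frame):
        for i, roi in enumerate(rois):
            if (n, i) in has_predecessor:
                continue  # not a chain head
            chain = [roi]
            cursor = (n, i)
            while cursor in successor:
                cursor = successor[cursor]
                chain.append(rois_per_frame[cursor[0]][cursor[1]])
            tracks.append(Track(track_id=len(tracks), rois=chain, dt_hours=dt_hours))

    total = sum(len(t.rois) for t in tracks)
    expected = sum(len(r) for r in rois_per_frame)
    if total != expected:
        raise IntegrityError(f"tracks cover {total} ROIs, expected {expected}")
    return tracks


def track_timecourse(
    rois_per_frame: list[list[Roi]],
    brightfield_frames: list[ImageFrame],
    dt_hours: float,
    max_link_distance_um: float = 10.0,
    upsample_factor: int = 1,
) -> tuple[list[Track], GrowthCurve, np.ndarray]:
    """Register all consecutive brightfield pairs, link ROIs, build tracks.

    Returns the tracks, the root growth curve, and the per-interval
    displacement vectors (voxels, shape ``(N-1, 3)``).
    """
    resolution = brightfield_frames[0].resolution
    n_frames = len(brightfield_frames)
    displacements = np.zeros((max(n_frames - 1, 0), 3))
    assignments = []
    for n in range(n_frames - 1):
        disp = register_frames(
            brightfield_frames[n], brightfield_frames[n + 1], upsample_factor=upsample_factor
        )
        displacements[n] = disp
        assignments.append(
            link_rois(
                rois_per_frame[n],
                rois_per_frame[n + 1],
                disp,
                resolution,
                max_link_distance_um=max_link_distance_um,
            )
        )
    tracks = build_tracks(rois_per_frame, assignments, dt_hours)
    magnitudes = [growth_magnitude(d, resolution) for d in displacements]
    return tracks, cumulative_growth(magnitudes), displacements
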