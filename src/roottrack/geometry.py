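"""Root coordinate system from the brightfield channel.

The root occupies the textured part of the brightfield image, so a
per-voxel gradient-energy feature (gradient magnitude with physical
spacing, smoothed over a small µm window) separates root tissue from the
smooth background.  A two-class k-means on that feature, followed by
largest-component selection and hole filling, yields the root mask; its
first principal axis defines the longitudinal axis and the extremal mask
voxel along that axis defines the tip.  ROI positions are then expressed
as straight-line distance to the tip and perpendicular distance to the
axis, both in µm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .model import DegenerateInputError, ImageFrame, Roi

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class RootGeometry:
    """Root mask, tip point and longitudinal axis for one time stamp."""

    root_mask: np.ndarray
    tip_point_um: np.ndarray  # (3,) µm
    axis_point_um: np.ndarray  # (3,) a point on the axis, µm
    axis_direction: np.ndarray  # (3,) unit vector, oriented toward the tip
    timestamp_index: int

    def __post_init__(self) -> None:
        self.tip_point_um = np.asarray(self.tip_point_um, dtype=float)
        self.axis_point_um = np.asarray(self.axis_point_um, dtype=float)
        self.axis_direction = np.asarray(self.axis_direction, dtype=float)
        norm = np.linalg.norm(self.axis_direction)
        if not np.isclose(norm, 1.0, atol=1e-8):
            raise ValueError("axis_direction must be a unit vector")


def gradient_energy(
    voxels: np.ndarray,
    resolution: tuple[float, float, float],
    smooth_um: float = 2.0,
) -> np.ndarray:
    """Smoothed gradient-magnitude feature used for root/background clustering."""
    voxels = np.asarray(voxels, dtype=float)
    grads = np.gradient(voxels, *resolution) if voxels.ndim == 3 else [np.gradient(voxels)]
    magnitude = np.sqrt(sum(g**2 for g in grads))
    sigma_vox = smooth_um / np.asarray(resolution)
    return ndimage.gaussian_filter(magnitude, sigma=sigma_vox)


def classify_root_voxels(
    frame: ImageFrame,
    n_clusters: int = 2,
    seed: int = 0,
    smooth_um: float = 2.0,
) -> np.ndarray:
    """Estimate which voxels contain root tissue.

    Clusters the per-voxel gradient-energy feature into ``n_clusters``
    groups with k-means (fixed seed, deterministic); the cluster with the
    highest mean gradient energy is the root class.  The mask is reduced
    to its largest 26-connected component with holes filled.

    Raises
    ------
    DegenerateInputError
        If the image is constant (no texture to cluster).
    """
    voxels = np.asarray(frame.voxels)
    if np.ptp(voxels) == 0:
        raise DegenerateInputError(
            f"brightfield frame {frame.timestamp_index} is constant; no texture to classify"
        )
    features = gradient_energy(voxels, frame.resolution, smooth_um=smooth_um)
    flat = features.reshape(-1, 1)
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=3)
    assignments = km.fit_predict(flat)
    root_class = int(np.argmax(km.cluster_centers_.ravel()))
    mask = (assignments == root_class).reshape(voxels.shape)

    components, n_comp = ndimage.label(mask, structure=_CONN26)
    if n_comp == 0:
        raise DegenerateInputError("clustering produced an empty root mask")
    sizes = ndimage.sum_labels(mask, components, index=np.arange(1, n_comp + 1))
    mask = components == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def estimate_axis_and_tip(
    root_mask: np.ndarray,
    resolution: tuple[float, float, float],
    timestamp_index: int = 0,
    tip_side: str = "positive",
) -> RootGeometry:
    """Fit the longitudinal axis and locate the tip from a root mask.

    The axis is the first principal component of the mask voxel
    coordinates in µm, anchored at their centroid; the tip is the mask
    voxel whose projection onto the axis is extremal on the chosen side
    (``tip_side``: ``"positive"`` or ``"negative"``), ties broken by
    smallest (z, y, x).  The returned direction is oriented toward the
    tip.

    Raises
    ------
    DegenerateInputError
        If the mask is empty or has no spatial extent (single voxel).
    """
    root_mask = np.asarray(root_mask, dtype=bool)
    coords_vox = np.argwhere(root_mask)
    if len(coords_vox) == 0:
        raise DegenerateInputError("cannot estimate axis and tip of an empty root mask")
    if len(coords_vox) == 1:
        raise DegenerateInputError(
            f"root mask is a single voxel at {tuple(coords_vox[0])}; axis undefined"
        )
    coords_um = coords_vox * np.asarray(resolution)
    centroid = coords_um.mean(axis=0)
    centered = coords_um - centroid
    cov = centered.T @ centered / len(centered)
    eigvals, eigvecs = np.linalg.eigh(cov)
    direction = eigvecs[:, -1]  # largest-variance axis
    # canonical sign (largest-magnitude component positive) so the two
    # axis ends are stable across frames; tip_side then picks one end
    lead = int(np.argmax(np.abs(direction)))
    if direction[lead] < 0:
        direction = -direction

    projections = centered @ direction
    if tip_side == "negative":
        direction = -direction
        projections = -projections
    elif tip_side != "positive":
        raise ValueError("tip_side must be 'positive' or 'negative'")
    extremal = projections.max()
    candidates = np.flatnonzero(np.isclose(projections, extremal))
    # deterministic tie-break: smallest (z, y, x) voxel index
    winner = candidates[np.lexsort(coords_vox[candidates].T[::-1])[0]]
    return RootGeometry(
        root_mask=root_mask,
        tip_point_um=coords_um[winner],
        axis_point_um=centroid,
        axis_direction=direction,
        timestamp_index=timestamp_index,
    )


def locate_roi(roi: Roi, geometry: RootGeometry) -> tuple[float, float]:
    """Distances (µm) from an ROI centroid to the root tip and axis.

    Returns ``(tip_distance, center_distance)``: the straight-line
    distance to the tip point and the perpendicular distance to the
    longitudinal axis line.
    """
    if roi.timestamp_index != geometry.timestamp_index:
        raise ValueError(
            f"ROI frame {roi.timestamp_index} does not match geometry frame "
            f"{geometry.timestamp_index}"
        )
    c = np.asarray(roi.centroid_um, dtype=float)
    tip_distance = float(np.linalg.norm(c - geometry.tip_point_um))
    rel = c - geometry.axis_point_um
    along = rel @ geometry.axis_direction
    center_distance = float(np.linalg.norm(rel - along * geometry.axis_direction))
    return tip_distance, center_distance


def locate_rois(rois: list[Roi], geometry: RootGeometry) -> list[Roi]:
    """Annotate ROIs in place with tip and center distances; returns them."""
    for roi in rois:
        roi.tip_distance_um, roi.center_distance_um = locate_roi(roi, geometry)
    return rois
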