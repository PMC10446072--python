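"""Spheroid detection, core/mantle partition, and cell-ECM co-localization.

The core/mantle partition follows the volumetric convention of the GA3
and Imaris pipelines: erode the whole-spheroid mask until a target
fraction of its volume remains as the core, the rest being the mantle
shell. Erosion depth is physical (µm-calibrated through the anisotropic
Euclidean distance transform), so the shell has uniform physical
thickness despite anisotropic voxels, and a distance-quantile refinement
hits the requested fraction within 2 % even on small masks where whole
erosion steps are too coarse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .core import LabelMap, VoxelGeometry
from .segment import threshold_otsu

__all__ = [
    "RegionPartition",
    "spheroid_mask",
    "core_mantle_partition",
    "assign_regions",
    "layer_based_regions",
    "object_contacts",
]

log = logging.getLogger(__name__)

#: Tolerance on |achieved - requested| core-volume fraction.
PARTITION_TOLERANCE = 0.02


@dataclass
class RegionPartition:
    """Disjoint core/mantle masks partitioning a spheroid mask."""

    core_mask: np.ndarray
    mantle_mask: np.ndarray
    achieved_core_fraction: float
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        if np.any(self.core_mask & self.mantle_mask):
            raise ValueError("core and mantle masks overlap")

    @property
    def spheroid(self) -> np.ndarray:
        return self.core_mask | self.mantle_mask


def spheroid_mask(
    nuclei: np.ndarray, geometry: VoxelGeometry, closing_radius_um: float = 14.0
) -> np.ndarray:
    """One solid mask of the whole spheroid from the nuclei channel.

    Global Otsu threshold, morphological closing with a µm-calibrated
    ball, per-slice hole filling, then the largest connected component.
    The default closing radius (14 µm, about two cell diameters) bridges
    both inter-nuclear gaps and the surface dips between the outermost
    nuclei, so the mask tracks the aggregate's envelope rather than the
    scalloped union of nuclei.
    """
    nuclei = np.asarray(nuclei, dtype=np.float64)
    if nuclei.min() == nuclei.max():
        raise ValueError("spheroid_mask: empty or constant nuclei channel")
    binary = threshold_otsu(nuclei, mode="global")
    if not binary.any():
        raise ValueError("spheroid_mask: empty foreground after thresholding")
    # µm-calibrated ball closing via two distance transforms (equivalent to
    # dilation+erosion with a ball element, but linear-time)
    d_to_fg = ndi.distance_transform_edt(~binary, sampling=geometry.spacing_zyx)
    dilated = d_to_fg <= closing_radius_um
    d_inside = ndi.distance_transform_edt(dilated, sampling=geometry.spacing_zyx)
    closed = d_inside > closing_radius_um
    closed |= binary  # closing never removes original foreground
    filled = np.empty_like(closed)
    for k in range(closed.shape[0]):
        filled[k] = ndi.binary_fill_holes(closed[k])
    labels, n = ndi.label(filled)
    if n == 0:
        raise ValueError("spheroid_mask: no component survived closing")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == counts.argmax()
    log.debug("spheroid_mask: %d components, kept largest (%d voxels)", n, counts.max())
    return mask


def core_mantle_partition(
    mask: np.ndarray, core_fraction: float, geometry: VoxelGeometry
) -> RegionPartition:
    """Erode a spheroid mask into a core holding ``core_fraction`` of its volume.

    The core is the set of mask voxels whose µm distance to the mask
    boundary is at least a threshold d, equivalent to d/step erosions
    with a µm-calibrated element; d is chosen as the distance quantile
    putting the achieved core fraction closest to the target
    (|achieved - target| <= 0.02 whenever the mask's distance values
    permit it). The mantle is the remainder.
    """
    mask = np.asarray(mask, dtype=bool)
    n_total = int(mask.sum())
    if n_total == 0:
        raise ValueError("core_mantle_partition: empty mask")
    if n_total == 1:
        raise ValueError("core_mantle_partition: single-voxel mask cannot be eroded")
    if not (0.0 < core_fraction < 1.0):
        raise ValueError(f"core_fraction must be in (0, 1), got {core_fraction}")
    dist = ndi.distance_transform_edt(mask, sampling=geometry.spacing_zyx)
    inside = np.sort(dist[mask])
    # keep the deepest core_fraction of voxels: search every distinct
    # distance value for the cut whose achieved fraction is closest to
    # the target (ties in the distance transform make a naive quantile
    # index unreliable)
    values, first_idx = np.unique(inside, return_index=True)
    achieved_all = (n_total - first_idx) / n_total  # fraction kept at each cut
    valid = (achieved_all > 0.0) & (achieved_all < 1.0)
    if not valid.any():
        raise ValueError(
            "core_mantle_partition: mask too small to erode toward "
            f"core_fraction={core_fraction}"
        )
    errs = np.where(valid, np.abs(achieved_all - core_fraction), np.inf)
    best_thr = values[int(np.argmin(errs))]
    core = mask & (dist >= best_thr)
    if not core.any() or core.sum() == n_total:
        raise ValueError(
            "core_mantle_partition: mask too small to erode toward "
            f"core_fraction={core_fraction}"
        )
    mantle = mask & ~core
    achieved = float(core.sum()) / n_total
    log.debug("core_mantle_partition: target %.3f achieved %.4f (d=%.3g µm)",
              core_fraction, achieved, best_thr)
    return RegionPartition(
        core_mask=core, mantle_mask=mantle,
        achieved_core_fraction=achieved, geometry=geometry,
    )


def assign_regions(objects: pd.DataFrame, partition: RegionPartition) -> pd.DataFrame:
    """Tag each object core/mantle by its centroid voxel; returns a copy.

    Centroids outside both masks (outside the spheroid) are tagged
    ``unassigned``.
    """
    g = partition.geometry
    out = objects.copy()
    if len(out) == 0:
        return out
    shape = partition.core_mask.shape
    iz, iy, ix, inside = _centroid_voxels(
        out, g, shape, ("centroid_x_um", "centroid_y_um", "centroid_z_um")
    )
    regions = np.full(len(out), "unassigned", dtype=object)
    regions[inside & partition.core_mask[iz, iy, ix]] = "core"
    regions[inside & partition.mantle_mask[iz, iy, ix]] = "mantle"
    out["region"] = regions
    return out


def _centroid_voxels(table, geometry, shape, cols):
    """Voxel indices of centroid positions, clipped, plus in-bounds flags."""
    x_col, y_col, z_col = cols
    iz = np.floor(table[z_col].to_numpy(float) / geometry.z_step).astype(int)
    iy = np.floor(table[y_col].to_numpy(float) / geometry.pixel_size_xy).astype(int)
    ix = np.floor(table[x_col].to_numpy(float) / geometry.pixel_size_xy).astype(int)
    inside = (
        (iz >= 0) & (iz < shape[0]) & (iy >= 0) & (iy < shape[1])
        & (ix >= 0) & (ix < shape[2])
    )
    return (np.clip(iz, 0, shape[0] - 1), np.clip(iy, 0, shape[1] - 1),
            np.clip(ix, 0, shape[2] - 1), inside)


def layer_based_regions(
    objects: pd.DataFrame,
    mask: np.ndarray,
    n_layers: float,
    cell_diameter: float,
    geometry: VoxelGeometry,
    x_col: str = "centroid_x_um",
    y_col: str = "centroid_y_um",
    z_col: str = "centroid_z_um",
) -> pd.DataFrame:
    """Manual-convention regions: mantle = within ``n_layers`` cell layers of the surface.

    A centroid is mantle iff its distance to the mask surface is at most
    ``n_layers x cell_diameter`` µm; deeper centroids are core. Centroids
    outside the mask are mantle (they sit at or beyond the surface).
    This emulates the by-eye peripheral-layer convention for comparison
    against the volumetric partition. ``n_layers = 0`` puts everything in
    the core.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("layer_based_regions: empty mask")
    out = objects.copy()
    if len(out) == 0:
        return out
    dist = ndi.distance_transform_edt(mask, sampling=geometry.spacing_zyx)
    cutoff = n_layers * cell_diameter
    iz, iy, ix, inside = _centroid_voxels(out, geometry, mask.shape,
                                          (x_col, y_col, z_col))
    regions = np.where(inside & (dist[iz, iy, ix] > cutoff), "core", "mantle")
    out["region"] = regions.astype(object)
    return out


def object_contacts(
    children: LabelMap,
    parents: LabelMap,
    max_distance: float,
    geometry: VoxelGeometry | None = None,
    touching_counts: bool = True,
) -> pd.DataFrame:
    """Object-based co-localization: which child objects touch a parent object.

    A child interacts iff its minimum surface-to-surface distance to any
    parent object is at most ``max_distance`` µm, measured between voxel
    centres through the µm-calibrated distance transform of the parent
    foreground (overlapping voxels are at distance 0). At
    ``max_distance = 0`` the criterion reduces to voxel overlap or,
    when ``touching_counts`` (default), 26-adjacency — touching is the
    boundary case of "< 0 µm distance" overlap scoring.

    Returns one row per child: ``child_id``, ``nearest_parent_id``,
    ``distance_um``, ``interacting``.
    """
    geometry = geometry or children.geometry
    if children.labels.shape != parents.labels.shape:
        raise ValueError("children and parents label maps differ in shape")
    child_lab = children.labels
    parent_fg = parents.labels > 0
    rows = []
    child_ids = children.label_values()
    if len(child_ids) == 0:
        return pd.DataFrame(
            columns=["child_id", "nearest_parent_id", "distance_um", "interacting"]
        )
    if not parent_fg.any():
        for cid in child_ids:
            rows.append({"child_id": int(cid), "nearest_parent_id": 0,
                         "distance_um": np.inf, "interacting": False})
        return pd.DataFrame(rows)
    dist, (iz, iy, ix) = ndi.distance_transform_edt(
        ~parent_fg, sampling=geometry.spacing_zyx, return_indices=True
    )
    d_min = ndi.minimum(dist, labels=child_lab, index=child_ids)
    argmins = ndi.minimum_position(dist, labels=child_lab, index=child_ids)
    if max_distance == 0:
        if touching_counts:
            # dilate parents by one voxel in every direction (26-neighbourhood)
            touch_fg = ndi.binary_dilation(parent_fg, structure=np.ones((3, 3, 3), bool))
        else:
            touch_fg = parent_fg
        touching_ids = set(np.unique(child_lab[touch_fg]).tolist()) - {0}
    else:
        touching_ids = None
    for cid, d, vox in zip(child_ids, np.atleast_1d(d_min), argmins):
        nearest = int(parents.labels[iz[vox], iy[vox], ix[vox]])
        if touching_ids is not None:
            interacting = int(cid) in touching_ids
        else:
            interacting = float(d) <= max_distance
        rows.append({"child_id": int(cid), "nearest_parent_id": nearest,
                     "distance_um": float(d), "interacting": bool(interacting)})
    out = pd.DataFrame(rows)
    log.debug("object_contacts: %d/%d children interacting (max_distance=%g µm)",
              int(out["interacting"].sum()), len(out), max_distance)
    return out
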