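"""SUV thresholding and connected-component labelling of hypermetabolic lesions.

The segmentation model is deliberately simple: a fixed absolute SUV threshold
(default 4.0, strict inequality) selects hypermetabolic voxels, and connected
components of the resulting binary mask are the lesions.  Classification of
components into pathological vs. physiological uptake is out of scope; masks
are assumed to contain pathological lesions only.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import SuvVolume

#: full 3x3x3 neighborhood (voxels touching at faces, edges or corners)
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)
#: face neighbors only
CONNECTIVITY_6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class Lesion:
    """One connected lesion: its voxels, centroid and boundary."""

    label: int
    indices: np.ndarray  # (n, 3) int voxel indices
    centroid_mm: np.ndarray  # (3,) unweighted mean of voxel centers
    boundary_indices: np.ndarray  # (b, 3) voxels with a face neighbor outside the mask
    volume_ml: float

    @property
    def n_voxels(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class LesionSet:
    """Labelled lesions on a voxel grid (0 = background, 1..n = lesions).

    Labels are contiguous and sorted by descending voxel count, ties broken by
    the lexicographically smallest voxel index in the component.
    """

    label_map: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]
    lesions: tuple[Lesion, ...]

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)

    @property
    def mask(self) -> np.ndarray:
        return self.label_map > 0

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz


class EmptyLesionSetError(ValueError):
    """Raised when a computation requires at least one pathological lesion."""


def threshold_segment(volume: SuvVolume, threshold: float = 4.0) -> np.ndarray:
    """Binary mask of voxels with SUV strictly greater than ``threshold``.

    An empty mask is legal (no pathological uptake above threshold).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    return volume.values > threshold


def boundary_mask(mask: np.ndarray) -> np.ndarray:
    """Mask voxels having at least one face neighbor outside the mask.

    Array borders count as outside: a voxel on the edge of the grid is a
    boundary voxel.
    """
    interior = ndimage.binary_erosion(mask, structure=CONNECTIVITY_6, border_value=0)
    return mask & ~interior


def label_components(
    mask: np.ndarray,
    spacing_mm: tuple[float, float, float],
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    connectivity: int = 26,
) -> LesionSet:
    """Partition a binary mask into connected lesions.

    Parameters
    ----------
    mask
        3D boolean array.
    spacing_mm, origin_mm
        Grid geometry; centroids and boundaries are expressed in mm.
    connectivity
        26 (default; merges diagonally-touching masses, as clinical readers
        do) or 6 (face neighbors only).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    if connectivity == 26:
        structure = CONNECTIVITY_26
    elif connectivity == 6:
        structure = CONNECTIVITY_6
    else:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")

    raw_labels, n = ndimage.label(mask, structure=structure)
    spacing = tuple(float(s) for s in spacing_mm)
    origin = tuple(float(o) for o in origin_mm)
    voxel_vol_ml = spacing[0] * spacing[1] * spacing[2] / 1000.0

    if n == 0:
        return LesionSet(
            label_map=np.zeros(mask.shape, dtype=np.int32),
            spacing_mm=spacing,
            origin_mm=origin,
            lesions=(),
        )

    # sort labels: descending voxel count, then lexicographic seed voxel
    order = []
    for lab in range(1, n + 1):
        idx = np.argwhere(raw_labels == lab)
        seed = tuple(idx[0])  # argwhere is C-ordered -> lexicographic minimum
        order.append((-len(idx), seed, idx))
    order.sort(key=lambda t: (t[0], t[1]))

    label_map = np.zeros(mask.shape, dtype=np.int32)
    bnd = boundary_mask(mask)
    lesions = []
    for new_label, (_, _, idx) in enumerate(order, start=1):
        label_map[tuple(idx.T)] = new_label
        centers = np.asarray(origin) + idx * np.asarray(spacing)
        on_boundary = bnd[tuple(idx.T)]
        lesions.append(
            Lesion(
                label=new_label,
                indices=idx,
                centroid_mm=centers.mean(axis=0),
                boundary_indices=idx[on_boundary],
                volume_ml=len(idx) * voxel_vol_ml,
            )
        )
    return LesionSet(label_map=label_map, spacing_mm=spacing, origin_mm=origin, lesions=tuple(lesions))


def lesion_set_from_labels(
    label_map: np.ndarray,
    spacing_mm: tuple[float, float, float],
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> LesionSet:
    """Build a LesionSet from an externally produced integer label map.

    Labels need not be contiguous; they are recompacted with the standard
    ordering (descending volume, then seed voxel).
    """
    label_map = np.asarray(label_map)
    spacing = tuple(float(s) for s in spacing_mm)
    origin = tuple(float(o) for o in origin_mm)
    voxel_vol_ml = spacing[0] * spacing[1] * spacing[2] / 1000.0
    labels = np.unique(label_map)
    labels = labels[labels > 0]

    order = []
    for lab in labels:
        idx = np.argwhere(label_map == lab)
        order.append((-len(idx), tuple(idx[0]), idx))
    order.sort(key=lambda t: (t[0], t[1]))

    new_map = np.zeros(label_map.shape, dtype=np.int32)
    bnd = boundary_mask(label_map > 0)
    lesions = []
    for new_label, (_, _, idx) in enumerate(order, start=1):
        new_map[tuple(idx.T)] = new_label
        centers = np.asarray(origin) + idx * np.asarray(spacing)
        on_boundary = bnd[tuple(idx.T)]
        lesions.append(
            Lesion(
                label=new_label,
                indices=idx,
                centroid_mm=centers.mean(axis=0),
                boundary_indices=idx[on_boundary],
                volume_ml=len(idx) * voxel_vol_ml,
            )
        )
    return LesionSet(label_map=new_map, spacing_mm=spacing, origin_mm=origin, lesions=tuple(lesions))


def min_size_filter(lesions: LesionSet, min_voxels: int = 1) -> LesionSet:
    """Drop lesions with fewer than ``min_voxels`` voxels; recompact labels."""
    if min_voxels < 1:
        raise ValueError(f"min_voxels must be >= 1, got {min_voxels}")
    if min_voxels == 1:
        return lesions
    keep = [les for les in lesions.lesions if les.n_voxels >= min_voxels]
    label_map = np.zeros(lesions.label_map.shape, dtype=np.int32)
    relabelled = []
    for new_label, les in enumerate(keep, start=1):
        label_map[tuple(les.indices.T)] = new_label
        relabelled.append(
            Lesion(
                label=new_label,
                indices=les.indices,
                centroid_mm=les.centroid_mm,
                boundary_indices=les.boundary_indices,
                volume_ml=les.volume_ml,
            )
        )
    return LesionSet(
        label_map=label_map,
        spacing_mm=lesions.spacing_mm,
        origin_mm=lesions.origin_mm,
        lesions=tuple(relabelled),
    )
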