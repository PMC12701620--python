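"""The 12 quantitative 3D PET parameters.

Four families:

* activity      — SUVmax, SUVmean, TLG
* tumor burden  — TMTV, TMTS, TVSR
* dispersion    — Dmax, TumBB, nROI
* massiveness   — itErosion, medEdgeD, medPCD

All are computed from a binary/labelled lesion mask on the voxel grid; no
mesh extraction or partial-volume modelling is involved, so every quantity
has an exact combinatorial definition that a brute-force oracle can check.

Conventions: voxel membership is all-or-nothing, distances are between voxel
centers in mm, volumes in ml (cm^3), surfaces in cm^2.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .segmentation import CONNECTIVITY_26, EmptyLesionSetError, LesionSet
from .volume import SuvVolume

#: canonical column order for feature tables
FEATURE_COLUMNS = [
    "suv_max",
    "suv_mean",
    "tmtv_ml",
    "tlg_g",
    "tmts_cm2",
    "tvsr_mm",
    "dmax_mm",
    "tumbb_ml",
    "n_roi",
    "it_erosion",
    "med_edge_d_mm",
    "med_pcd_mm",
]

#: the four correlation families the features fall into
FEATURE_CLUSTERS = {
    "activity": ["suv_max", "suv_mean"],
    "burden": ["tmtv_ml", "tmts_cm2"],
    "massiveness": ["med_pcd_mm", "med_edge_d_mm", "it_erosion", "tvsr_mm"],
    "dispersion": ["dmax_mm", "tumbb_ml", "n_roi"],
}
#: total lesion glycolysis sits at the junction of activity and burden
JUNCTION_FEATURE = "tlg_g"


@dataclass(frozen=True)
class FeatureVector:
    """The 12 PET parameters for one patient."""

    suv_max: float
    suv_mean: float
    tmtv_ml: float
    tlg_g: float
    tmts_cm2: float
    tvsr_mm: float
    dmax_mm: float
    tumbb_ml: float
    n_roi: int
    it_erosion: float
    med_edge_d_mm: float
    med_pcd_mm: float

    def as_dict(self) -> dict[str, float]:
        d = asdict(self)
        return {k: d[k] for k in FEATURE_COLUMNS}


def _require_lesions(lesions: LesionSet) -> None:
    if lesions.n_lesions == 0:
        raise EmptyLesionSetError("no pathological lesion: features are undefined")


# ---------------------------------------------------------------------------
# activity
# ---------------------------------------------------------------------------

def activity_features(volume: SuvVolume, lesions: LesionSet) -> tuple[float, float, float]:
    """(SUVmax, SUVmean, TLG) pooled over all lesion voxels.

    SUVmean is the mean over the union of all lesion voxels (voxel-pooled,
    not a mean of per-lesion means); TLG = TMTV x SUVmean, in grams.
    """
    _require_lesions(lesions)
    suv = volume.values[lesions.mask]
    suv_max = float(suv.max())
    suv_mean = float(suv.mean())
    tmtv_ml = float(lesions.mask.sum()) * lesions.voxel_volume_mm3 / 1000.0
    return suv_max, suv_mean, tmtv_ml * suv_mean


# ---------------------------------------------------------------------------
# burden
# ---------------------------------------------------------------------------

def exposed_face_area_mm2(mask: np.ndarray, spacing_mm: tuple[float, float, float]) -> float:
    """Total area of faces separating a mask voxel from a non-mask voxel.

    Faces are counted per orientation with the anisotropy-correct face area
    (the product of the two orthogonal spacings).  Grid borders count as
    outside.
    """
    mask = np.asarray(mask, dtype=bool)
    s = spacing_mm
    face_areas = (s[1] * s[2], s[0] * s[2], s[0] * s[1])
    total = 0.0
    for axis, area in enumerate(face_areas):
        padded = np.pad(mask, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        diff = padded.astype(np.int8)
        n_exposed = np.abs(np.diff(diff, axis=axis)).sum()
        total += float(n_exposed) * area
    return total


def burden_features(lesions: LesionSet) -> tuple[float, float, float]:
    """(TMTV ml, TMTS cm^2, TVSR mm).

    TMTV = voxel count x voxel volume; TMTS by exposed-face counting (a
    deterministic, exactly checkable surface estimate, systematically larger
    than a smooth-surface mesh for curved shapes); TVSR = TMTV / TMTS in mm.
    """
    _require_lesions(lesions)
    tmtv_mm3 = float(lesions.mask.sum()) * lesions.voxel_volume_mm3
    tmts_mm2 = exposed_face_area_mm2(lesions.mask, lesions.spacing_mm)
    return tmtv_mm3 / 1000.0, tmts_mm2 / 100.0, tmtv_mm3 / tmts_mm2


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def _max_pairwise_distance(points: np.ndarray) -> float:
    """Largest Euclidean distance between any two points.

    The maximum is attained on the convex hull, so for large clouds the hull
    vertices are enumerated instead of all pairs; the arithmetic on the
    surviving pairs is identical to the direct computation.
    """
    if len(points) < 2:
        return 0.0
    if len(points) > 1500:
        try:
            hull = ConvexHull(points)
            points = points[hull.vertices]
        except QhullError:  # degenerate (coplanar/collinear) clouds
            pass
    return float(pdist(points).max())


def dispersion_features(lesions: LesionSet) -> tuple[float, float, int]:
    """(Dmax mm, TumBB ml, nROI).

    Dmax is the maximum distance between any two lesion-voxel centers across
    all lesions pooled — for a single lesion it reduces to that lesion's own
    maximal diameter.  TumBB is the axis-aligned bounding box spanning all
    lesion voxels, each voxel contributing its full extent.
    """
    _require_lesions(lesions)
    all_idx = np.vstack([les.indices for les in lesions.lesions])
    centers = np.asarray(lesions.origin_mm) + all_idx * np.asarray(lesions.spacing_mm)
    dmax = _max_pairwise_distance(centers)
    extent_vox = all_idx.max(axis=0) - all_idx.min(axis=0) + 1
    tumbb_mm3 = float(np.prod(extent_vox * np.asarray(lesions.spacing_mm)))
    return dmax, tumbb_mm3 / 1000.0, lesions.n_lesions


# ---------------------------------------------------------------------------
# massiveness
# ---------------------------------------------------------------------------

class _DenseComponent:
    """Dense boolean mask of one component over its bounding box, for O(1)
    voxel-membership lookups."""

    def __init__(self, les_indices: np.ndarray):
        self.lo = les_indices.min(axis=0)
        self.hi = les_indices.max(axis=0)
        self.mask = np.zeros(tuple(self.hi - self.lo + 1), dtype=bool)
        self.mask[tuple((les_indices - self.lo).T)] = True

    def contains(self, idx: np.ndarray) -> np.ndarray:
        """Vectorized membership of an (n, 3) int index array."""
        rel = idx - self.lo
        inside = np.all((rel >= 0) & (rel <= self.hi - self.lo), axis=-1)
        rel = np.clip(rel, 0, self.hi - self.lo)
        return inside & self.mask[rel[..., 0], rel[..., 1], rel[..., 2]]


def _resample_component_to_grid(
    les_indices: np.ndarray,
    spacing_mm: tuple[float, float, float],
    origin_mm: tuple[float, float, float],
    target_mm: float,
) -> np.ndarray:
    """Nearest-neighbor resampling of one component onto an isotropic grid.

    The target grid covers the component's bounding box with one voxel of
    margin; each target voxel takes the value of the source voxel nearest to
    its center.
    """
    spacing = np.asarray(spacing_mm)
    origin = np.asarray(origin_mm)
    lo_mm = origin + les_indices.min(axis=0) * spacing - target_mm
    hi_mm = origin + les_indices.max(axis=0) * spacing + target_mm
    n_vox = np.maximum(np.ceil((hi_mm - lo_mm) / target_mm).astype(int) + 1, 1)

    dense = _DenseComponent(les_indices)
    axes = [lo_mm[a] + target_mm * np.arange(n_vox[a]) for a in range(3)]
    # nearest source voxel index for each target center, per axis
    near = [np.rint((axes[a] - origin[a]) / spacing[a]).astype(int) for a in range(3)]
    ii, jj, kk = np.meshgrid(*near, indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1)
    return dense.contains(idx)


_STRUCTURING_ELEMENTS = {
    "cube": CONNECTIVITY_26,  # full 3x3x3
    "cross": ndimage.generate_binary_structure(3, 1),  # faces only
}


def erosion_count(component_mask: np.ndarray, structuring_element: str = "cube") -> int:
    """Number of erosions needed to remove a component entirely."""
    structure = _STRUCTURING_ELEMENTS[structuring_element]
    count = 0
    current = component_mask
    while current.any():
        current = ndimage.binary_erosion(current, structure=structure, border_value=0)
        count += 1
    return count


def iterative_erosion(
    lesions: LesionSet, erosion_spacing_mm: float = 4.0, structuring_element: str = "cube"
) -> float:
    """Mean per-component erosion depth on an isotropic coarse grid.

    Each connected component is resampled (nearest neighbor) to an isotropic
    ``erosion_spacing_mm`` grid and eroded with a full 3x3x3 structuring
    element until it vanishes.  A component that disappears on resampling
    contributes a count of 1.  The index is the unweighted mean over
    components, which is non-integer for mixed lesion sizes.
    """
    _require_lesions(lesions)
    counts = []
    for les in lesions.lesions:
        grid = _resample_component_to_grid(
            les.indices, lesions.spacing_mm, lesions.origin_mm, erosion_spacing_mm
        )
        counts.append(max(erosion_count(grid, structuring_element), 1))
    return float(np.mean(counts))


def _pooled_median(per_lesion: list[np.ndarray], pooling: str) -> float:
    """Median over all (lesion, boundary-voxel) values, or median of
    per-lesion medians when ``pooling == "per-lesion"``."""
    if pooling == "pooled":
        return float(np.median(np.concatenate(per_lesion)))
    if pooling == "per-lesion":
        return float(np.median([np.median(d) for d in per_lesion]))
    raise ValueError(f"pooling must be 'pooled' or 'per-lesion', got {pooling!r}")


def median_centroid_periphery_distance(lesions: LesionSet, pooling: str = "pooled") -> float:
    """Median distance from lesion centroids to their boundary-voxel centers.

    Distances are pooled over all (lesion, boundary voxel) pairs before
    taking the median, so large lesions weigh more — consistent with reading
    the index as overall massiveness.
    """
    _require_lesions(lesions)
    spacing = np.asarray(lesions.spacing_mm)
    origin = np.asarray(lesions.origin_mm)
    dists = []
    for les in lesions.lesions:
        centers = origin + les.boundary_indices * spacing
        dists.append(np.linalg.norm(centers - les.centroid_mm, axis=1))
    return _pooled_median(dists, pooling)


def _edge_chords_one_lesion(
    les_indices: np.ndarray,
    centroid_mm: np.ndarray,
    boundary_indices: np.ndarray,
    spacing_mm: tuple[float, float, float],
    origin_mm: tuple[float, float, float],
    step_mm: float,
) -> np.ndarray:
    """Chord lengths from each boundary voxel through the centroid to the
    opposite edge of the lesion, by ray marching with nearest-voxel lookup."""
    spacing = np.asarray(spacing_mm)
    origin = np.asarray(origin_mm)
    dense = _DenseComponent(les_indices)
    starts = origin + boundary_indices * spacing
    dirvec = centroid_mm - starts
    norms = np.linalg.norm(dirvec, axis=1)

    # generous upper bound on any chord: bounding-box diagonal
    extent = (les_indices.max(axis=0) - les_indices.min(axis=0) + 1) * spacing
    max_t = float(np.linalg.norm(extent)) + 2 * step_mm
    n_steps = int(math.ceil(max_t / step_mm)) + 1
    ts = step_mm * np.arange(1, n_steps + 1)

    degenerate = norms < 1e-12  # single-voxel lesion: ray direction undefined
    unit = np.where(degenerate[:, None], 1.0, dirvec / np.where(degenerate, 1.0, norms)[:, None])
    # (B, T, 3) sample points along every ray
    pts = starts[:, None, :] + ts[None, :, None] * unit[:, None, :]
    near = np.rint((pts - origin) / spacing).astype(int)
    inside = dense.contains(near)  # (B, T)
    outside = ~inside
    first_out = np.where(outside.any(axis=1), outside.argmax(axis=1), len(ts) - 1)
    chords = ts[first_out]
    chords[degenerate] = 0.0
    return chords


def median_edge_distance(
    lesions: LesionSet, step_fraction: float = 0.25, pooling: str = "pooled"
) -> float:
    """Median edge-to-opposite-edge distance, pooled over boundary voxels.

    For every boundary voxel the ray through the lesion's centroid is marched
    (step = ``step_fraction`` x the minimum spacing, nearest-voxel membership
    test on the native grid) until it leaves the component; the chord length
    from the boundary voxel to the exit point is one edge distance.  For a
    roughly convex lesion the chord through the centroid approximates the
    distance between opposite edges, ~ the local diameter.
    """
    _require_lesions(lesions)
    step_mm = step_fraction * min(lesions.spacing_mm)
    chords = [
        _edge_chords_one_lesion(
            les.indices, les.centroid_mm, les.boundary_indices,
            lesions.spacing_mm, lesions.origin_mm, step_mm,
        )
        for les in lesions.lesions
    ]
    return _pooled_median(chords, pooling)


def massiveness_features(
    lesions: LesionSet,
    erosion_spacing_mm: float = 4.0,
    structuring_element: str = "cube",
    pooling: str = "pooled",
) -> tuple[float, float, float]:
    """(itErosion, medPCD mm, medEdgeD mm)."""
    return (
        iterative_erosion(lesions, erosion_spacing_mm, structuring_element),
        median_centroid_periphery_distance(lesions, pooling),
        median_edge_distance(lesions, pooling=pooling),
    )


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def extract_all(
    volume: SuvVolume, lesions: LesionSet, erosion_spacing_mm: float = 4.0
) -> FeatureVector:
    """All 12 parameters; unit identities TVSR = 10*TMTV/TMTS and
    TLG = TMTV*SUVmean hold by construction."""
    _require_lesions(lesions)
    suv_max, suv_mean, tlg_g = activity_features(volume, lesions)
    tmtv_ml, tmts_cm2, tvsr_mm = burden_features(lesions)
    dmax_mm, tumbb_ml, n_roi = dispersion_features(lesions)
    it_erosion, med_pcd_mm, med_edge_d_mm = massiveness_features(lesions, erosion_spacing_mm)
    return FeatureVector(
        suv_max=suv_max,
        suv_mean=suv_mean,
        tmtv_ml=tmtv_ml,
        tlg_g=tlg_g,
        tmts_cm2=tmts_cm2,
        tvsr_mm=tvsr_mm,
        dmax_mm=dmax_mm,
        tumbb_ml=tumbb_ml,
        n_roi=n_roi,
        it_erosion=it_erosion,
        med_edge_d_mm=med_edge_d_mm,
        med_pcd_mm=med_pcd_mm,
    )
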