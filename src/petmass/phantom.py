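"""Digital phantoms: PET-like SUV volumes with analytically known lesions.

A phantom is a low-SUV background grid with hypermetabolic lesions of simple
geometry (sphere, cuboid, ellipsoid, union of spheres).  Voxel membership is
voxel-center-inside-shape with no partial-volume modelling, so analytic
volumes and brute-force oracles agree exactly with the digitized shape.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .segmentation import LesionSet, lesion_set_from_labels
from .volume import SuvVolume

Shape = Literal["sphere", "cuboid", "ellipsoid", "union-of-spheres"]
SuvProfile = Literal["uniform", "radial-linear"]


@dataclass(frozen=True)
class LesionSpec:
    """Geometry and uptake of one synthetic lesion.

    ``radius_mm`` is a scalar for spheres, a (3,) triple for ellipsoids
    (semi-axes) and cuboids (half edge lengths), or a list of scalars for a
    union of spheres (paired with ``centers_mm``).  ``suv_profile`` is either
    uniform at ``suv_peak`` or a linear radial fall-off from ``suv_peak`` at
    the center to ``suv_peak / 2`` at the surface.
    """

    shape: Shape
    center_mm: tuple[float, float, float]
    radius_mm: float | tuple[float, float, float] | Sequence[float]
    suv_peak: float
    suv_profile: SuvProfile = "uniform"
    centers_mm: Sequence[tuple[float, float, float]] | None = None  # union-of-spheres only

    def __post_init__(self) -> None:
        if self.suv_peak <= 0:
            raise ValueError(f"suv_peak must be > 0, got {self.suv_peak}")
        radii = np.atleast_1d(np.asarray(self.radius_mm, dtype=float))
        if np.any(radii <= 0):
            raise ValueError(f"size parameters must be > 0, got {self.radius_mm}")
        if self.shape == "union-of-spheres" and self.centers_mm is None:
            raise ValueError("union-of-spheres requires centers_mm")

    # --- analytic geometry -------------------------------------------------
    def bounding_box_mm(self) -> tuple[np.ndarray, np.ndarray]:
        if self.shape == "union-of-spheres":
            centers = np.asarray(self.centers_mm, dtype=float)
            radii = np.broadcast_to(
                np.atleast_1d(np.asarray(self.radius_mm, dtype=float)), (len(centers),)
            )
            return (centers - radii[:, None]).min(axis=0), (centers + radii[:, None]).max(axis=0)
        center = np.asarray(self.center_mm, dtype=float)
        if self.shape == "sphere":
            half = np.full(3, float(np.asarray(self.radius_mm)))
        else:  # cuboid half-edges or ellipsoid semi-axes
            half = np.asarray(self.radius_mm, dtype=float)
            if half.shape != (3,):
                raise ValueError(f"{self.shape} needs 3 size parameters, got {self.radius_mm}")
        return center - half, center + half

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        """Boolean membership of an (n, 3) array of physical points."""
        pts = np.atleast_2d(points_mm)
        center = np.asarray(self.center_mm, dtype=float)
        if self.shape == "sphere":
            r = float(np.asarray(self.radius_mm))
            return np.linalg.norm(pts - center, axis=1) <= r
        if self.shape == "cuboid":
            half = np.asarray(self.radius_mm, dtype=float)
            return np.all(np.abs(pts - center) <= half, axis=1)
        if self.shape == "ellipsoid":
            semi = np.asarray(self.radius_mm, dtype=float)
            return np.sum(((pts - center) / semi) ** 2, axis=1) <= 1.0
        # union-of-spheres
        centers = np.asarray(self.centers_mm, dtype=float)
        radii = np.broadcast_to(
            np.atleast_1d(np.asarray(self.radius_mm, dtype=float)), (len(centers),)
        )
        inside = np.zeros(len(pts), dtype=bool)
        for c, r in zip(centers, radii):
            inside |= np.linalg.norm(pts - c, axis=1) <= r
        return inside

    def normalized_radius(self, points_mm: np.ndarray) -> np.ndarray:
        """Relative distance from center to surface in [0, 1] (radial profile)."""
        pts = np.atleast_2d(points_mm)
        center = np.asarray(self.center_mm, dtype=float)
        if self.shape == "sphere":
            return np.linalg.norm(pts - center, axis=1) / float(np.asarray(self.radius_mm))
        if self.shape == "ellipsoid":
            semi = np.asarray(self.radius_mm, dtype=float)
            return np.sqrt(np.sum(((pts - center) / semi) ** 2, axis=1))
        if self.shape == "cuboid":
            half = np.asarray(self.radius_mm, dtype=float)
            return np.max(np.abs(pts - center) / half, axis=1)
        # union-of-spheres: relative to the nearest sphere
        centers = np.asarray(self.centers_mm, dtype=float)
        radii = np.broadcast_to(
            np.atleast_1d(np.asarray(self.radius_mm, dtype=float)), (len(centers),)
        )
        rel = np.stack(
            [np.linalg.norm(pts - c, axis=1) / r for c, r in zip(centers, radii)], axis=1
        )
        return rel.min(axis=1)

    def analytic_volume_mm3(self) -> float | None:
        """Closed-form volume where the shape permits (None for unions that
        may overlap)."""
        if self.shape == "sphere":
            r = float(np.asarray(self.radius_mm))
            return 4.0 / 3.0 * math.pi * r**3
        if self.shape == "cuboid":
            half = np.asarray(self.radius_mm, dtype=float)
            return float(np.prod(2 * half))
        if self.shape == "ellipsoid":
            semi = np.asarray(self.radius_mm, dtype=float)
            return 4.0 / 3.0 * math.pi * float(np.prod(semi))
        return None

    def analytic_surface_mm2(self) -> float | None:
        if self.shape == "sphere":
            r = float(np.asarray(self.radius_mm))
            return 4.0 * math.pi * r**2
        if self.shape == "cuboid":
            e = 2 * np.asarray(self.radius_mm, dtype=float)
            return float(2 * (e[0] * e[1] + e[0] * e[2] + e[1] * e[2]))
        return None


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic SUV volume."""

    grid_shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    background_suv: float
    lesions: tuple[LesionSpec, ...] | list[LesionSpec]
    noise_sd: float = 0.0
    seed: int = 0
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(int(n) < 1 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be >= 1 per axis, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be > 0, got {self.spacing_mm}")
        if self.background_suv < 0:
            raise ValueError("background_suv must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class PhantomGroundTruth:
    """What the generator knows exactly about each lesion."""

    lesion_set: LesionSet
    #: label map in the order lesions were listed in the spec (labels 1..n),
    #: before the canonical volume-sorted relabelling of ``lesion_set``
    label_map_spec_order: np.ndarray
    analytic_volumes_mm3: tuple[float | None, ...]
    analytic_surfaces_mm2: tuple[float | None, ...]


def make_phantom(spec: PhantomSpec) -> tuple[SuvVolume, PhantomGroundTruth]:
    """Render a phantom and its exact ground truth.

    A voxel takes a lesion's SUV iff its center lies inside the lesion shape
    (first listed lesion wins on overlap), else the background SUV.  Gaussian
    noise (sd ``noise_sd``) is added afterwards and clipped at 0.  The ground
    truth records every lesion's true voxel set plus closed-form volume and
    surface where the shape permits.
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    origin = np.asarray(spec.origin_mm, dtype=float)
    grid_lo = origin - spacing / 2
    grid_hi = origin + (np.asarray(shape) - 1) * spacing + spacing / 2

    for i, les in enumerate(spec.lesions):
        lo, hi = les.bounding_box_mm()
        if np.any(lo < grid_lo) or np.any(hi > grid_hi):
            raise ValueError(
                f"lesion {i} ({les.shape} at {les.center_mm}) extends outside the grid"
            )

    values = np.full(shape, float(spec.background_suv))
    label_map = np.zeros(shape, dtype=np.int32)

    for lab, les in enumerate(spec.lesions, start=1):
        lo, hi = les.bounding_box_mm()
        lo_idx = np.maximum(np.floor((lo - origin) / spacing).astype(int) - 1, 0)
        hi_idx = np.minimum(np.ceil((hi - origin) / spacing).astype(int) + 1, np.asarray(shape) - 1)
        sub = np.meshgrid(
            *[np.arange(lo_idx[a], hi_idx[a] + 1) for a in range(3)], indexing="ij"
        )
        idx = np.stack([s.ravel() for s in sub], axis=1)
        pts = origin + idx * spacing
        inside = les.contains(pts)
        idx = idx[inside]
        unclaimed = label_map[tuple(idx.T)] == 0  # first lesion wins on overlap
        idx = idx[unclaimed]
        if len(idx) == 0:
            continue
        label_map[tuple(idx.T)] = lab
        if les.suv_profile == "uniform":
            values[tuple(idx.T)] = les.suv_peak
        else:  # radial-linear: peak at center, peak/2 at the surface
            rel = les.normalized_radius(origin + idx * spacing)
            values[tuple(idx.T)] = les.suv_peak * (1.0 - 0.5 * np.clip(rel, 0.0, 1.0))

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = np.clip(values + rng.normal(0.0, spec.noise_sd, size=shape), 0.0, None)

    volume = SuvVolume(values=values, spacing_mm=tuple(spacing), origin_mm=tuple(origin))
    truth = PhantomGroundTruth(
        lesion_set=lesion_set_from_labels(label_map, tuple(spacing), tuple(origin)),
        label_map_spec_order=label_map,
        analytic_volumes_mm3=tuple(l.analytic_volume_mm3() for l in spec.lesions),
        analytic_surfaces_mm2=tuple(l.analytic_surface_mm2() for l in spec.lesions),
    )
    return volume, truth
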