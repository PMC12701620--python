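"""Container for a 3D standardized-uptake-value (SUV) image."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SuvVolume:
    """A 3D scalar grid of SUV values on a regular (possibly anisotropic) grid.

    Coordinates are 0-based voxel indices; the center of voxel ``(i, j, k)``
    sits at ``origin_mm + (i, j, k) * spacing_mm``.  All physical distances in
    this package are between voxel centers, in millimetres.

    Parameters
    ----------
    values
        3D float array of SUV values (dimensionless, >= 0).
    spacing_mm
        Voxel spacing per axis in mm, all > 0.
    origin_mm
        Physical position of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"SUV volume must be 3D, got {values.ndim}D")
        if not np.all(np.isfinite(values)):
            raise ValueError("SUV volume contains non-finite values")
        if np.any(values < 0):
            raise ValueError("SUV values must be >= 0")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing_mm must be 3 positive reals, got {self.spacing_mm}")
        origin = tuple(float(o) for o in self.origin_mm)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    def voxel_centers_mm(self, indices: np.ndarray) -> np.ndarray:
        """Physical centers (mm) of an (n, 3) array of voxel indices."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)
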