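"""NIfTI and CSV input/output.

Volumes and label maps travel as NIfTI-1 with voxel spacing in the header;
cohorts and feature tables as comma-separated UTF-8 CSV with "." decimals
and units encoded in the column names (``tmtv_ml``, ``med_edge_d_mm``, ...),
so files round-trip through pandas without a custom parser.
"""
from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .segmentation import LesionSet, lesion_set_from_labels
from .volume import SuvVolume


class FormatError(ValueError):
    """Input file does not satisfy the expected format."""


def _load_3d(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float], tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"{path}: missing or invalid voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return data, tuple(float(z) for z in zooms), origin


def _affine(spacing_mm, origin_mm) -> np.ndarray:
    aff = np.diag([*spacing_mm, 1.0])
    aff[:3, 3] = origin_mm
    return aff


def read_volume(path: str | Path) -> SuvVolume:
    """Read a 3D SUV volume; spacing comes from the NIfTI header (mm)."""
    data, spacing, origin = _load_3d(path)
    return SuvVolume(values=data.astype(float), spacing_mm=spacing, origin_mm=origin)


def write_volume(volume: SuvVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float64), _affine(volume.spacing_mm, volume.origin_mm))
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def read_labels(path: str | Path) -> LesionSet:
    """Read an integer label map and rebuild the lesion set (lossless for
    integer labels)."""
    data, spacing, origin = _load_3d(path)
    labels = np.rint(data).astype(np.int32)
    return lesion_set_from_labels(labels, spacing, origin)


def write_labels(lesions: LesionSet, path: str | Path) -> None:
    img = nib.Nifti1Image(
        lesions.label_map.astype(np.int32), _affine(lesions.spacing_mm, lesions.origin_mm)
    )
    img.header.set_zooms(lesions.spacing_mm)
    nib.save(img, str(path))


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Byte-stable CSV: fixed float formatting, LF endings, UTF-8."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format="%.10g", lineterminator="\n")


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    write_table(cohort, path)
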