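"""On-disk conventions: NIfTI-1 volumes, b-value sidecars and CSV cohort tables.

A diffusion series is stored as a 4-D NIfTI-1 file plus an FSL-style b-value
sidecar (one whitespace-separated row; comma-separated also accepted). Masks
and parameter maps are 3-D NIfTI-1 volumes on the same grid. Cohort tables
are CSV with a header row. Every reader/writer pair round-trips exactly.

Readers sort the b grid ascending and reorder the 4th signal axis to match,
so the in-memory :class:`~dkimri.data.DWISeries` is invariant to the on-disk
volume order. NaN is the sentinel for "no estimate" in parameter maps.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .data import RESPONSE_CLASSES, BValueScheme, CohortTable, DWISeries, ROIMask

__all__ = [
    "read_bvals",
    "write_bvals",
    "read_dwi_series",
    "write_dwi_series",
    "read_roi_mask",
    "write_roi_mask",
    "write_parameter_maps",
    "read_parameter_maps",
    "read_cohort_table",
    "write_cohort_table",
    "MAP_NAMES",
]

logger = logging.getLogger(__name__)

#: Per-metric file stems used by the parameter-map writer/reader.
MAP_NAMES = ("adc", "d_app", "k_app", "s0", "qc")


def read_bvals(path) -> list[float]:
    """Read a b-value sidecar: whitespace- or comma-separated numbers."""
    text = Path(path).read_text()
    tokens = [t for t in re.split(r"[,\s]+", text.strip()) if t]
    if not tokens:
        raise ValueError(f"no b-values found in {path}")
    return [float(t) for t in tokens]


def write_bvals(values, path) -> Path:
    path = Path(path)
    path.write_text(" ".join(format(float(v), "g") for v in values) + "\n")
    return path


def _affine(voxel_size) -> np.ndarray:
    aff = np.diag([*voxel_size, 1.0])
    return aff


def _save_nifti(array, voxel_size, path) -> Path:
    img = nib.Nifti1Image(np.asarray(array), _affine(voxel_size))
    img.header.set_xyzt_units(xyz="mm")
    nib.save(img, str(path))
    return Path(path)


def read_dwi_series(image_path, bval_path) -> DWISeries:
    """Load a 4-D NIfTI series with its b-value sidecar.

    The returned series has its scheme sorted ascending and the signal's
    4th axis reordered to match; voxel size is taken from the image header.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{image_path}: expected a 4-D volume, got ndim={data.ndim}")
    bvals = read_bvals(bval_path)
    if len(bvals) != data.shape[3]:
        raise ValueError(
            f"{bval_path}: {len(bvals)} b-values but {data.shape[3]} volumes in {image_path}"
        )
    if any(b < 0 for b in bvals):
        raise ValueError(f"{bval_path}: negative b-value in {bvals}")
    order = np.argsort(bvals, kind="stable")
    scheme = BValueScheme([bvals[i] for i in order])
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DWISeries(signal=data[..., order], scheme=scheme, voxel_size=voxel_size)


def write_dwi_series(series: DWISeries, image_path, bval_path) -> tuple[Path, Path]:
    img_path = _save_nifti(series.signal, series.voxel_size, image_path)
    bv_path = write_bvals(series.scheme.values, bval_path)
    return img_path, bv_path


def read_roi_mask(path, series: DWISeries | None = None) -> ROIMask:
    """Load a 3-D integer label mask, optionally validated against a series grid."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D mask, got ndim={data.ndim}")
    mask = ROIMask(labels=data)
    if series is not None:
        mask.validate_grid(series)
    return mask


def write_roi_mask(mask: ROIMask, path, voxel_size=(1.0, 1.0, 1.0)) -> Path:
    return _save_nifti(mask.labels.astype(np.int16), voxel_size, path)


def write_parameter_maps(maps, out_dir, voxel_size=(1.0, 1.0, 1.0)) -> dict[str, Path]:
    """Write one NIfTI volume per metric (adc, d_app, k_app, s0, qc) into ``out_dir``.

    Values are stored unscaled (diffusivities in mm²/s) as float64 so that
    a read after write reproduces the arrays bit-exactly; the qc map is
    stored as int16. Returns the mapping metric name -> file path.
    """
    out_dir = Path(out_dir)
    if not out_dir.exists():
        out_dir.mkdir(parents=True)
    paths: dict[str, Path] = {}
    for name in MAP_NAMES:
        arr = getattr(maps, name)
        if name == "qc":
            arr = np.asarray(arr, dtype=np.int16)
        else:
            arr = np.asarray(arr, dtype=np.float64)
        paths[name] = _save_nifti(arr, voxel_size, out_dir / f"{name}.nii")
    return paths


def read_parameter_maps(maps_dir):
    """Read parameter maps written by :func:`write_parameter_maps`."""
    from .models import ParameterMaps

    maps_dir = Path(maps_dir)
    arrays = {}
    for name in MAP_NAMES:
        path = maps_dir / f"{name}.nii"
        if not path.exists():
            raise FileNotFoundError(f"missing parameter map {path}")
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj)
        arrays[name] = arr.astype(np.int16) if name == "qc" else np.asarray(arr, dtype=np.float64)
    return ParameterMaps(**arrays)


def read_cohort_table(path) -> CohortTable:
    """Read a cohort CSV; unknown columns are preserved."""
    df = pd.read_csv(path)
    return CohortTable(df)


def write_cohort_table(table: CohortTable, path) -> Path:
    path = Path(path)
    table.to_frame().to_csv(path, index=False)
    return path
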