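"""Per-patient volume-of-interest (VOI) summaries.

All of a patient's tumour ROIs are pooled into a single VOI (the union of
the positive mask labels) and each parameter map is reduced over the VOI's
successfully fitted voxels to one number per patient — the value the group
statistics consume. The reduction is a voxel-weighted mean by default
(median available as a policy); voxels with a nonzero fit-status code are
excluded and counted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .data import RESPONSE_CLASSES, ROIMask
from .models import QC_OK, ParameterMaps

__all__ = ["PatientRecord", "VOISummary", "combine_rois_to_voi", "summarize_voi", "build_patient_record"]

logger = logging.getLogger(__name__)

SUMMARY_POLICIES = ("mean", "median")


@dataclass
class PatientRecord:
    """One patient's VOI metrics, response class and optional histology."""

    patient_id: str
    response_class: str
    voi_voxel_count: int
    adc_voi: float
    d_app_voi: float
    k_app_voi: float
    cellularity_cells_per_um2: float | None = None
    ki67_percent: float | None = None

    def __post_init__(self) -> None:
        if self.response_class not in RESPONSE_CLASSES:
            raise ValueError(
                f"response_class must be one of {RESPONSE_CLASSES}, got {self.response_class!r}"
            )
        if self.voi_voxel_count < 0:
            raise ValueError("voi_voxel_count must be >= 0")
        metrics = (self.adc_voi, self.d_app_voi, self.k_app_voi)
        if self.voi_voxel_count == 0 and not all(math.isnan(m) for m in metrics):
            raise ValueError("summary metrics must be NaN when the VOI is empty")
        if self.ki67_percent is not None and not 0.0 <= self.ki67_percent <= 100.0:
            raise ValueError(f"ki67_percent must be in [0, 100], got {self.ki67_percent}")

    def to_dict(self) -> dict:
        d = {
            "patient_id": self.patient_id,
            "response_class": self.response_class,
            "voi_voxel_count": self.voi_voxel_count,
            "adc_voi": self.adc_voi,
            "d_app_voi": self.d_app_voi,
            "k_app_voi": self.k_app_voi,
        }
        if self.cellularity_cells_per_um2 is not None:
            d["cellularity_cells_per_um2"] = self.cellularity_cells_per_um2
        if self.ki67_percent is not None:
            d["ki67_percent"] = self.ki67_percent
        return d


class VOISummary(NamedTuple):
    adc_voi: float
    d_app_voi: float
    k_app_voi: float
    n_used: int
    n_excluded: int


def combine_rois_to_voi(mask: ROIMask) -> np.ndarray:
    """Union of all positive lesion labels as a boolean VOI mask (idempotent)."""
    return np.asarray(mask.labels) > 0


def summarize_voi(maps: ParameterMaps, voi: np.ndarray, policy: str = "mean") -> VOISummary:
    """Reduce each metric over the VOI's qc-clean voxels with mean or median."""
    if policy not in SUMMARY_POLICIES:
        raise ValueError(f"policy must be one of {SUMMARY_POLICIES}, got {policy!r}")
    voi = np.asarray(voi, dtype=bool)
    if voi.shape != maps.grid_shape:
        raise ValueError(f"VOI grid {voi.shape} does not match maps grid {maps.grid_shape}")
    usable = voi & (maps.qc == QC_OK)
    n_used = int(usable.sum())
    n_excluded = int(voi.sum()) - n_used
    if n_used == 0:
        return VOISummary(np.nan, np.nan, np.nan, 0, n_excluded)
    reduce = np.mean if policy == "mean" else np.median
    return VOISummary(
        adc_voi=float(reduce(maps.adc[usable])),
        d_app_voi=float(reduce(maps.d_app[usable])),
        k_app_voi=float(reduce(maps.k_app[usable])),
        n_used=n_used,
        n_excluded=n_excluded,
    )


def build_patient_record(
    patient_id: str,
    maps: ParameterMaps,
    mask: ROIMask,
    response_class: str = "unclassified",
    histology: dict | None = None,
    policy: str = "mean",
) -> PatientRecord:
    """Assemble a patient record from fitted maps, a lesion mask and metadata."""
    voi = combine_rois_to_voi(mask)
    summary = summarize_voi(maps, voi, policy=policy)
    if summary.n_used == 0:
        logger.warning("patient %s: no evaluable VOI voxels", patient_id)
    histology = histology or {}
    return PatientRecord(
        patient_id=str(patient_id),
        response_class=response_class,
        voi_voxel_count=summary.n_used,
        adc_voi=summary.adc_voi,
        d_app_voi=summary.d_app_voi,
        k_app_voi=summary.k_app_voi,
        cellularity_cells_per_um2=histology.get("cellularity_cells_per_um2"),
        ki67_percent=histology.get("ki67_percent"),
    )
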