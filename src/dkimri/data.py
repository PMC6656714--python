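"""In-memory containers for multi-b-value diffusion MRI data.

The acquisition model is a 4-D signal array — one 3-D magnitude volume per
diffusion weighting (b-value, s/mm²) — together with the ordered b grid
(:class:`BValueScheme`), integer lesion masks on the same voxel grid
(:class:`ROIMask`) and a per-patient cohort table (:class:`CohortTable`).

Units are fixed package-wide: b in s/mm², diffusivities in mm²/s, so the
product b·D is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BValueScheme",
    "DWISeries",
    "ROIMask",
    "CohortTable",
    "RESPONSE_CLASSES",
]

#: Allowed values of the per-patient treatment-response label.
RESPONSE_CLASSES = ("responder", "non-responder", "unclassified")


@dataclass(frozen=True)
class BValueScheme:
    """An ordered set of diffusion weightings (b-values, s/mm²).

    At least three distinct weightings are required: the kurtosis signal
    model has three unknowns (S0, D_app, K_app) per voxel.
    """

    values: tuple[float, ...]

    def __init__(self, values) -> None:
        vals = tuple(float(v) for v in np.asarray(values).ravel())
        if len(vals) < 3:
            raise ValueError(f"need at least 3 b-values, got {len(vals)}")
        if any(v < 0 for v in vals):
            raise ValueError(f"b-values must be non-negative, got {vals}")
        if any(b >= a for b, a in zip(vals, vals[1:])):
            raise ValueError(f"b-values must be strictly increasing, got {vals}")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @property
    def b_max(self) -> float:
        return self.values[-1]

    def indices_of(self, subset) -> np.ndarray:
        """Positions of ``subset`` b-values within the scheme.

        Raises ``ValueError`` if any requested b-value is absent.
        """
        idx = []
        for b in subset:
            matches = [i for i, v in enumerate(self.values) if np.isclose(v, float(b))]
            if not matches:
                raise ValueError(f"b={b} s/mm² is not in the scheme {self.values}")
            idx.append(matches[0])
        return np.asarray(idx, dtype=int)


@dataclass
class DWISeries:
    """A 4-D diffusion-weighted series: ``signal[x, y, z, i]`` at ``scheme.values[i]``."""

    signal: np.ndarray
    scheme: BValueScheme
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError(f"signal must be 4-D (x, y, z, b), got ndim={self.signal.ndim}")
        if self.signal.shape[3] != len(self.scheme):
            raise ValueError(
                f"signal has {self.signal.shape[3]} volumes but scheme has "
                f"{len(self.scheme)} b-values"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if np.any(self.signal < 0):
            raise ValueError("magnitude signal must be non-negative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3:
            raise ValueError("voxel_size must have 3 components (mm)")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class ROIMask:
    """Integer lesion labels on a 3-D grid: 0 = background, k > 0 = lesion k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"mask must be 3-D, got ndim={labels.ndim}")
        if not np.issubdtype(labels.dtype, np.integer):
            rounded = np.round(labels)
            if not np.allclose(labels, rounded, atol=1e-8, equal_nan=False):
                raise ValueError("mask labels must be integers")
            labels = rounded.astype(np.int32)
        if labels.min() < 0:
            raise ValueError("mask labels must be non-negative")
        self.labels = labels

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def lesion_ids(self) -> tuple[int, ...]:
        ids = np.unique(self.labels)
        return tuple(int(k) for k in ids if k > 0)

    @property
    def n_lesions(self) -> int:
        return len(self.lesion_ids)

    def validate_grid(self, series: DWISeries) -> None:
        if self.grid_shape != series.grid_shape:
            raise ValueError(
                f"mask grid {self.grid_shape} does not match series grid {series.grid_shape}"
            )


#: Columns every cohort table must carry.
COHORT_REQUIRED_COLUMNS = ("patient_id", "response_class")


@dataclass
class CohortTable:
    """Per-patient summary table: one row per patient.

    Required columns are ``patient_id`` (unique) and ``response_class``
    (one of :data:`RESPONSE_CLASSES`). Metric columns (``adc_voi``,
    ``d_app_voi``, ``k_app_voi``), histology covariates
    (``cellularity_cells_per_um2``, ``ki67_percent``) and any extra columns
    are carried through unchanged.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.frame).reset_index(drop=True)
        for col in COHORT_REQUIRED_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"cohort table missing required column {col!r}")
        ids = df["patient_id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate patient ids: {dupes}")
        bad = set(df["response_class"].astype(str)) - set(RESPONSE_CLASSES)
        if bad:
            raise ValueError(
                f"unknown response class(es) {sorted(bad)}; expected one of {RESPONSE_CLASSES}"
            )
        self.frame = df

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_responders(self) -> int:
        return int((self.frame["response_class"] == "responder").sum())

    @property
    def n_non_responders(self) -> int:
        return int((self.frame["response_class"] == "non-responder").sum())

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    @classmethod
    def from_records(cls, records) -> "CohortTable":
        """Build from an iterable of ``PatientRecord`` objects or dicts."""
        rows = []
        for rec in records:
            rows.append(rec if isinstance(rec, dict) else rec.to_dict())
        return cls(pd.DataFrame(rows))
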