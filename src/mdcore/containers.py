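"""In-memory containers shared across the analysis stages.

All containers are thin, validated wrappers around numpy arrays with
explicit axis labels.  Axis conventions:

* ``BetaTable.beta``        — (subjects, areas, contrasts)
* ``SegmentBetaTable.beta`` — (subjects, segments, contrasts), segments
  ordered posterior→anterior with a marked inter-areal border
* ``ParcelTimeSeries.data`` — (timepoints, parcels), one per subject
* ``FCMatrix.r``            — (parcels, parcels), one per subject
* ``VoxelTable``            — subcortical voxels with structure labels,
  per-subject task betas and one rest session of time series
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BetaTable",
    "SegmentBetaTable",
    "ParcelTimeSeries",
    "FCMatrix",
    "VoxelTable",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a container or file fails schema validation."""


def _as_tuple(x) -> tuple:
    return tuple(str(v) for v in x)


@dataclass
class BetaTable:
    """Task-contrast effect sizes (betas/copes), subjects x areas x contrasts.

    ``hemispheres`` is None for hemisphere-averaged tables, otherwise one
    'L'/'R' label per area; area names may then repeat across hemispheres
    but must be unique within a hemisphere.
    """

    beta: np.ndarray
    subject_ids: tuple
    area_ids: tuple
    contrast_ids: tuple
    hemispheres: tuple | None = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.subject_ids = _as_tuple(self.subject_ids)
        self.area_ids = _as_tuple(self.area_ids)
        self.contrast_ids = _as_tuple(self.contrast_ids)
        if self.hemispheres is not None:
            self.hemispheres = _as_tuple(self.hemispheres)
        if self.beta.ndim != 3:
            raise ValidationError(
                f"beta must be 3-D (subjects, areas, contrasts); got {self.beta.ndim}-D"
            )
        s, a, c = self.beta.shape
        if (s, a, c) != (len(self.subject_ids), len(self.area_ids), len(self.contrast_ids)):
            raise ValidationError(
                f"beta shape {self.beta.shape} does not match id lengths "
                f"({len(self.subject_ids)}, {len(self.area_ids)}, {len(self.contrast_ids)})"
            )
        if s < 2:
            raise ValidationError("BetaTable requires >= 2 subjects")
        if not np.all(np.isfinite(self.beta)):
            raise ValidationError("beta contains non-finite values")
        if self.hemispheres is not None:
            if len(self.hemispheres) != a:
                raise ValidationError("hemispheres length must match number of areas")
            seen = set()
            for name, hemi in zip(self.area_ids, self.hemispheres):
                if hemi not in ("L", "R"):
                    raise ValidationError(f"unknown hemisphere label {hemi!r}")
                key = (hemi, name)
                if key in seen:
                    raise ValidationError(f"duplicate area {name!r} in hemisphere {hemi}")
                seen.add(key)
        else:
            if len(set(self.area_ids)) != a:
                raise ValidationError("area ids must be unique")

    @property
    def n_subjects(self) -> int:
        return self.beta.shape[0]

    @property
    def n_areas(self) -> int:
        return self.beta.shape[1]

    def area_index(self, area_id: str, hemisphere: str | None = None) -> int:
        for i, name in enumerate(self.area_ids):
            if name == area_id and (
                hemisphere is None
                or self.hemispheres is None
                or self.hemispheres[i] == hemisphere
            ):
                return i
        raise KeyError(f"area {area_id!r} not found")


@dataclass
class SegmentBetaTable:
    """Betas for ordered segments spanning an areal border.

    Segments run posterior→anterior; ``border_index`` marks the first
    segment of the anterior area (so the border lies between segments
    ``border_index - 1`` and ``border_index``).
    """

    beta: np.ndarray
    subject_ids: tuple
    segment_areas: tuple  # area label per segment, e.g. 10x 'SCEF' then 10x '8BM'
    segment_numbers: tuple  # 1-based index within each area
    contrast_ids: tuple
    border_index: int = 10

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.subject_ids = _as_tuple(self.subject_ids)
        self.segment_areas = _as_tuple(self.segment_areas)
        self.segment_numbers = tuple(int(v) for v in self.segment_numbers)
        self.contrast_ids = _as_tuple(self.contrast_ids)
        if self.beta.ndim != 3:
            raise ValidationError("segment beta must be 3-D (subjects, segments, contrasts)")
        n_seg = self.beta.shape[1]
        if len(self.segment_areas) != n_seg or len(self.segment_numbers) != n_seg:
            raise ValidationError("segment labels must match the segment axis")
        if not 0 < self.border_index < n_seg:
            raise ValidationError("border index must fall strictly inside the segment axis")
        areas = list(dict.fromkeys(self.segment_areas))
        if len(areas) != 2:
            raise ValidationError("segment table must span exactly two areas")
        if self.segment_areas[self.border_index - 1] == self.segment_areas[self.border_index]:
            raise ValidationError("border index must separate the two areas")

    @property
    def n_segments(self) -> int:
        return self.beta.shape[1]

    @property
    def segment_labels(self) -> tuple:
        return tuple(
            f"{a}_{i}" for a, i in zip(self.segment_areas, self.segment_numbers)
        )

    def reversed(self) -> "SegmentBetaTable":
        """Anterior→posterior view (used for order-equivariance checks)."""
        n = self.n_segments
        return SegmentBetaTable(
            beta=self.beta[:, ::-1, :].copy(),
            subject_ids=self.subject_ids,
            segment_areas=self.segment_areas[::-1],
            segment_numbers=self.segment_numbers[::-1],
            contrast_ids=self.contrast_ids,
            border_index=n - self.border_index,
        )


@dataclass
class ParcelTimeSeries:
    """One subject's parcel-averaged rest time series (timepoints x parcels)."""

    data: np.ndarray
    parcel_ids: tuple
    hemispheres: tuple

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.parcel_ids = _as_tuple(self.parcel_ids)
        self.hemispheres = _as_tuple(self.hemispheres)
        if self.data.ndim != 2:
            raise ValidationError("time series must be 2-D (timepoints, parcels)")
        if self.data.shape[1] != len(self.parcel_ids):
            raise ValidationError("parcel ids must match the parcel axis")
        if len(self.hemispheres) != len(self.parcel_ids):
            raise ValidationError("hemisphere labels must match the parcel axis")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]


@dataclass
class FCMatrix:
    """Per-subject parcellated functional-connectivity (Pearson r) matrix."""

    r: np.ndarray
    parcel_ids: tuple
    hemispheres: tuple

    SYMMETRY_TOL = 1e-10

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.parcel_ids = _as_tuple(self.parcel_ids)
        self.hemispheres = _as_tuple(self.hemispheres)
        n = len(self.parcel_ids)
        if self.r.shape != (n, n):
            raise ValidationError(f"FC matrix shape {self.r.shape} does not match {n} parcels")
        if len(self.hemispheres) != n:
            raise ValidationError("hemisphere labels must match the parcel axis")
        if not np.allclose(self.r, self.r.T, atol=self.SYMMETRY_TOL, rtol=0):
            raise ValidationError("FC matrix is not symmetric within tolerance")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-12, rtol=0):
            raise ValidationError("FC matrix diagonal must be exactly 1")
        off = self.r[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < -1.0 - 1e-12 or off.max() > 1.0 + 1e-12):
            raise ValidationError("correlations must lie in [-1, 1]")

    @property
    def n_parcels(self) -> int:
        return self.r.shape[0]


@dataclass
class VoxelTable:
    """Subcortical/cerebellar voxels: structure labels, task betas, rest series.

    ``betas`` has shape (subjects, voxels, contrasts).  ``timeseries``
    (timepoints, voxels) is a single rest session generated jointly with
    ``cortex`` (the matching cortical parcel series), so voxel-to-parcel FC
    is well defined.  Either may be None when only one analysis is run.
    """

    voxel_ids: tuple
    structures: tuple
    betas: np.ndarray | None = None
    subject_ids: tuple | None = None
    contrast_ids: tuple | None = None
    timeseries: np.ndarray | None = None
    cortex: ParcelTimeSeries | None = None
    known_structures: tuple = field(default=None)

    def __post_init__(self):
        self.voxel_ids = _as_tuple(self.voxel_ids)
        self.structures = _as_tuple(self.structures)
        n = len(self.voxel_ids)
        if len(self.structures) != n:
            raise ValidationError("structure labels must match voxel ids")
        if self.known_structures is not None:
            self.known_structures = _as_tuple(self.known_structures)
            unknown = sorted(set(self.structures) - set(self.known_structures))
            if unknown:
                raise ValidationError(f"unknown structure labels: {unknown}")
        if self.betas is not None:
            self.betas = np.asarray(self.betas, dtype=float)
            if self.betas.ndim != 3 or self.betas.shape[1] != n:
                raise ValidationError("betas must be (subjects, voxels, contrasts)")
            self.subject_ids = _as_tuple(self.subject_ids)
            self.contrast_ids = _as_tuple(self.contrast_ids)
            if self.betas.shape[0] != len(self.subject_ids):
                raise ValidationError("subject ids must match beta subject axis")
            if self.betas.shape[2] != len(self.contrast_ids):
                raise ValidationError("contrast ids must match beta contrast axis")
        if self.timeseries is not None:
            self.timeseries = np.asarray(self.timeseries, dtype=float)
            if self.timeseries.ndim != 2 or self.timeseries.shape[1] != n:
                raise ValidationError("timeseries must be (timepoints, voxels)")

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_ids)

    def structure_counts(self) -> dict:
        counts: dict = {}
        for s in self.structures:
            counts[s] = counts.get(s, 0) + 1
        return counts
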