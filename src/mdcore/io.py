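"""File formats: TSV schemas for the tabular containers, JSON for sets,
partitions and reports, and an optional CIFTI adapter.

All TSVs are UTF-8 with dot decimal separators; floats are serialized with
17 significant digits so read(write(x)) round-trips bit-identically.
Schema violations raise :class:`~mdcore.containers.ValidationError` with
the offending line number where applicable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    BetaTable,
    FCMatrix,
    ParcelTimeSeries,
    SegmentBetaTable,
    ValidationError,
    VoxelTable,
)

__all__ = [
    "write_beta_table",
    "read_beta_table",
    "write_segment_table",
    "read_segment_table",
    "write_fc_matrix",
    "read_fc_matrix",
    "write_timeseries",
    "read_timeseries",
    "write_voxel_table",
    "read_voxel_table",
    "write_json",
    "read_json",
    "read_parcellated_cifti",
]

FLOAT_FMT = "%.17g"

_BETA_COLUMNS = ("subject", "hemisphere", "area", "contrast", "beta")
_SEGMENT_COLUMNS = ("subject", "area", "segment_index", "contrast", "beta")
_VOXEL_COLUMNS = ("subject", "voxel", "structure", "contrast", "beta")


def _read_tsv(path, required_columns) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"{path.name}: {exc}") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing column(s) {missing} in header")
    return df


def _parse_floats(df: pd.DataFrame, column: str, path) -> np.ndarray:
    raw = df[column].to_numpy()
    out = np.empty(len(raw))
    for i, v in enumerate(raw):
        try:
            out[i] = float(v)
        except ValueError:
            # +2: one for the header line, one for 1-based numbering
            raise ValidationError(
                f"{Path(path).name}: line {i + 2}: invalid float {v!r} in column {column!r}"
            ) from None
    return out


def write_beta_table(b: BetaTable, path) -> None:
    """Long-format TSV: subject, hemisphere, area, contrast, beta."""
    n_s, n_a, n_c = b.beta.shape
    hemi = b.hemispheres if b.hemispheres is not None else ("NA",) * n_a
    rows = {
        "subject": np.repeat(b.subject_ids, n_a * n_c),
        "hemisphere": np.tile(np.repeat(hemi, n_c), n_s),
        "area": np.tile(np.repeat(b.area_ids, n_c), n_s),
        "contrast": np.tile(b.contrast_ids, n_s * n_a),
        "beta": [FLOAT_FMT % v for v in b.beta.ravel()],
    }
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_beta_table(path) -> BetaTable:
    df = _read_tsv(path, _BETA_COLUMNS)
    beta = _parse_floats(df, "beta", path)
    subjects = tuple(dict.fromkeys(df["subject"]))
    contrasts = tuple(dict.fromkeys(df["contrast"]))
    pairs = tuple(dict.fromkeys(zip(df["hemisphere"], df["area"])))
    hemis = tuple(h for h, _ in pairs)
    areas = tuple(a for _, a in pairs)
    n_s, n_a, n_c = len(subjects), len(areas), len(contrasts)
    if len(df) != n_s * n_a * n_c:
        raise ValidationError(
            f"{Path(path).name}: {len(df)} rows, expected a complete "
            f"{n_s} x {n_a} x {n_c} table ({n_s * n_a * n_c})"
        )
    s_idx = {s: i for i, s in enumerate(subjects)}
    a_idx = {p: i for i, p in enumerate(pairs)}
    c_idx = {c: i for i, c in enumerate(contrasts)}
    arr = np.full((n_s, n_a, n_c), np.nan)
    si = df["subject"].map(s_idx).to_numpy()
    ai = np.array([a_idx[p] for p in zip(df["hemisphere"], df["area"])])
    ci = df["contrast"].map(c_idx).to_numpy()
    arr[si, ai, ci] = beta
    if np.isnan(arr).any():
        raise ValidationError(f"{Path(path).name}: duplicate or missing cells")
    hemispheres = None if set(hemis) == {"NA"} else hemis
    return BetaTable(
        beta=arr, subject_ids=subjects, area_ids=areas,
        contrast_ids=contrasts, hemispheres=hemispheres,
    )


def write_segment_table(t: SegmentBetaTable, path) -> None:
    """Long-format TSV: subject, area, segment_index, contrast, beta."""
    n_s, n_seg, n_c = t.beta.shape
    rows = {
        "subject": np.repeat(t.subject_ids, n_seg * n_c),
        "area": np.tile(np.repeat(t.segment_areas, n_c), n_s),
        "segment_index": np.tile(np.repeat(t.segment_numbers, n_c), n_s),
        "contrast": np.tile(t.contrast_ids, n_s * n_seg),
        "beta": [FLOAT_FMT % v for v in t.beta.ravel()],
    }
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_segment_table(t_path, border_index: int | None = None) -> SegmentBetaTable:
    df = _read_tsv(t_path, _SEGMENT_COLUMNS)
    beta = _parse_floats(df, "beta", t_path)
    subjects = tuple(dict.fromkeys(df["subject"]))
    contrasts = tuple(dict.fromkeys(df["contrast"]))
    segs = tuple(dict.fromkeys(zip(df["area"], df["segment_index"])))
    n_s, n_seg, n_c = len(subjects), len(segs), len(contrasts)
    if len(df) != n_s * n_seg * n_c:
        raise ValidationError(f"{Path(t_path).name}: incomplete segment table")
    s_idx = {s: i for i, s in enumerate(subjects)}
    g_idx = {g: i for i, g in enumerate(segs)}
    c_idx = {c: i for i, c in enumerate(contrasts)}
    arr = np.full((n_s, n_seg, n_c), np.nan)
    si = df["subject"].map(s_idx).to_numpy()
    gi = np.array([g_idx[g] for g in zip(df["area"], df["segment_index"])])
    ci = df["contrast"].map(c_idx).to_numpy()
    arr[si, gi, ci] = beta
    if np.isnan(arr).any():
        raise ValidationError(f"{Path(t_path).name}: duplicate or missing cells")
    areas = tuple(a for a, _ in segs)
    if border_index is None:
        first = areas[0]
        border_index = next(i for i, a in enumerate(areas) if a != first)
    return SegmentBetaTable(
        beta=arr,
        subject_ids=subjects,
        segment_areas=areas,
        segment_numbers=tuple(int(i) for _, i in segs),
        contrast_ids=contrasts,
        border_index=border_index,
    )


def write_fc_matrix(fc: FCMatrix, path) -> None:
    """Dense TSV with a header row and an index column of parcel ids.

    Parcel ids carry the hemisphere as an 'L_'/'R_' prefix.
    """
    df = pd.DataFrame(fc.r, index=fc.parcel_ids, columns=fc.parcel_ids)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="parcel")


def read_fc_matrix(path) -> FCMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{Path(path).name}: row and column parcel ids differ")
    parcel_ids = tuple(df.columns)
    hemis = []
    for p in parcel_ids:
        if p.startswith("L_"):
            hemis.append("L")
        elif p.startswith("R_"):
            hemis.append("R")
        else:
            raise ValidationError(
                f"{Path(path).name}: parcel id {p!r} lacks an L_/R_ hemisphere prefix"
            )
    return FCMatrix(r=df.to_numpy(dtype=float), parcel_ids=parcel_ids, hemispheres=tuple(hemis))


def write_timeseries(ts: ParcelTimeSeries, path) -> None:
    """TSV matrix, timepoints x parcels, parcel ids in the header."""
    pd.DataFrame(ts.data, columns=ts.parcel_ids).to_csv(
        path, sep="\t", float_format=FLOAT_FMT, index=False
    )


def read_timeseries(path) -> ParcelTimeSeries:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    parcel_ids = tuple(df.columns)
    hemis = tuple("L" if p.startswith("L_") else "R" for p in parcel_ids)
    return ParcelTimeSeries(
        data=df.to_numpy(dtype=float), parcel_ids=parcel_ids, hemispheres=hemis
    )


def write_voxel_table(v: VoxelTable, path, timeseries_path=None) -> None:
    """Long-format TSV of voxel betas; time series go to a separate matrix TSV."""
    if v.betas is None:
        raise ValidationError("voxel table has no betas to write")
    n_s, n_v, n_c = v.betas.shape
    rows = {
        "subject": np.repeat(v.subject_ids, n_v * n_c),
        "voxel": np.tile(np.repeat(v.voxel_ids, n_c), n_s),
        "structure": np.tile(np.repeat(v.structures, n_c), n_s),
        "contrast": np.tile(v.contrast_ids, n_s * n_v),
        "beta": [FLOAT_FMT % x for x in v.betas.ravel()],
    }
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if timeseries_path is not None and v.timeseries is not None:
        pd.DataFrame(v.timeseries, columns=v.voxel_ids).to_csv(
            timeseries_path, sep="\t", float_format=FLOAT_FMT, index=False
        )


def read_voxel_table(path, known_structures=None) -> VoxelTable:
    df = _read_tsv(path, _VOXEL_COLUMNS)
    beta = _parse_floats(df, "beta", path)
    subjects = tuple(dict.fromkeys(df["subject"]))
    contrasts = tuple(dict.fromkeys(df["contrast"]))
    pairs = tuple(dict.fromkeys(zip(df["voxel"], df["structure"])))
    voxels = tuple(p[0] for p in pairs)
    structures = tuple(p[1] for p in pairs)
    n_s, n_v, n_c = len(subjects), len(voxels), len(contrasts)
    if len(df) != n_s * n_v * n_c:
        raise ValidationError(f"{Path(path).name}: incomplete voxel table")
    s_idx = {s: i for i, s in enumerate(subjects)}
    v_idx = {p: i for i, p in enumerate(pairs)}
    c_idx = {c: i for i, c in enumerate(contrasts)}
    arr = np.full((n_s, n_v, n_c), np.nan)
    arr[
        df["subject"].map(s_idx).to_numpy(),
        np.array([v_idx[p] for p in zip(df["voxel"], df["structure"])]),
        df["contrast"].map(c_idx).to_numpy(),
    ] = beta
    if np.isnan(arr).any():
        raise ValidationError(f"{Path(path).name}: duplicate or missing cells")
    return VoxelTable(
        voxel_ids=voxels,
        structures=structures,
        betas=arr,
        subject_ids=subjects,
        contrast_ids=contrasts,
        known_structures=known_structures,
    )


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (frozenset, set)):
            return sorted(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, cls=_JSONEncoder, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def read_json(path):
    return json.loads(Path(path).read_text(encoding="utf-8"))


def read_parcellated_cifti(path):
    """Adapter for parcellated CIFTI files (.ptseries.nii / .pscalar.nii).

    Returns (data, parcel_names): data is (rows, parcels).  Requires
    nibabel; the core pipeline never needs this — it exists so real
    parcellated exports can be converted to the TSV schemas.
    """
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading CIFTI files requires nibabel") from exc
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    parcel_axis = None
    for i in range(data.ndim):
        ax = img.header.get_axis(i)
        if isinstance(ax, nib.cifti2.cifti2_axes.ParcelsAxis):
            parcel_axis = (i, ax)
    if parcel_axis is None:
        raise ValidationError(f"{Path(path).name}: no parcel axis found")
    i, ax = parcel_axis
    if i == 0:
        data = data.T
    return data, tuple(ax.name)
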