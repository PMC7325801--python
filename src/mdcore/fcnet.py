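"""Parcellated functional connectivity: construction, connection-group
statistics, network cross-tabulation, and classical MDS.

Per subject, FC is the Pearson correlation matrix of parcel-averaged rest
time series.  For group statistics correlations are Fisher r-to-z
transformed (arctanh) before averaging; group-average matrices are
back-transformed for display while statistics stay in z-space.

Connection groups: with parcels partitioned into {core, penumbra, nonMD},
the unordered class pairs give six groups of within-hemisphere connections
(core-core, core-penumbra, penumbra-penumbra, core-nonMD, penumbra-nonMD,
nonMD-nonMD).  Per subject and hemisphere the group mean is the mean z over
that group's parcel pairs (diagonal excluded); groups are compared with
paired t-tests across subjects over all C(6,2)=15 pairs per hemisphere,
Bonferroni-corrected for the 30 comparisons across both hemispheres.

MDS: classical (Torgerson) scaling of the 1-r distance matrix — double
center -1/2 * J D^2 J, eigendecompose, scale eigenvectors by the square
root of their (positive) eigenvalues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .containers import FCMatrix, ParcelTimeSeries, ValidationError

__all__ = [
    "GROUP_NAMES",
    "CLASSES",
    "ConnectionGroupStats",
    "MDSResult",
    "parcel_fc",
    "fisher_z",
    "fisher_z_inv",
    "connection_pair_counts",
    "connection_group_stats",
    "network_crosstab",
    "network_restricted_group_stats",
    "group_average_fc",
    "classical_mds",
]

CLASSES = ("core", "penumbra", "nonMD")
# unordered class pairs, in a fixed display order
GROUP_NAMES = (
    ("core", "core"),
    ("core", "penumbra"),
    ("penumbra", "penumbra"),
    ("core", "nonMD"),
    ("penumbra", "nonMD"),
    ("nonMD", "nonMD"),
)

R_CLAMP = 1.0 - 1e-7


def parcel_fc(ts: ParcelTimeSeries) -> FCMatrix:
    """Pearson correlation matrix of one subject's parcel time series."""
    if ts.n_timepoints < 3:
        raise ValidationError("need >= 3 timepoints for a correlation matrix")
    sd = ts.data.std(axis=0)
    constant = np.flatnonzero(sd == 0.0)
    if constant.size:
        names = [ts.parcel_ids[i] for i in constant[:5]]
        raise ValidationError(f"constant time series for parcel(s): {names}")
    r = np.corrcoef(ts.data, rowvar=False)
    r = 0.5 * (r + r.T)
    np.fill_diagonal(r, 1.0)
    np.clip(r, -1.0, 1.0, out=r)
    return FCMatrix(r=r, parcel_ids=ts.parcel_ids, hemispheres=ts.hemispheres)


def fisher_z(r, clamp: bool = True):
    """Fisher r-to-z (arctanh), clamping |r| to 1-1e-7 with a warning."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        if not clamp:
            raise ValidationError("|r| >= 1 outside arctanh domain")
        warnings.warn("clamping |r| >= 1 to 1 - 1e-7 before arctanh", stacklevel=2)
        r = np.clip(r, -R_CLAMP, R_CLAMP)
    return np.arctanh(r)


def fisher_z_inv(z):
    """Inverse Fisher transform (tanh)."""
    return np.tanh(np.asarray(z, dtype=float))


def _pair_masks(classes: np.ndarray, hemis: np.ndarray) -> dict:
    """Boolean upper-triangle masks for each (hemisphere, group)."""
    n = classes.size
    iu, ju = np.triu_indices(n, k=1)
    same_hemi = hemis[iu] == hemis[ju]
    masks = {}
    for hemi in ("L", "R"):
        in_hemi = same_hemi & (hemis[iu] == hemi)
        for ga, gb in GROUP_NAMES:
            pair_ab = (classes[iu] == ga) & (classes[ju] == gb)
            pair_ba = (classes[iu] == gb) & (classes[ju] == ga)
            masks[(hemi, (ga, gb))] = in_hemi & (pair_ab | pair_ba)
    return masks, iu, ju


def _classes_and_hemis(fc: FCMatrix, partition: dict):
    missing = [p for p in fc.parcel_ids if p not in partition]
    if missing:
        raise ValidationError(f"parcels missing from partition: {missing[:5]}")
    classes = np.array([partition[p] for p in fc.parcel_ids])
    bad = sorted(set(classes) - set(CLASSES))
    if bad:
        raise ValidationError(f"unknown partition classes: {bad}")
    return classes, np.array(fc.hemispheres)


def connection_pair_counts(fc: FCMatrix, partition: dict) -> dict:
    """(hemisphere, group) -> number of within-hemisphere parcel pairs."""
    classes, hemis = _classes_and_hemis(fc, partition)
    masks, _, _ = _pair_masks(classes, hemis)
    return {key: int(mask.sum()) for key, mask in masks.items()}


@dataclass
class ConnectionGroupStats:
    """Per-subject group-mean z values and all pairwise group comparisons."""

    group_names: tuple
    hemispheres: tuple
    mean_z: dict          # hemi -> (subjects, groups) array
    pair_counts: dict     # (hemi, group) -> pair count
    comparisons: list     # dicts: hemi, group_a, group_b, t, df, p, significant
    m: int
    alpha: float

    def group_mean(self, hemi: str, group) -> float:
        gi = self.group_names.index(tuple(group))
        return float(self.mean_z[hemi][:, gi].mean())


def connection_group_stats(
    fcs: list[FCMatrix],
    partition: dict,
    alpha: float = 0.05,
    allow_empty: bool = False,
) -> ConnectionGroupStats:
    """Six connection-group means per subject/hemisphere plus paired tests.

    Group means are means of Fisher-z values over within-hemisphere parcel
    pairs; all 15 group pairs per hemisphere are compared with paired
    t-tests across subjects at p <= alpha/30 (Bonferroni over the 30
    comparisons).  An empty group raises unless ``allow_empty`` (its mean
    is then NaN and its comparisons are skipped).
    """
    if not fcs:
        raise ValidationError("need at least one subject FC matrix")
    first = fcs[0]
    classes, hemis = _classes_and_hemis(first, partition)
    masks, iu, ju = _pair_masks(classes, hemis)
    empty = [key for key, mask in masks.items() if not mask.any()]
    if empty and not allow_empty:
        raise ValidationError(f"connection groups with no pairs: {empty}")
    n_s = len(fcs)
    hemispheres = ("L", "R")
    mean_z = {h: np.full((n_s, len(GROUP_NAMES)), np.nan) for h in hemispheres}
    for si, fc in enumerate(fcs):
        if fc.parcel_ids != first.parcel_ids:
            raise ValidationError("subject FC matrices cover different parcels")
        z_upper = fisher_z(fc.r[iu, ju])
        for hi, hemi in enumerate(hemispheres):
            for gi, group in enumerate(GROUP_NAMES):
                mask = masks[(hemi, group)]
                if mask.any():
                    mean_z[hemi][si, gi] = z_upper[mask].mean()
    m = 2 * len(list(combinations(GROUP_NAMES, 2)))  # 30
    comparisons = []
    for hemi in hemispheres:
        for (gi, ga), (gj, gb) in combinations(enumerate(GROUP_NAMES), 2):
            a, b = mean_z[hemi][:, gi], mean_z[hemi][:, gj]
            if np.isnan(a).any() or np.isnan(b).any():
                continue
            d = a - b
            sd = d.std(ddof=1)
            if sd == 0.0:
                t, p = (0.0, 1.0) if d.mean() == 0 else (np.sign(d.mean()) * np.inf, 0.0)
            else:
                t = d.mean() / (sd / np.sqrt(n_s))
                p = 2.0 * stats.t.sf(abs(t), n_s - 1)
            comparisons.append(
                {
                    "hemisphere": hemi,
                    "group_a": ga,
                    "group_b": gb,
                    "mean_diff_z": float(d.mean()),
                    "t": float(t),
                    "df": n_s - 1,
                    "p": float(p),
                    "significant": bool(p <= alpha / m),
                }
            )
    return ConnectionGroupStats(
        group_names=GROUP_NAMES,
        hemispheres=hemispheres,
        mean_z=mean_z,
        pair_counts={key: int(mask.sum()) for key, mask in masks.items()},
        comparisons=comparisons,
        m=m,
        alpha=alpha,
    )


def network_crosstab(partition: dict, network_labels: dict) -> dict:
    """Contingency counts of core/penumbra/nonMD parcels per network."""
    missing = sorted(set(partition) - set(network_labels))
    if missing:
        raise ValidationError(f"parcels without network labels: {missing[:5]}")
    counts: dict = {}
    for parcel, cls in partition.items():
        net = network_labels[parcel]
        counts.setdefault(net, {c: 0 for c in CLASSES})
        counts[net][cls] += 1
    return counts


def network_restricted_group_stats(
    fcs: list[FCMatrix],
    partition: dict,
    network_labels: dict,
    network: str,
    alpha: float = 0.05,
) -> ConnectionGroupStats:
    """Connection-group statistics among the parcels of a single network.

    Parcels outside the network keep their class but contribute no pairs:
    implemented by restricting the FC matrices to the network's parcels
    and delegating.  Groups emptied by the restriction are allowed.
    """
    keep = [i for i, p in enumerate(fcs[0].parcel_ids) if network_labels.get(p) == network]
    if len(keep) < 2:
        raise ValidationError(f"network {network!r} has fewer than 2 parcels")
    idx = np.asarray(keep)
    restricted = [
        FCMatrix(
            r=fc.r[np.ix_(idx, idx)],
            parcel_ids=tuple(fc.parcel_ids[i] for i in keep),
            hemispheres=tuple(fc.hemispheres[i] for i in keep),
        )
        for fc in fcs
    ]
    sub_partition = {p: partition[p] for p in restricted[0].parcel_ids}
    return connection_group_stats(restricted, sub_partition, alpha=alpha, allow_empty=True)


def group_average_fc(fcs: list[FCMatrix]) -> FCMatrix:
    """Elementwise mean in z-space, back-transformed to r; unit diagonal."""
    if not fcs:
        raise ValidationError("need at least one subject FC matrix")
    first = fcs[0]
    for fc in fcs[1:]:
        if fc.r.shape != first.r.shape or fc.parcel_ids != first.parcel_ids:
            raise ValidationError("subject FC matrices have mismatched dimensions")
    z = np.zeros_like(first.r)
    mask = ~np.eye(first.n_parcels, dtype=bool)
    for fc in fcs:
        z[mask] += fisher_z(fc.r[mask])
    r = np.zeros_like(z)
    r[mask] = fisher_z_inv(z[mask] / len(fcs))
    np.fill_diagonal(r, 1.0)
    return FCMatrix(r=r, parcel_ids=first.parcel_ids, hemispheres=first.hemispheres)


@dataclass
class MDSResult:
    """Classical-MDS embedding: coordinates (areas x k) and all eigenvalues."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    n_negative: int

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distances reproduced by the embedding."""
        diff = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))


def classical_mds(d: np.ndarray, k: int = 2) -> MDSResult:
    """Classical (Torgerson) multidimensional scaling of a distance matrix.

    Double-centers -1/2 * J D^2 J, eigendecomposes, and returns the top-k
    coordinates scaled by the square root of the eigenvalues.  Negative
    eigenvalues (the distance need not be Euclidean) are truncated to zero
    with a warning; coordinates are unique up to rotation/reflection.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape != (n, n):
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10, rtol=0):
        raise ValidationError("distance matrix must be symmetric")
    if np.any(d < 0) or not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValidationError("distances must be nonnegative with zero diagonal")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_neg = int((eigval < -1e-10 * max(1.0, abs(eigval[0]))).sum())
    if n_neg:
        warnings.warn(
            f"{n_neg} negative eigenvalue(s) truncated (non-Euclidean distances)",
            stacklevel=2,
        )
    top = eigval[:k].clip(min=0.0)
    coords = eigvec[:, :k] * np.sqrt(top)[None, :]
    return MDSResult(coordinates=coords, eigenvalues=eigval, n_negative=n_neg)
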