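"""Subcortical/cerebellar MD mapping.

Two complementary voxelwise analyses over 19 labelled subcortical and
cerebellar structures:

* **Task conjunction** — per structure and contrast, voxelwise one-sample
  t-tests (positive-gated) corrected by Benjamini-Hochberg FDR within the
  structure at q = alpha / n_structures (FDR within structure, Bonferroni
  over the 19 structures), then the conjunction of significant voxels
  across the three contrasts.
* **Core-FC permutation mapping** — each voxel's score is its mean
  Fisher-z connectivity to the cortical core MD areas.  Significance comes
  from a per-voxel empirical null built from the voxel's mean z to many
  random sets of ``core_size`` parcels drawn across both hemispheres; a
  voxel is significant when its observed score strictly exceeds its null's
  97.5th percentile (nearest-rank).

Replication between two half-cohort maps is summarized by the Pearson
correlation of the continuous scores and the Dice coefficient of the
significant-voxel sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ParcelTimeSeries, ValidationError, VoxelTable
from .fcnet import fisher_z

__all__ = [
    "VoxelMap",
    "structure_task_conjunction",
    "voxel_core_fc",
    "voxel_parcel_z",
    "permutation_null",
    "permutation_null_scores",
    "replication_metrics",
    "dice",
]

DEFAULT_PERCENTILE = 97.5
DEFAULT_N_PERM = 10_000
PAPER_N_PERM = 100_000


@dataclass
class VoxelMap:
    """Per-voxel score, null percentile threshold, and significance flag."""

    voxel_ids: tuple
    structures: tuple
    score: np.ndarray
    null_percentile: np.ndarray
    significant: np.ndarray

    def __post_init__(self):
        bad = self.significant & ~(self.score > self.null_percentile)
        if bad.any():
            raise ValidationError("significant voxels must exceed their null percentile")

    def significant_set(self, structure: str | None = None) -> frozenset:
        return frozenset(
            v
            for v, s, sig in zip(self.voxel_ids, self.structures, self.significant)
            if sig and (structure is None or s == structure)
        )


def structure_task_conjunction(
    v: VoxelTable,
    alpha: float = 0.05,
    n_structures: int = 19,
) -> np.ndarray:
    """Conjunction of FDR-significant positive voxels across all contrasts.

    Per structure and contrast: voxelwise one-sample t across subjects,
    two-sided p, positive-mean gate, Benjamini-Hochberg step-up within the
    structure at q = alpha / n_structures.  Returns a boolean vector over
    voxels (True = significant in every contrast).
    """
    if v.betas is None:
        raise ValidationError("voxel table has no task betas")
    n_s = v.betas.shape[0]
    if n_s < 2:
        raise ValidationError("task conjunction requires >= 2 subjects")
    q = alpha / n_structures
    structures = np.array(v.structures)
    n_vox, n_c = v.betas.shape[1], v.betas.shape[2]
    flags = np.ones(n_vox, dtype=bool)
    for ci in range(n_c):
        sig_c = np.zeros(n_vox, dtype=bool)
        for s in dict.fromkeys(v.structures):
            vi = np.flatnonzero(structures == s)
            x = v.betas[:, vi, ci]
            mean = x.mean(axis=0)
            sd = x.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = mean / (sd / np.sqrt(n_s))
            p = 2.0 * stats.t.sf(np.abs(t), n_s - 1)
            p = np.where(sd == 0.0, np.where(mean == 0.0, 1.0, 0.0), p)
            reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
            sig_c[vi] = reject & (mean > 0)
        flags &= sig_c
    return flags


def voxel_parcel_z(v: VoxelTable, cortex: ParcelTimeSeries | None = None) -> np.ndarray:
    """Fisher-z connectivity of every voxel to every cortical parcel.

    Uses the voxel table's rest session and its matching cortical session
    (overridable).  Returns a (voxels, parcels) matrix.
    """
    if v.timeseries is None:
        raise ValidationError("voxel table has no time series")
    cortex = cortex if cortex is not None else v.cortex
    if cortex is None:
        raise ValidationError("no cortical parcel time series supplied")
    if cortex.n_timepoints != v.timeseries.shape[0]:
        raise ValidationError("voxel and parcel time series lengths differ")
    vx = v.timeseries
    px = cortex.data
    v_sd = vx.std(axis=0)
    p_sd = px.std(axis=0)
    if np.any(v_sd == 0.0):
        names = [v.voxel_ids[i] for i in np.flatnonzero(v_sd == 0.0)[:5]]
        raise ValidationError(f"constant time series for voxel(s): {names}")
    if np.any(p_sd == 0.0):
        names = [cortex.parcel_ids[i] for i in np.flatnonzero(p_sd == 0.0)[:5]]
        raise ValidationError(f"constant time series for parcel(s): {names}")
    t = vx.shape[0]
    vc = vx - vx.mean(axis=0)
    pc = px - px.mean(axis=0)
    r = (vc.T @ pc) / (t * np.outer(v_sd, p_sd))
    np.clip(r, -1.0, 1.0, out=r)
    return fisher_z(r)


def voxel_core_fc(
    v: VoxelTable,
    core_parcels,
    cortex: ParcelTimeSeries | None = None,
    z: np.ndarray | None = None,
) -> np.ndarray:
    """Mean Fisher-z connectivity of each voxel to the cortical core areas.

    ``core_parcels`` are parcel ids (both hemispheres).  ``z`` may carry a
    precomputed voxel-by-parcel z matrix to avoid recomputation.
    """
    cortex = cortex if cortex is not None else v.cortex
    if cortex is None:
        raise ValidationError("no cortical parcel time series supplied")
    core_parcels = list(core_parcels)
    if not core_parcels:
        raise ValidationError("core parcel set is empty")
    missing = [p for p in core_parcels if p not in cortex.parcel_ids]
    if missing:
        raise ValidationError(f"core parcels missing from cortex: {missing[:5]}")
    if z is None:
        z = voxel_parcel_z(v, cortex)
    idx = [cortex.parcel_ids.index(p) for p in core_parcels]
    return z[:, idx].mean(axis=1)


def _nearest_rank_percentile(sorted_null: np.ndarray, percentile: float) -> np.ndarray:
    """Nearest-rank percentile along the last axis of a pre-sorted array."""
    n = sorted_null.shape[-1]
    rank = int(np.ceil(percentile / 100.0 * n))
    rank = min(max(rank, 1), n)
    return sorted_null[..., rank - 1]


def permutation_null_scores(
    z: np.ndarray,
    core_idx,
    n_perm: int = DEFAULT_N_PERM,
    percentile: float = DEFAULT_PERCENTILE,
    seed: int = 0,
    exhaustive: bool = False,
    exclude_core: bool = False,
    chunk: int = 500,
):
    """Permutation test on a precomputed voxel-by-parcel z matrix.

    Each permutation draws ``len(core_idx)`` parcel columns without
    replacement (one shared draw per permutation, reused for every voxel);
    the null score is the mean z over the drawn set.  Returns
    (observed, threshold, significant): the observed mean z over
    ``core_idx``, the per-voxel nearest-rank ``percentile`` of the null,
    and the strict-inequality flags.

    ``exhaustive=True`` enumerates all parcel subsets instead of sampling
    (small problems only).  ``exclude_core=True`` removes the true core
    parcels from the null draws.
    """
    z = np.asarray(z, dtype=float)
    core_idx = np.asarray(list(core_idx), dtype=int)
    core_size = core_idx.size
    if core_size == 0:
        raise ValidationError("core set is empty")
    observed = z[:, core_idx].mean(axis=1)
    pool = np.arange(z.shape[1])
    if exclude_core:
        pool = np.setdiff1d(pool, core_idx)
    if core_size > pool.size:
        raise ValidationError("core_size exceeds the number of candidate parcels")
    if exhaustive:
        draws = np.array(list(combinations(pool, core_size)))
    else:
        if n_perm < 100:
            raise ValidationError("n_perm must be >= 100")
        rng = np.random.default_rng(seed)
        draws = np.empty((n_perm, core_size), dtype=int)
        for i in range(n_perm):
            draws[i] = rng.choice(pool, size=core_size, replace=False)
    n_draws = draws.shape[0]
    null = np.empty((z.shape[0], n_draws))
    for start in range(0, n_draws, chunk):
        block = draws[start : start + chunk]  # (b, core_size)
        null[:, start : start + len(block)] = z[:, block].mean(axis=2)
    null.sort(axis=1)
    threshold = _nearest_rank_percentile(null, percentile)
    return observed, threshold, observed > threshold


def permutation_null(
    v: VoxelTable,
    core_parcels,
    n_perm: int = DEFAULT_N_PERM,
    percentile: float = DEFAULT_PERCENTILE,
    seed: int = 0,
    cortex: ParcelTimeSeries | None = None,
    exhaustive: bool = False,
    exclude_core: bool = False,
) -> VoxelMap:
    """Permutation test of voxel-to-core connectivity (see
    :func:`permutation_null_scores`): the voxel-by-parcel z matrix is
    computed once, the null draws random parcel sets of the core's size
    across both hemispheres, and a voxel is significant iff its observed
    core score strictly exceeds its null's ``percentile``.
    """
    cortex = cortex if cortex is not None else v.cortex
    if cortex is None:
        raise ValidationError("no cortical parcel time series supplied")
    core_parcels = list(core_parcels)
    missing = [p for p in core_parcels if p not in cortex.parcel_ids]
    if missing:
        raise ValidationError(f"core parcels missing from cortex: {missing[:5]}")
    z = voxel_parcel_z(v, cortex)
    core_idx = [cortex.parcel_ids.index(p) for p in core_parcels]
    observed, threshold, significant = permutation_null_scores(
        z, core_idx, n_perm=n_perm, percentile=percentile, seed=seed,
        exhaustive=exhaustive, exclude_core=exclude_core,
    )
    return VoxelMap(
        voxel_ids=v.voxel_ids,
        structures=v.structures,
        score=observed,
        null_percentile=threshold,
        significant=significant,
    )


def dice(a, b) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|); 1.0 when both sets are empty."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return 2.0 * len(a & b) / (len(a) + len(b))


def replication_metrics(map_a: VoxelMap, map_b: VoxelMap, structure: str) -> dict:
    """Pearson r of scores and Dice of significant sets within one structure."""
    if map_a.voxel_ids != map_b.voxel_ids:
        raise ValidationError("maps cover different voxel universes")
    sel = np.array([s == structure for s in map_a.structures])
    if not sel.any():
        raise ValidationError(f"structure {structure!r} has no voxels")
    xa, xb = map_a.score[sel], map_b.score[sel]
    if xa.std() == 0 or xb.std() == 0:
        raise ValidationError("constant score vector: correlation undefined")
    r = float(np.corrcoef(xa, xb)[0, 1])
    d = dice(map_a.significant_set(structure), map_b.significant_set(structure))
    return {"pearson_r": r, "dice": d}
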