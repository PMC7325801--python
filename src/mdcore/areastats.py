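"""Parcel-level task statistics and MD-system classification.

The analysis chain is:

1. :func:`hemisphere_average` — average each area's betas over the two
   hemispheres (improves SNR; the planted effects are bilateral).
2. :func:`area_ttests` — per-area one-sample t-tests of the group betas
   against zero, Bonferroni-corrected over the 180 areas per contrast.
   "Significant positive" means two-sided p <= alpha/m AND a positive mean
   (a positive-mean gate on a two-sided test, conservative relative to a
   one-sided test).
3. :func:`conjunction_extended_md` — the extended MD system is the
   conjunction (intersection) of significant-positive areas across the
   three contrasts.
4. :func:`core_classification` — core MD areas activate significantly above
   the mean of the extended set.  For each area and contrast we form
   per-subject differences from that subject's extended-set mean (a
   paired-style test: the global subject offset cancels) and t-test them
   with Bonferroni correction over the extended-set size.  Areas above the
   mean in all three contrasts are "full" core, in exactly two "partial"
   core; the remainder of the extended set is the penumbra.
5. :func:`task_profiles` / :func:`split_half_profile_correlation` —
   normalized task profiles across the MD set (z-scored across areas within
   each subject and contrast, then subject-averaged) and their split-half
   replication matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import BetaTable, ValidationError

__all__ = [
    "AreaStat",
    "MDPartition",
    "TaskProfile",
    "hemisphere_average",
    "area_ttests",
    "conjunction_extended_md",
    "core_classification",
    "merge_areas",
    "task_profiles",
    "split_half_profile_correlation",
    "one_sample_ttest",
]

DEFAULT_ALPHA = 0.05
DEFAULT_BONFERRONI_M = 180


@dataclass(frozen=True)
class AreaStat:
    """One-sample t-test result for a single area (or segment)."""

    area_id: str
    mean_beta: float
    t: float
    df: int
    p: float
    significant_positive: bool
    degenerate: bool = False  # zero variance across subjects


@dataclass
class MDPartition:
    """Extended / core(full, partial) / penumbra membership, plus the stats."""

    extended_set: frozenset
    core_full_set: frozenset = frozenset()
    core_partial_set: frozenset = frozenset()
    stats: dict = None  # contrast -> {area -> AreaStat}

    def __post_init__(self):
        if not (self.core_full_set | self.core_partial_set) <= self.extended_set:
            raise ValidationError("core sets must be subsets of the extended set")
        if self.core_full_set & self.core_partial_set:
            raise ValidationError("full and partial core sets must be disjoint")

    @property
    def core_set(self) -> frozenset:
        return self.core_full_set | self.core_partial_set

    @property
    def penumbra_set(self) -> frozenset:
        return self.extended_set - self.core_set


@dataclass
class TaskProfile:
    """Normalized (z-scored) task profiles across an MD area set."""

    area_ids: tuple
    contrast_ids: tuple
    zbar: np.ndarray              # (areas, contrasts): subject-mean z
    sd_between_tasks: np.ndarray  # (areas,): subject-mean SD of z across contrasts
    preference_weights: np.ndarray  # (areas, contrasts): nonnegative


def one_sample_ttest(x: np.ndarray) -> tuple[float, int, float, bool]:
    """Two-sided one-sample t-test of a 1-D sample against zero.

    Returns (t, df, p, degenerate).  A zero-variance sample is flagged
    degenerate: t is +/-inf (or 0 for an all-zero sample) and p is 0
    (or 1), so the caller decides significance by the sign of the mean.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValidationError("t-test requires >= 2 observations")
    mean = x.mean()
    sd = x.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 1.0, True
        return float(np.sign(mean)) * np.inf, df, 0.0, True
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p), False


def hemisphere_average(b: BetaTable) -> BetaTable:
    """Average each area's betas across the L and R hemispheres.

    Every area must appear in both hemispheres; the output drops the
    hemisphere axis and keeps one row per area name.
    """
    if b.hemispheres is None:
        raise ValidationError("table already hemisphere-averaged (no hemisphere labels)")
    left = {a: i for i, (a, h) in enumerate(zip(b.area_ids, b.hemispheres)) if h == "L"}
    right = {a: i for i, (a, h) in enumerate(zip(b.area_ids, b.hemispheres)) if h == "R"}
    unpaired = sorted(set(left) ^ set(right))
    if unpaired:
        raise ValidationError(f"areas missing from one hemisphere: {unpaired}")
    names = [a for a, h in zip(b.area_ids, b.hemispheres) if h == "L"]
    li = np.array([left[a] for a in names])
    ri = np.array([right[a] for a in names])
    return BetaTable(
        beta=0.5 * (b.beta[:, li, :] + b.beta[:, ri, :]),
        subject_ids=b.subject_ids,
        area_ids=tuple(names),
        contrast_ids=b.contrast_ids,
        hemispheres=None,
    )


def area_ttests(
    b: BetaTable,
    contrast: str,
    alpha: float = DEFAULT_ALPHA,
    m: int = DEFAULT_BONFERRONI_M,
) -> list[AreaStat]:
    """Per-area one-sample t-tests of one contrast's betas against zero.

    ``significant_positive`` requires two-sided p <= alpha/m and a positive
    mean.  ``m`` is the Bonferroni correction count (the full number of
    areas tested per contrast, 180 by default).
    """
    if m < b.n_areas:
        raise ValidationError(f"Bonferroni m={m} smaller than {b.n_areas} areas tested")
    ci = b.contrast_ids.index(contrast)
    threshold = alpha / m
    x = b.beta[:, :, ci]
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    degen = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    # zero-variance areas: decide by the sign of the constant mean
    with np.errstate(invalid="ignore"):
        t = np.where(degen, np.sign(mean) * np.inf, t)
        t = np.where(degen & (mean == 0.0), 0.0, t)
    p = np.where(degen, np.where(mean == 0.0, 1.0, 0.0), p)
    sig = (p <= threshold) & (mean > 0)
    return [
        AreaStat(
            area_id=area, mean_beta=float(mean[ai]), t=float(t[ai]), df=n - 1,
            p=float(p[ai]), significant_positive=bool(sig[ai]),
            degenerate=bool(degen[ai]),
        )
        for ai, area in enumerate(b.area_ids)
    ]


def conjunction_extended_md(stats_per_contrast: dict) -> MDPartition:
    """Intersection of significant-positive areas across all contrasts.

    ``stats_per_contrast`` maps contrast id -> list of :class:`AreaStat`
    over the same area universe.
    """
    if not stats_per_contrast:
        raise ValidationError("need at least one contrast")
    universes = [
        tuple(s.area_id for s in stats) for stats in stats_per_contrast.values()
    ]
    if len({frozenset(u) for u in universes}) != 1:
        raise ValidationError("contrasts cover different area universes")
    sig_sets = [
        {s.area_id for s in stats if s.significant_positive}
        for stats in stats_per_contrast.values()
    ]
    extended = frozenset.intersection(*map(frozenset, sig_sets))
    stats = {
        c: {s.area_id: s for s in stats} for c, stats in stats_per_contrast.items()
    }
    return MDPartition(extended_set=extended, stats=stats)


def core_classification(
    b: BetaTable,
    extended_set,
    alpha: float = DEFAULT_ALPHA,
) -> MDPartition:
    """Classify extended-MD areas as core (full/partial) or penumbra.

    For each extended area and contrast, per-subject differences from that
    subject's mean over the extended set are t-tested against zero
    (Bonferroni m = extended-set size).  Significantly-above-mean in all
    contrasts -> full core; in exactly all-but-one (two of three) ->
    partial core; otherwise penumbra.
    """
    extended = sorted(extended_set)
    if len(extended) < 2:
        raise ValidationError("extended set must have >= 2 areas to define a mean")
    missing = [a for a in extended if a not in b.area_ids]
    if missing:
        raise ValidationError(f"extended areas missing from table: {missing}")
    idx = np.array([b.area_ids.index(a) for a in extended])
    sub = b.beta[:, idx, :]  # (subjects, extended areas, contrasts)
    diffs = sub - sub.mean(axis=1, keepdims=True)
    m = len(extended)
    threshold = alpha / m
    n_c = len(b.contrast_ids)
    stats_out: dict = {c: {} for c in b.contrast_ids}
    n_sig = np.zeros(m, dtype=int)
    for ci, contrast in enumerate(b.contrast_ids):
        for ai, area in enumerate(extended):
            t, df, p, degen = one_sample_ttest(diffs[:, ai, ci])
            mean = float(diffs[:, ai, ci].mean())
            sig = (p <= threshold) and (mean > 0)
            stats_out[contrast][area] = AreaStat(
                area_id=area, mean_beta=mean, t=t, df=df, p=p,
                significant_positive=bool(sig), degenerate=degen,
            )
            n_sig[ai] += int(sig)
    full = frozenset(a for ai, a in enumerate(extended) if n_sig[ai] == n_c)
    partial = frozenset(
        a
        for ai, a in enumerate(extended)
        if 0 < n_sig[ai] == n_c - 1
    )
    return MDPartition(
        extended_set=frozenset(extended),
        core_full_set=full,
        core_partial_set=partial,
        stats=stats_out,
    )


def merge_areas(
    b: BetaTable,
    area_list,
    weights=None,
    merged_id: str = None,
) -> BetaTable:
    """Replace ``area_list`` with a single weighted-mean composite area.

    Default weights are equal.  The composite is appended and the member
    areas removed; other areas are untouched.
    """
    area_list = list(area_list)
    if not area_list:
        raise ValidationError("cannot merge an empty area list")
    if b.hemispheres is not None:
        raise ValidationError("merge_areas expects a hemisphere-averaged table")
    idx = []
    for a in area_list:
        if a not in b.area_ids:
            raise ValidationError(f"area {a!r} not in table")
        idx.append(b.area_ids.index(a))
    if weights is None:
        w = np.full(len(idx), 1.0 / len(idx))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(idx),):
            raise ValidationError("weights must match the merged area list")
        if w.sum() <= 0:
            raise ValidationError("weights must have a positive sum")
        w = w / w.sum()
    merged = np.einsum("sac,a->sc", b.beta[:, idx, :], w)
    keep = [i for i in range(b.n_areas) if i not in set(idx)]
    merged_id = merged_id or "+".join(area_list)
    return BetaTable(
        beta=np.concatenate([b.beta[:, keep, :], merged[:, None, :]], axis=1),
        subject_ids=b.subject_ids,
        area_ids=tuple(b.area_ids[i] for i in keep) + (merged_id,),
        contrast_ids=b.contrast_ids,
        hemispheres=None,
    )


def task_profiles(b: BetaTable, md_set) -> TaskProfile:
    """Normalized task profiles across an MD area set.

    For each subject and contrast, betas are z-scored across the MD areas
    (sample SD); ``zbar`` is the subject-mean z.  ``sd_between_tasks`` per
    area is the subject-mean of the sample SD of that subject's z-scores
    across contrasts.  ``preference_weights`` shift each area's mean z to
    be nonnegative (for display as relative task preferences).
    """
    md = sorted(md_set)
    if len(md) < 3:
        raise ValidationError("task profiles need >= 3 MD areas")
    missing = [a for a in md if a not in b.area_ids]
    if missing:
        raise ValidationError(f"MD areas missing from table: {missing}")
    idx = np.array([b.area_ids.index(a) for a in md])
    sub = b.beta[:, idx, :]  # (subjects, md areas, contrasts)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    degenerate = np.argwhere(sd[:, 0, :] == 0.0)
    if degenerate.size:
        s, c = degenerate[0]
        raise ValidationError(
            f"zero across-area variance for subject {b.subject_ids[s]!r}, "
            f"contrast {b.contrast_ids[c]!r}"
        )
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd
    zbar = z.mean(axis=0)
    if len(b.contrast_ids) >= 2:
        sd_between = z.std(axis=2, ddof=1).mean(axis=0)
    else:
        sd_between = np.zeros(len(md))  # one contrast: no between-task spread
    pref = zbar - zbar.min(axis=1, keepdims=True)
    return TaskProfile(
        area_ids=tuple(md),
        contrast_ids=b.contrast_ids,
        zbar=zbar,
        sd_between_tasks=sd_between,
        preference_weights=pref,
    )


def split_half_profile_correlation(b: BetaTable, md_set, split) -> np.ndarray:
    """Cross-contrast correlation of group-mean profiles between two halves.

    ``split`` is a boolean array over subjects (True -> group 1).  Entry
    (i, j) is the Pearson correlation, across the MD areas, between group
    1's mean profile for contrast i and group 2's mean profile for
    contrast j.  Diagonal entries therefore measure split-half
    replication; off-diagonal entries measure between-task similarity.
    """
    split = np.asarray(split, dtype=bool)
    if split.shape != (b.n_subjects,):
        raise ValidationError("split must be a boolean vector over subjects")
    if split.all() or not split.any():
        raise ValidationError("split must leave both groups nonempty")
    md = sorted(md_set)
    idx = np.array([b.area_ids.index(a) for a in md])
    g1 = b.beta[split][:, idx, :].mean(axis=0)     # (areas, contrasts)
    g2 = b.beta[~split][:, idx, :].mean(axis=0)
    n_c = len(b.contrast_ids)
    out = np.empty((n_c, n_c))
    for i in range(n_c):
        for j in range(n_c):
            x, y = g1[:, i], g2[:, j]
            if x.std() == 0 or y.std() == 0:
                raise ValidationError(
                    f"constant group profile for contrast pair ({i}, {j})"
                )
            out[i, j] = np.corrcoef(x, y)[0, 1]
    return out
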