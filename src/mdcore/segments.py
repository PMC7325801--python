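"""Segment-wise activation analysis across an areal border.

The dorsomedial frontal MD activation straddles the border between areas
8BM and SCEF.  Each area is divided into 10 equal posterior→anterior
segments (division itself happens upstream; the segment beta table is the
contract boundary) and every segment is tested as if it were an area of
its own: significantly positive in all three contrasts at the same
Bonferroni criterion used for the 180 areas.  Significant segments of the
two areas are then merged into a single composite "8BM/SCEF" area.
"""

from __future__ import annotations

import numpy as np

from .areastats import (
    DEFAULT_ALPHA,
    DEFAULT_BONFERRONI_M,
    AreaStat,
    area_ttests,
    merge_areas,
)
from .containers import BetaTable, SegmentBetaTable, ValidationError

__all__ = [
    "segment_profile",
    "segment_ttests",
    "segment_conjunction_test",
    "composite_area",
]


def _as_beta_table(t: SegmentBetaTable) -> BetaTable:
    return BetaTable(
        beta=t.beta,
        subject_ids=t.subject_ids,
        area_ids=t.segment_labels,
        contrast_ids=t.contrast_ids,
        hemispheres=None,
    )


def segment_profile(t: SegmentBetaTable) -> np.ndarray:
    """Group-mean beta per segment and contrast, preserving segment order."""
    return t.beta.mean(axis=0)


def segment_ttests(
    t: SegmentBetaTable,
    contrast: str,
    alpha: float = DEFAULT_ALPHA,
    m: int = DEFAULT_BONFERRONI_M,
) -> list[AreaStat]:
    """Per-segment one-sample t-tests, same criterion as for areas."""
    return area_ttests(_as_beta_table(t), contrast, alpha=alpha, m=m)


def segment_conjunction_test(
    t: SegmentBetaTable,
    alpha: float = DEFAULT_ALPHA,
    m: int = DEFAULT_BONFERRONI_M,
) -> np.ndarray:
    """Which segments survive as extended-MD regions on their own.

    A segment is flagged iff it is significantly positive in every contrast
    at the per-contrast criterion used for areas (two-sided p <= alpha/m
    with positive mean; m = 180 by default, i.e. each segment is held to
    the same standard as a full area).
    Returns a boolean vector over segments in table order.
    """
    flags = np.ones(t.n_segments, dtype=bool)
    for contrast in t.contrast_ids:
        stats = segment_ttests(t, contrast, alpha=alpha, m=m)
        flags &= np.array([s.significant_positive for s in stats])
    return flags


def composite_area(
    t: SegmentBetaTable,
    flags,
    merged_id: str = "8BM/SCEF",
) -> np.ndarray:
    """Merge the flagged segments into one composite area.

    Returns the composite beta per subject and contrast (equal-weight mean
    over significant segments, delegated to the generic area merge).
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != (t.n_segments,):
        raise ValidationError("flags must be a boolean vector over segments")
    members = [lab for lab, f in zip(t.segment_labels, flags) if f]
    if not members:
        raise ValidationError("no significant segment: composite area is empty")
    merged = merge_areas(_as_beta_table(t), members, merged_id=merged_id)
    return merged.beta[:, -1, :]
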