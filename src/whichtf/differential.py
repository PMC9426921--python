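"""Differential mode: rank TFs on regions accessible in one sample but not
another, in both directions.

The derived region set for direction A-minus-B is the base-level difference
A \\ B (portion subtraction, matching ``bedtools subtract`` semantics); a
whole-feature mode that drops any A element touching B is available as an
option. A generalised set-combination form, (intersection of group 1) minus
(union of group 2), supports multi-replicate contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import reduce
from typing import Optional, Sequence

from .intervals import (
    GenomicIntervalSet,
    intersect_portions,
    select_overlapping_elements,
    subtract_portions,
)
from .refdata import ReferenceData, TFBSLibrary
from .ranker import TFRanking, rank_tfs
from .termselect import NoInformativeRegionsError, select_top_terms

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialResult",
    "differential_regions",
    "combine_regions",
    "run_differential",
]


@dataclass
class DifferentialResult:
    direction: str  # "A_minus_B" or "B_minus_A"
    regions: GenomicIntervalSet
    ranking: Optional[TFRanking]  # None when no differential regions survive
    reason: Optional[str] = None


def differential_regions(
    a: GenomicIntervalSet,
    b: GenomicIntervalSet,
    whole_feature: bool = False,
) -> GenomicIntervalSet:
    """Portions of A not covered by B (or, whole A elements untouched by B)."""
    if whole_feature:
        touched = select_overlapping_elements(a, b)
        touched_keys = {(iv.chrom, iv.start, iv.end, iv.name) for iv in touched}
        return GenomicIntervalSet(
            iv for iv in a if (iv.chrom, iv.start, iv.end, iv.name) not in touched_keys
        )
    return subtract_portions(a, b)


def combine_regions(
    intersect_group: Sequence[GenomicIntervalSet],
    union_group: Sequence[GenomicIntervalSet] = (),
) -> GenomicIntervalSet:
    """(base-level intersection of group 1) minus (union of group 2)."""
    if not intersect_group:
        raise ValueError("intersect_group must contain at least one region set")
    core = reduce(intersect_portions, intersect_group[1:], intersect_group[0].merged())
    if not union_group:
        return core
    union = GenomicIntervalSet(
        iv for s in union_group for iv in s
    ).merged()
    return subtract_portions(core, union)


def _run_direction(
    label: str,
    regions: GenomicIntervalSet,
    tfbs_lib: TFBSLibrary,
    refs: ReferenceData,
    K: int,
    top_m: int,
) -> DifferentialResult:
    if len(regions) == 0:
        logger.info("%s: no differential regions", label)
        return DifferentialResult(
            direction=label,
            regions=regions,
            ranking=None,
            reason="no differential regions",
        )
    try:
        selection = select_top_terms(regions, tfbs_lib, refs, K=K)
    except NoInformativeRegionsError as exc:
        logger.info("%s: %s", label, exc)
        return DifferentialResult(
            direction=label, regions=regions, ranking=None, reason=str(exc)
        )
    ranking = rank_tfs(regions, tfbs_lib, selection, refs, top_m=top_m)
    return DifferentialResult(direction=label, regions=regions, ranking=ranking)


def run_differential(
    a: GenomicIntervalSet,
    b: GenomicIntervalSet,
    tfbs_lib: TFBSLibrary,
    refs: ReferenceData,
    K: int = 100,
    top_m: int = 10,
    whole_feature: bool = False,
) -> tuple[DifferentialResult, DifferentialResult]:
    """Single-mode pipeline on A \\ B and on B \\ A; two direction reports."""
    ab = differential_regions(a, b, whole_feature=whole_feature)
    ba = differential_regions(b, a, whole_feature=whole_feature)
    return (
        _run_direction("A_minus_B", ab, tfbs_lib, refs, K, top_m),
        _run_direction("B_minus_A", ba, tfbs_lib, refs, K, top_m),
    )
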