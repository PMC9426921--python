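"""Abundance-only comparator ranking: binomial enrichment of each TF's
binding sites against the fraction of the genome covered by the query,
with no use of functional annotation. TFs are ordered by binomial fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .enrichstats import binomial_fold, binomial_tail
from .intervals import (
    GenomicIntervalSet,
    merged_length,
    select_overlapping_elements,
)
from .refdata import TFBSLibrary

__all__ = ["BaselineRow", "BaselineRanking", "prism_enrichment_ranking"]


@dataclass(frozen=True)
class BaselineRow:
    rank: int
    tf: str
    total_sites: int  # M_i
    sites_in_query: int  # m_i
    coverage_fraction: float  # c
    binom_p: float
    fold: float


@dataclass
class BaselineRanking:
    rows: list[BaselineRow]

    @property
    def tf_order(self) -> list[str]:
        return [r.tf for r in self.rows]


def prism_enrichment_ranking(
    query: GenomicIntervalSet,
    tfbs_lib: TFBSLibrary,
    chrom_sizes: Mapping[str, int],
    nongap: Optional[GenomicIntervalSet] = None,
) -> BaselineRanking:
    """Rank TFs by binomial fold of sites-in-query over genome coverage.

    c is the fraction of the genome (total chromosome lengths by default,
    or the non-gap track when supplied) covered by the query. Per TF,
    p = binomial_tail(m_i, M_i, c) and fold = (m_i / M_i) / c; ordering is
    descending fold, ties by ascending p then TF name.
    """
    if len(query) == 0:
        raise ValueError("empty query")
    genome = (
        merged_length(nongap) if nongap is not None else sum(chrom_sizes.values())
    )
    if genome <= 0:
        raise ValueError("genome length must be positive")
    c = merged_length(query) / genome

    rows = []
    for tf in tfbs_lib.tf_names:
        track = tfbs_lib.tracks[tf]
        M_i = len(track)
        m_i = len(select_overlapping_elements(track, query))
        p = binomial_tail(m_i, M_i, c) if M_i > 0 else 1.0
        fold = binomial_fold(m_i, M_i, c) if M_i > 0 else 0.0
        rows.append((tf, M_i, m_i, p, fold))
    rows.sort(key=lambda r: (-r[4], r[3], r[0]))
    return BaselineRanking(
        rows=[
            BaselineRow(
                rank=i,
                tf=tf,
                total_sites=M,
                sites_in_query=m,
                coverage_fraction=c,
                binom_p=p,
                fold=fold,
            )
            for i, (tf, M, m, p, fold) in enumerate(rows, start=1)
        ]
    )
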