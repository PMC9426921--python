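"""Selection of the top-K enriched ontology terms for a query.

The selected terms define the strata within which TFs are subsequently
ranked. Enrichment per term combines a region-based binomial test (query
elements falling in the term's merged regulatory domain vs the term's
non-gap base probability p_pi) and a gene-based hypergeometric test
(annotated genes whose domain is hit by the query). Terms are ordered by
ascending binomial p, ties by ascending hypergeometric p, then term id, so
the selection for a smaller K is always a prefix of that for a larger K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .enrichstats import binomial_logtail, hypergeometric_logtail
from .intervals import GenomicIntervalSet, select_overlapping_elements
from .refdata import ReferenceData, TFBSLibrary

__all__ = [
    "TermEnrichment",
    "TermSelection",
    "NoInformativeRegionsError",
    "great_term_test",
    "select_top_terms",
]


class NoInformativeRegionsError(ValueError):
    """No query element overlaps any predicted binding site."""


@dataclass(frozen=True)
class TermEnrichment:
    term_id: str
    binom_logp: float  # natural log
    hyper_logp: float
    n_genes_term: int
    n_genes_hit: int
    region_hits: int
    p_pi: float

    @property
    def binom_p(self) -> float:
        return math.exp(self.binom_logp)

    @property
    def hyper_p(self) -> float:
        return math.exp(self.hyper_logp)


@dataclass
class TermSelection:
    """Ordered top terms (pi_1 ... pi_K) with per-term enrichment."""

    terms: list[TermEnrichment]
    query_elems: GenomicIntervalSet  # query elements overlapping >=1 TFBS

    @property
    def term_ids(self) -> list[str]:
        return [t.term_id for t in self.terms]

    def __len__(self) -> int:
        return len(self.terms)


def great_term_test(
    query_elems: GenomicIntervalSet,
    term: str,
    refs: ReferenceData,
    *,
    _genes_hit: frozenset[str] | None = None,
) -> TermEnrichment:
    """Binomial and hypergeometric enrichment of one term for the query.

    Binomial: region_hits query elements (of |query_elems|) in the term's
    merged domain, against base probability p_pi. Hypergeometric: of the
    n genes (with >=1 annotation) whose domain overlaps the query, how many
    are annotated to the term, drawn from K term genes in a universe of N
    annotated genes.
    """
    annot = refs.annotations
    term_genes = annot.term_to_genes.get(term, frozenset())
    if not term_genes:
        raise ValueError(f"term {term!r} annotates no genes")

    dom = annot.term_domain(term)
    region_hits = len(select_overlapping_elements(query_elems, dom))
    p_pi = annot.term_base_probability(term)
    binom_logp = binomial_logtail(region_hits, len(query_elems), p_pi)

    universe = annot.annotated_genes
    if _genes_hit is None:
        _genes_hit = frozenset(
            g
            for g in universe
            if g in refs.regdom
            and len(
                select_overlapping_elements(
                    GenomicIntervalSet([refs.regdom[g]]), query_elems
                )
            )
            > 0
        )
    n_hit = len(_genes_hit)
    k_hit = len(_genes_hit & term_genes)
    hyper_logp = hypergeometric_logtail(
        k_hit, n_hit, len(term_genes & universe), len(universe)
    )
    return TermEnrichment(
        term_id=term,
        binom_logp=binom_logp,
        hyper_logp=hyper_logp,
        n_genes_term=len(term_genes),
        n_genes_hit=k_hit,
        region_hits=region_hits,
        p_pi=p_pi,
    )


def _genes_hit_by_query(
    refs: ReferenceData, query_elems: GenomicIntervalSet
) -> frozenset[str]:
    """Annotated genes whose regulatory domain overlaps >=1 query element."""
    hit = set()
    for g in refs.annotations.annotated_genes:
        if g not in refs.regdom:
            continue
        dom_set = GenomicIntervalSet([refs.regdom[g]])
        if len(select_overlapping_elements(dom_set, query_elems)) > 0:
            hit.add(g)
    return frozenset(hit)


def select_top_terms(
    query: GenomicIntervalSet,
    tfbs_lib: TFBSLibrary,
    refs: ReferenceData,
    K: int = 100,
    min_genes: int = 2,
    max_genes: int = 500,
) -> TermSelection:
    """Rank ontology terms for the TFBS-overlapping query elements; keep top K.

    Query elements are kept whole when they overlap >= 1 predicted binding
    site of any TF; terms must annotate between `min_genes` and `max_genes`
    genes after propagation.
    """
    union = tfbs_lib.union_track()
    query_elems = select_overlapping_elements(query, union)
    if len(query_elems) == 0:
        raise NoInformativeRegionsError(
            "no informative regions: no query element overlaps any predicted TFBS"
        )
    annot = refs.annotations
    candidates = [
        t
        for t in sorted(annot.terms)
        if min_genes <= annot.gene_count(t) <= max_genes
    ]
    genes_hit = _genes_hit_by_query(refs, query_elems)
    scored = [
        great_term_test(query_elems, t, refs, _genes_hit=genes_hit)
        for t in candidates
    ]
    scored.sort(key=lambda te: (te.binom_logp, te.hyper_logp, te.term_id))
    return TermSelection(terms=scored[:K], query_elems=query_elems)
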