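"""Reference model: gene regulatory domains, propagated ontology annotations,
term base probabilities, and the per-TF binding-site library.

Regulatory domains follow the basal-plus-extension association rule: each
gene gets a strand-aware basal domain around its TSS (default 5 kb upstream,
1 kb downstream) which is then extended in both directions, up to a maximum
(default 1 Mb), stopping at the nearest neighbouring gene's basal domain on
the same chromosome. A gene always retains its own basal domain even when a
neighbour's basal domain overlaps it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .intervals import (
    GenomicInterval,
    GenomicIntervalSet,
    intersect_portions,
    merged_length,
    read_bed,
)

__all__ = [
    "GeneModel",
    "RegulatoryDomainMap",
    "OntologyGraph",
    "AnnotationTable",
    "TFBSLibrary",
    "ReferenceData",
    "build_regulatory_domains",
    "propagate_annotations",
    "term_base_probability",
    "load_tfbs_library",
    "read_gene_models",
    "read_annotation_pairs",
    "read_ontology_edges",
    "read_tf_gene_map",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its canonical TSS position and strand."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: negative TSS")


@dataclass
class RegulatoryDomainMap:
    """Per-gene putative regulatory interval (single interval per gene)."""

    domains: dict[str, GenomicInterval]

    def __getitem__(self, gene_id: str) -> GenomicInterval:
        return self.domains[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.domains

    def union(self, gene_ids: Iterable[str]) -> GenomicIntervalSet:
        """Merged union of the domains of the given genes."""
        return GenomicIntervalSet(
            self.domains[g] for g in gene_ids if g in self.domains
        ).merged()


class OntologyGraph:
    """Term identifiers plus child -> parent (is_a) edges; must be acyclic."""

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        terms: Iterable[str] = (),
        names: Optional[Mapping[str, str]] = None,
    ) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        g.add_edges_from(edges)  # child -> parent
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology is_a graph contains a cycle: {cycle}")
        self._g = g
        self.names = dict(names or {})

    @property
    def terms(self) -> set[str]:
        return set(self._g.nodes)

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from `term` along is_a edges (excl. itself)."""
        if term not in self._g:
            return set()
        return set(nx.descendants(self._g, term))  # edges point child->parent

    def name(self, term: str) -> str:
        return self.names.get(term, term)


@dataclass
class AnnotationTable:
    """Gene <-> term relation after upward (is_a) propagation.

    Caches per-term merged regulatory domains and base probabilities, keyed
    by term, once :meth:`attach_domains` has been called.
    """

    gene_to_terms: dict[str, frozenset[str]]
    term_to_genes: dict[str, frozenset[str]]
    _term_domain_cache: dict[str, GenomicIntervalSet] = field(default_factory=dict)
    _p_pi_cache: dict[str, float] = field(default_factory=dict)
    _regdom: Optional[RegulatoryDomainMap] = None
    _nongap: Optional[GenomicIntervalSet] = None

    @property
    def terms(self) -> set[str]:
        return set(self.term_to_genes)

    @property
    def annotated_genes(self) -> set[str]:
        return {g for g, ts in self.gene_to_terms.items() if ts}

    def gene_count(self, term: str) -> int:
        return len(self.term_to_genes.get(term, frozenset()))

    def is_annotated(self, gene_id: str, term: str) -> bool:
        return term in self.gene_to_terms.get(gene_id, frozenset())

    def attach_domains(
        self, regdom: RegulatoryDomainMap, nongap: GenomicIntervalSet
    ) -> None:
        """Bind the domain map and non-gap track used by the caches."""
        self._regdom = regdom
        self._nongap = nongap
        self._term_domain_cache.clear()
        self._p_pi_cache.clear()

    def term_domain(self, term: str) -> GenomicIntervalSet:
        """Merged union of the regulatory domains of the term's genes."""
        if self._regdom is None:
            raise RuntimeError("call attach_domains() first")
        if term not in self._term_domain_cache:
            self._term_domain_cache[term] = self._regdom.union(
                sorted(self.term_to_genes.get(term, frozenset()))
            )
        return self._term_domain_cache[term]

    def term_base_probability(self, term: str) -> float:
        if self._nongap is None:
            raise RuntimeError("call attach_domains() first")
        if term not in self._p_pi_cache:
            self._p_pi_cache[term] = term_base_probability(
                term, self._regdom, self, self._nongap
            )
        return self._p_pi_cache[term]


@dataclass
class TFBSLibrary:
    """Per-TF predicted binding-site tracks, capped at `per_tf_cap` sites."""

    tracks: dict[str, GenomicIntervalSet]
    tf_gene_map: dict[str, str] = field(default_factory=dict)

    @property
    def tf_names(self) -> list[str]:
        return sorted(self.tracks)

    def __len__(self) -> int:
        return len(self.tracks)

    def union_track(self) -> GenomicIntervalSet:
        """Element union over all TFs, exact-coordinate duplicates collapsed."""
        seen: dict[tuple[str, int, int], GenomicInterval] = {}
        for tf in self.tf_names:
            for iv in self.tracks[tf]:
                seen.setdefault((iv.chrom, iv.start, iv.end), iv)
        return GenomicIntervalSet(seen.values())


@dataclass
class ReferenceData:
    """Everything the pipeline needs besides the query itself."""

    genes: list[GeneModel]
    regdom: RegulatoryDomainMap
    ontology: OntologyGraph
    annotations: AnnotationTable
    chrom_sizes: dict[str, int]
    nongap: GenomicIntervalSet


def build_regulatory_domains(
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_extension: int = 1_000_000,
) -> RegulatoryDomainMap:
    """Assign each gene a regulatory domain by basal-plus-extension.

    Basal domain: [tss - basal_up, tss + basal_down) on the + strand,
    mirrored on the - strand. Each flank extends away from the basal domain
    up to `max_extension` bases but stops at the nearest neighbouring gene's
    basal domain boundary; domains are clipped to the chromosome.
    """
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom!r}")
        if g.tss >= chrom_sizes[g.chrom]:
            raise ValueError(
                f"gene {g.gene_id}: TSS {g.tss} beyond chromosome end "
                f"{chrom_sizes[g.chrom]}"
            )

    def basal(g: GeneModel) -> tuple[int, int]:
        if g.strand == "+":
            s, e = g.tss - basal_up, g.tss + basal_down
        else:
            s, e = g.tss - basal_down, g.tss + basal_up
        return max(0, s), min(chrom_sizes[g.chrom], e)

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    domains: dict[str, GenomicInterval] = {}
    for chrom, gs in by_chrom.items():
        clen = chrom_sizes[chrom]
        basals = {g.gene_id: basal(g) for g in gs}
        for g in gs:
            bs, be = basals[g.gene_id]
            left_stop = 0
            right_stop = clen
            for h in gs:
                if h.gene_id == g.gene_id:
                    continue
                hs, he = basals[h.gene_id]
                # neighbour to the left: its basal starts before ours
                if (hs, he, h.gene_id) < (bs, be, g.gene_id):
                    left_stop = max(left_stop, he)
                else:
                    right_stop = min(right_stop, hs)
            start = max(0, bs - max_extension, min(left_stop, bs))
            end = min(clen, be + max_extension, max(right_stop, be))
            # own basal always retained
            start = min(start, bs)
            end = max(end, be)
            domains[g.gene_id] = GenomicInterval(chrom, start, end, name=g.gene_id)
    return RegulatoryDomainMap(domains)


def propagate_annotations(
    raw: Iterable[tuple[str, str]], graph: OntologyGraph
) -> AnnotationTable:
    """Transitive closure of gene-term pairs over is_a edges, deduplicated."""
    gene_to_terms: dict[str, set[str]] = {}
    for gene, term in raw:
        terms = gene_to_terms.setdefault(gene, set())
        if term in terms:
            continue
        terms.add(term)
        terms.update(graph.ancestors(term))
    term_to_genes: dict[str, set[str]] = {}
    for gene, terms in gene_to_terms.items():
        for t in terms:
            term_to_genes.setdefault(t, set()).add(gene)
    return AnnotationTable(
        gene_to_terms={g: frozenset(ts) for g, ts in gene_to_terms.items()},
        term_to_genes={t: frozenset(gs) for t, gs in term_to_genes.items()},
    )


def term_base_probability(
    term: str,
    regdom: RegulatoryDomainMap,
    annot: AnnotationTable,
    nongap: GenomicIntervalSet,
) -> float:
    """Probability of drawing a non-gap base annotated with `term`.

    p_pi = |union of the term's gene domains, restricted to non-gap bases|
    / |non-gap bases|, under the uniform base distribution.
    """
    genes = annot.term_to_genes.get(term, frozenset())
    if not genes:
        raise ValueError(f"term {term!r} has no annotated genes")
    total = merged_length(nongap)
    if total == 0:
        raise ValueError("non-gap track is empty")
    dom = regdom.union(sorted(genes))
    return merged_length(intersect_portions(dom, nongap)) / total


def _cap_track(
    track: GenomicIntervalSet, per_tf_cap: int
) -> GenomicIntervalSet:
    """Keep the per_tf_cap best-scoring sites; coordinate order breaks ties."""
    ivs = list(track)
    # exact-coordinate duplicates within one track collapse to one element
    uniq: dict[tuple[str, int, int], GenomicInterval] = {}
    for iv in ivs:
        uniq.setdefault((iv.chrom, iv.start, iv.end), iv)
    ivs = list(uniq.values())
    if len(ivs) <= per_tf_cap:
        return GenomicIntervalSet(ivs)
    if all(iv.score is not None for iv in ivs):
        ivs.sort(key=lambda iv: (-iv.score, iv.sort_key()))
        ivs = ivs[:per_tf_cap]
        return GenomicIntervalSet(ivs)
    return GenomicIntervalSet(ivs)


def load_tfbs_library(
    tracks: Mapping[str, str | Path] | str | Path,
    per_tf_cap: int = 5000,
    tf_gene_map: Optional[Mapping[str, str]] = None,
) -> TFBSLibrary:
    """Load per-TF BED tracks, truncating each to its top-scoring sites.

    `tracks` is either a directory of ``<TF>.bed`` files or an explicit
    TF -> path mapping. Tracks over `per_tf_cap` sites that carry scores are
    truncated to the cap's highest-scoring sites (ties broken by coordinate);
    unscored tracks are kept whole.
    """
    if isinstance(tracks, (str, Path)):
        d = Path(tracks)
        mapping = {p.stem: p for p in sorted(d.glob("*.bed"))}
        if not mapping:
            raise ValueError(f"no .bed tracks found in {d}")
    else:
        mapping = {tf: Path(p) for tf, p in tracks.items()}
    loaded: dict[str, GenomicIntervalSet] = {}
    for tf in sorted(mapping):
        try:
            raw = read_bed(mapping[tf])
        except Exception as exc:
            raise ValueError(f"TFBS track for {tf!r} unreadable: {exc}") from exc
        loaded[tf] = _cap_track(raw, per_tf_cap)
    return TFBSLibrary(tracks=loaded, tf_gene_map=dict(tf_gene_map or {}))


# ---------------------------------------------------------------------------
# TSV readers
# ---------------------------------------------------------------------------

def _read_tsv_rows(path: str | Path, n_cols: int) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < n_cols:
                raise ValueError(f"{path}:{ln}: expected {n_cols} columns")
            rows.append(parts[:n_cols])
    return rows


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read (gene_id, chrom, strand, tss) TSV."""
    genes = [
        GeneModel(gid, chrom, strand, int(tss))
        for gid, chrom, strand, tss in _read_tsv_rows(path, 4)
    ]
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene id {g.gene_id!r}")
        seen.add(g.gene_id)
    return genes


def read_annotation_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read (gene_id, term_id) TSV."""
    return [(g, t) for g, t in _read_tsv_rows(path, 2)]


def read_ontology_edges(path: str | Path) -> list[tuple[str, str]]:
    """Read (child_id, parent_id) TSV."""
    return [(c, p) for c, p in _read_tsv_rows(path, 2)]


def read_tf_gene_map(path: str | Path) -> dict[str, str]:
    """Read (tf_name, gene_id) TSV."""
    return {tf: g for tf, g in _read_tsv_rows(path, 2)}
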