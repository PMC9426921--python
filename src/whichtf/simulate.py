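"""Synthetic input bundles with a planted dominant TF.

The generator emulates the statistical structure the ranking method
assumes: a dominant TF's conserved binding sites concentrate inside the
regulatory domains of the genes annotated to functionally coherent
ontology terms, while a high-abundance decoy TF has many sites inside the
accessible regions but is uniform with respect to term domains. Background
TFs scatter uniformly over the genome.

Every file of a bundle (gene models, annotations, ontology edges,
chromosome sizes, assembly gaps, per-TF site tracks, scored query peaks,
TF-to-gene map) is written as plain text and is byte-identical for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .intervals import (
    GenomicInterval,
    GenomicIntervalSet,
    intersect_portions,
    write_bed,
)
from .refdata import GeneModel, build_regulatory_domains

__all__ = ["FixtureSpec", "FixtureBundle", "generate_fixture", "generate_differential_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions of a synthetic study (one planted TF, one decoy).

    `concentration` is the fraction of the planted TF's in-query sites that
    are placed inside (query ∩ planted-term domains); at 0 the planted TF
    loses its functional coherence and becomes indistinguishable from an
    ordinary in-query TF.
    """

    n_chroms: int = 1
    chrom_length: int = 1_000_000
    n_genes: int = 60
    n_leaf_terms: int = 9
    n_root_terms: int = 3
    genes_per_term: int = 5
    n_tfs: int = 20
    sites_per_tf: int = 300
    site_length: int = 10
    n_peaks: int = 400
    peak_length: int = 300
    peak_term_fraction: float = 0.4  # peaks placed inside planted-term domains
    planted_term_index: int = 0  # which leaf term carries the signal
    planted_tf: str = "TF_planted"
    decoy_tf: str = "TF_decoy"
    concentration: float = 0.8
    planted_in_query_fraction: float = 0.6
    decoy_in_query_fraction: float = 0.85
    decoy_abundance_multiplier: float = 2.0
    gap_length: int = 5000
    seed: int = 7

    def __post_init__(self) -> None:
        if not (0.0 <= self.concentration <= 1.0):
            raise ValueError("concentration must be in [0, 1]")
        if self.decoy_abundance_multiplier < 1.0:
            raise ValueError("decoy abundance must be >= planted abundance")
        if self.n_leaf_terms * self.genes_per_term > self.n_genes:
            raise ValueError("not enough genes to fill the leaf terms")
        if self.n_tfs < 3:
            raise ValueError("need at least planted, decoy and one background TF")
        if not (0 <= self.planted_term_index < self.n_leaf_terms):
            raise ValueError("planted_term_index out of range")


@dataclass
class FixtureBundle:
    """Paths of one generated input bundle."""

    root: Path
    query: Path
    tfbs_dir: Path
    genes: Path
    annotations: Path
    ontology: Path
    chrom_sizes: Path
    gaps: Path
    tf_gene_map: Path
    planted_tf: str
    decoy_tf: str
    planted_term: str


def _leaf_name(i: int) -> str:
    return f"T{i + 1:02d}"


def _root_name(i: int) -> str:
    return f"R{i + 1:02d}"


def _make_genes(spec: FixtureSpec, rng: np.random.Generator) -> list[GeneModel]:
    genes = []
    per_chrom = spec.n_genes // spec.n_chroms
    extra = spec.n_genes - per_chrom * spec.n_chroms
    idx = 0
    for c in range(spec.n_chroms):
        n_here = per_chrom + (1 if c < extra else 0)
        spacing = spec.chrom_length // (n_here + 1)
        for g in range(n_here):
            jitter = int(rng.integers(-spacing // 4, spacing // 4 + 1))
            tss = (g + 1) * spacing + jitter
            tss = min(max(tss, 6000), spec.chrom_length - 6000)
            strand = "+" if idx % 2 == 0 else "-"
            genes.append(GeneModel(f"G{idx + 1:03d}", f"chr{c + 1}", strand, tss))
            idx += 1
    return genes


def _sample_within(
    regions: GenomicIntervalSet,
    n: int,
    length: int,
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    """Uniform starts of `n` length-`length` windows fully inside `regions`."""
    segs = [iv for iv in regions.merged() if iv.length >= length]
    if n > 0 and not segs:
        raise ValueError(
            "infeasible placement: no target segment can hold a "
            f"{length} bp element"
        )
    if n == 0:
        return []
    weights = np.array([iv.length - length + 1 for iv in segs], dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(segs), size=n, p=weights)
    out = []
    for i in picks:
        seg = segs[int(i)]
        off = int(rng.integers(0, seg.length - length + 1))
        out.append((seg.chrom, seg.start + off))
    return out


def _uniform_genome_region(spec: FixtureSpec) -> GenomicIntervalSet:
    """Placement region for 'uniform' elements: away from chromosome edges
    (by one site length) and from the terminal assembly gap."""
    margin = spec.site_length
    ivs = []
    for c in range(spec.n_chroms):
        hi = spec.chrom_length - spec.gap_length - margin
        ivs.append(GenomicInterval(f"chr{c + 1}", margin, hi))
    return GenomicIntervalSet(ivs)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _write_tsv(path: Path, rows: list[tuple]) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _build_refs(spec: FixtureSpec, rng: np.random.Generator):
    """Genes, ontology, annotations and planted-term domain (in memory)."""
    genes = _make_genes(spec, rng)
    chrom_sizes = {f"chr{c + 1}": spec.chrom_length for c in range(spec.n_chroms)}
    edges = [
        (_leaf_name(k), _root_name(k % spec.n_root_terms))
        for k in range(spec.n_leaf_terms)
    ]
    annotations = []
    for k in range(spec.n_leaf_terms):
        block = genes[k * spec.genes_per_term : (k + 1) * spec.genes_per_term]
        annotations.extend((g.gene_id, _leaf_name(k)) for g in block)
    regdom = build_regulatory_domains(genes, chrom_sizes)
    return genes, chrom_sizes, edges, annotations, regdom


def _term_domain(spec: FixtureSpec, genes, regdom, leaf_index: int) -> GenomicIntervalSet:
    block = genes[
        leaf_index * spec.genes_per_term : (leaf_index + 1) * spec.genes_per_term
    ]
    return regdom.union([g.gene_id for g in block])


def _place_query(
    spec: FixtureSpec,
    planted_domain: GenomicIntervalSet,
    rng: np.random.Generator,
    n_peaks: Optional[int] = None,
    start_index: int = 0,
    term_fraction: Optional[float] = None,
) -> list[GenomicInterval]:
    n_peaks = spec.n_peaks if n_peaks is None else n_peaks
    frac = spec.peak_term_fraction if term_fraction is None else term_fraction
    n_term = _round_half_up(frac * n_peaks)
    genome = _uniform_genome_region(spec)
    target = intersect_portions(planted_domain, genome)
    placements = _sample_within(target, n_term, spec.peak_length, rng)
    placements += _sample_within(genome, n_peaks - n_term, spec.peak_length, rng)
    peaks = []
    for i, (chrom, start) in enumerate(placements):
        score = float(np.round(rng.uniform(100.0, 1000.0), 3))
        peaks.append(
            GenomicInterval(
                chrom,
                start,
                start + spec.peak_length,
                name=f"peak{start_index + i + 1:05d}",
                score=score,
            )
        )
    return peaks


def _build_track(
    spec: FixtureSpec,
    tf: str,
    placements: list[tuple[str, int]],
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    sites = []
    for i, (chrom, start) in enumerate(placements):
        score = float(np.round(rng.uniform(0.0, 1.0), 4))
        sites.append(
            GenomicInterval(
                chrom,
                start,
                start + spec.site_length,
                name=f"{tf}_site{i + 1:05d}",
                score=score,
            )
        )
    return sites


def _place_planted_tf(
    spec: FixtureSpec,
    tf: str,
    query_set: GenomicIntervalSet,
    planted_domain: GenomicIntervalSet,
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """In-query sites split between term-concentrated and anywhere-in-query."""
    genome = _uniform_genome_region(spec)
    query_target = intersect_portions(query_set, genome)
    conc_target = intersect_portions(query_target, planted_domain)
    n_in_query = _round_half_up(spec.planted_in_query_fraction * spec.sites_per_tf)
    n_conc = _round_half_up(spec.concentration * n_in_query)
    placements = _sample_within(conc_target, n_conc, spec.site_length, rng)
    placements += _sample_within(
        query_target, n_in_query - n_conc, spec.site_length, rng
    )
    placements += _sample_within(
        genome, spec.sites_per_tf - n_in_query, spec.site_length, rng
    )
    return _build_track(spec, tf, placements, rng)


def _place_decoy_tf(
    spec: FixtureSpec,
    query_set: GenomicIntervalSet,
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """Abundant and query-seeking, but agnostic to term domains."""
    genome = _uniform_genome_region(spec)
    query_target = intersect_portions(query_set, genome)
    n_decoy = _round_half_up(spec.decoy_abundance_multiplier * spec.sites_per_tf)
    n_in_query = _round_half_up(spec.decoy_in_query_fraction * n_decoy)
    placements = _sample_within(query_target, n_in_query, spec.site_length, rng)
    placements += _sample_within(genome, n_decoy - n_in_query, spec.site_length, rng)
    return _build_track(spec, spec.decoy_tf, placements, rng)


def _place_background_tfs(
    spec: FixtureSpec, rng: np.random.Generator
) -> dict[str, list[GenomicInterval]]:
    """Uniform over the genome."""
    genome = _uniform_genome_region(spec)
    tracks = {}
    for b in range(spec.n_tfs - 2):
        tf = f"TF_bg{b + 1:02d}"
        placements = _sample_within(genome, spec.sites_per_tf, spec.site_length, rng)
        tracks[tf] = _build_track(spec, tf, placements, rng)
    return tracks


def _place_tf_sites(
    spec: FixtureSpec,
    query_set: GenomicIntervalSet,
    planted_domain: GenomicIntervalSet,
    rng: np.random.Generator,
) -> dict[str, list[GenomicInterval]]:
    tracks = {
        spec.planted_tf: _place_planted_tf(
            spec, spec.planted_tf, query_set, planted_domain, rng
        )
    }
    tracks[spec.decoy_tf] = _place_decoy_tf(spec, query_set, rng)
    tracks.update(_place_background_tfs(spec, rng))
    return tracks


def _write_bundle(
    out_dir: Path,
    spec: FixtureSpec,
    genes,
    chrom_sizes,
    edges,
    annotations,
    query: list[GenomicInterval],
    tracks: dict[str, list[GenomicInterval]],
    tf_gene_map: dict[str, str],
    query_filename: str = "query.bed",
) -> FixtureBundle:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tfbs_dir = out_dir / "tfbs"
    tfbs_dir.mkdir(exist_ok=True)

    paths = FixtureBundle(
        root=out_dir,
        query=out_dir / query_filename,
        tfbs_dir=tfbs_dir,
        genes=out_dir / "genes.tsv",
        annotations=out_dir / "annotations.tsv",
        ontology=out_dir / "ontology.tsv",
        chrom_sizes=out_dir / "chrom.sizes",
        gaps=out_dir / "gaps.bed",
        tf_gene_map=out_dir / "tf_gene_map.tsv",
        planted_tf=spec.planted_tf,
        decoy_tf=spec.decoy_tf,
        planted_term=_leaf_name(spec.planted_term_index),
    )
    _write_tsv(paths.genes, [(g.gene_id, g.chrom, g.strand, g.tss) for g in genes])
    _write_tsv(paths.annotations, sorted(annotations))
    _write_tsv(paths.ontology, edges)
    _write_tsv(paths.chrom_sizes, sorted(chrom_sizes.items()))
    gaps = GenomicIntervalSet(
        GenomicInterval(c, ln - spec.gap_length, ln)
        for c, ln in sorted(chrom_sizes.items())
    )
    write_bed(gaps, paths.gaps)
    write_bed(GenomicIntervalSet(query), paths.query)
    for tf in sorted(tracks):
        write_bed(GenomicIntervalSet(tracks[tf]), tfbs_dir / f"{tf}.bed")
    _write_tsv(paths.tf_gene_map, sorted(tf_gene_map.items()))
    return paths


def _make_tf_gene_map(spec: FixtureSpec, genes, tracks) -> dict[str, str]:
    planted_gene = genes[spec.planted_term_index * spec.genes_per_term].gene_id
    # decoy maps to a gene outside every term (so its closed loop is false)
    unannotated = genes[spec.n_leaf_terms * spec.genes_per_term :]
    decoy_gene = (unannotated[0] if unannotated else genes[-1]).gene_id
    mapping = {spec.planted_tf: planted_gene, spec.decoy_tf: decoy_gene}
    bg = [tf for tf in sorted(tracks) if tf not in mapping]
    for i, tf in enumerate(bg):
        mapping[tf] = genes[i % len(genes)].gene_id
    return mapping


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixtureBundle:
    """Write one complete input bundle under `out_dir`.

    Raises ``ValueError`` for infeasible specs (for example a planted-term
    domain with no segment long enough to hold a site).
    """
    rng = np.random.default_rng(spec.seed)
    genes, chrom_sizes, edges, annotations, regdom = _build_refs(spec, rng)
    planted_domain = _term_domain(spec, genes, regdom, spec.planted_term_index)
    query = _place_query(spec, planted_domain, rng)
    query_set = GenomicIntervalSet(query)
    tracks = _place_tf_sites(spec, query_set, planted_domain, rng)
    tf_gene_map = _make_tf_gene_map(spec, genes, tracks)
    return _write_bundle(
        Path(out_dir), spec, genes, chrom_sizes, edges, annotations,
        query, tracks, tf_gene_map,
    )


def generate_differential_fixture(
    spec_a: FixtureSpec, spec_b: FixtureSpec, out_dir: str | Path
) -> tuple[FixtureBundle, FixtureBundle]:
    """Two query bundles sharing all reference data.

    The queries share a common core of peaks; each side adds unique peaks
    inside its own planted term's domain, with its planted TF's sites
    concentrated there. Direction-specific TFs are therefore recoverable
    only from their own direction's differential regions.
    """
    for attr in (
        "n_chroms", "chrom_length", "n_genes", "n_leaf_terms", "n_root_terms",
        "genes_per_term", "sites_per_tf", "site_length", "seed",
    ):
        if getattr(spec_a, attr) != getattr(spec_b, attr):
            raise ValueError(f"differential specs must share {attr}")
    if spec_a.planted_term_index == spec_b.planted_term_index:
        raise ValueError("the two directions must plant different terms")
    if spec_a.planted_tf == spec_b.planted_tf:
        raise ValueError("the two directions must plant different TFs")

    rng = np.random.default_rng(spec_a.seed)
    genes, chrom_sizes, edges, annotations, regdom = _build_refs(spec_a, rng)
    dom_a = _term_domain(spec_a, genes, regdom, spec_a.planted_term_index)
    dom_b = _term_domain(spec_b, genes, regdom, spec_b.planted_term_index)

    n_unique = _round_half_up(spec_a.peak_term_fraction * spec_a.n_peaks)
    n_core = spec_a.n_peaks - n_unique
    core = _place_query(
        spec_a, dom_a, rng, n_peaks=n_core, term_fraction=0.0
    )
    uniq_a = _place_query(
        spec_a, dom_a, rng, n_peaks=n_unique, start_index=n_core,
        term_fraction=1.0,
    )
    uniq_b = _place_query(
        spec_b, dom_b, rng, n_peaks=n_unique, start_index=n_core + n_unique,
        term_fraction=1.0,
    )
    query_a = core + uniq_a
    query_b = core + uniq_b

    # per-side planted TFs concentrate in their own unique regions; the
    # decoy seeks both queries; backgrounds are uniform
    tracks = {
        spec_a.planted_tf: _place_planted_tf(
            spec_a, spec_a.planted_tf, GenomicIntervalSet(uniq_a), dom_a, rng
        ),
        spec_b.planted_tf: _place_planted_tf(
            spec_b, spec_b.planted_tf, GenomicIntervalSet(uniq_b), dom_b, rng
        ),
        spec_a.decoy_tf: _place_decoy_tf(
            spec_a, GenomicIntervalSet(query_a + uniq_b), rng
        ),
    }
    tracks.update(_place_background_tfs(spec_a, rng))

    tf_gene_map = _make_tf_gene_map(spec_a, genes, tracks)
    tf_gene_map[spec_b.planted_tf] = genes[
        spec_b.planted_term_index * spec_b.genes_per_term
    ].gene_id

    out_dir = Path(out_dir)
    bundle_a = _write_bundle(
        out_dir, spec_a, genes, chrom_sizes, edges, annotations,
        query_a, tracks, tf_gene_map, query_filename="query_a.bed",
    )
    bundle_b = _write_bundle(
        out_dir, spec_b, genes, chrom_sizes, edges, annotations,
        query_b, tracks, tf_gene_map, query_filename="query_b.bed",
    )
    return bundle_a, bundle_b
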