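"""Run configuration, reference loading, the single-run pipeline, the
robustness grid, and TSV report writers.

All randomness in a run flows from ``RunConfig.seed``. Reports carry the
full resolved parameter set in a header block for provenance, and the main
report TSV parses back losslessly (full-precision machine columns are kept
alongside the display columns).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .baseline import BaselineRanking, prism_enrichment_ranking
from .intervals import (
    GenomicInterval,
    GenomicIntervalSet,
    read_bed,
    read_chrom_sizes,
    subsample_by_score,
    subtract_portions,
    trim_to_midpoint,
)
from .ranker import TFRanking, rank_tfs
from .refdata import (
    OntologyGraph,
    ReferenceData,
    TFBSLibrary,
    build_regulatory_domains,
    load_tfbs_library,
    propagate_annotations,
    read_annotation_pairs,
    read_gene_models,
    read_ontology_edges,
    read_tf_gene_map,
)
from .termselect import select_top_terms

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "load_reference",
    "load_library",
    "run_single",
    "run_robustness",
    "write_ranking_report",
    "write_term_report",
    "read_ranking_report",
]


@dataclass
class RunConfig:
    """Paths and parameters of one run; see the class fields for defaults."""

    query: Path
    tfbs_dir: Path
    genes: Path
    annotations: Path
    ontology: Path
    chrom_sizes: Path
    gaps: Optional[Path] = None
    tf_gene_map: Optional[Path] = None
    out_dir: Optional[Path] = None
    top_terms: int = 100  # K
    adaptive_top_m: int = 10
    min_term_genes: int = 2
    max_term_genes: int = 500
    per_tf_cap: int = 5000
    basal_up: int = 5000
    basal_down: int = 1000
    max_extension: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("query", "tfbs_dir", "genes", "annotations", "ontology",
                     "chrom_sizes", "gaps", "tf_gene_map"):
            p = getattr(self, name)
            if p is not None:
                p = Path(p)
                setattr(self, name, p)
                if not p.exists():
                    raise FileNotFoundError(f"{name}: no such path: {p}")
        if self.out_dir is not None:
            self.out_dir = Path(self.out_dir)
        if self.top_terms < 1 or self.adaptive_top_m < 1:
            raise ValueError("top_terms and adaptive_top_m must be >= 1")
        if not (1 <= self.min_term_genes <= self.max_term_genes):
            raise ValueError("require 1 <= min_term_genes <= max_term_genes")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def resolved(self) -> dict:
        out = {}
        for k, v in asdict(self).items():
            out[k] = str(v) if isinstance(v, Path) else v
        return out


def load_reference(config: RunConfig) -> ReferenceData:
    """Load gene models, ontology and annotations; build domains and caches."""
    genes = read_gene_models(config.genes)
    chrom_sizes = read_chrom_sizes(config.chrom_sizes)
    graph = OntologyGraph(read_ontology_edges(config.ontology))
    annot = propagate_annotations(read_annotation_pairs(config.annotations), graph)
    regdom = build_regulatory_domains(
        genes,
        chrom_sizes,
        basal_up=config.basal_up,
        basal_down=config.basal_down,
        max_extension=config.max_extension,
    )
    full = GenomicIntervalSet(
        GenomicInterval(c, 0, ln) for c, ln in chrom_sizes.items()
    )
    if config.gaps is not None:
        nongap = subtract_portions(full, read_bed(config.gaps))
    else:
        nongap = full  # no gap track: whole chromosomes count as non-gap
    annot.attach_domains(regdom, nongap)
    logger.info(
        "reference: %d genes, %d terms, %d annotated genes",
        len(genes),
        len(annot.terms),
        len(annot.annotated_genes),
    )
    return ReferenceData(
        genes=genes,
        regdom=regdom,
        ontology=graph,
        annotations=annot,
        chrom_sizes=chrom_sizes,
        nongap=nongap,
    )


def load_library(config: RunConfig) -> TFBSLibrary:
    tf_gene_map = (
        read_tf_gene_map(config.tf_gene_map) if config.tf_gene_map else None
    )
    lib = load_tfbs_library(
        config.tfbs_dir, per_tf_cap=config.per_tf_cap, tf_gene_map=tf_gene_map
    )
    logger.info(
        "TFBS library: %d TFs, %d sites total",
        len(lib),
        sum(len(t) for t in lib.tracks.values()),
    )
    return lib


def run_single(
    config: RunConfig,
    refs: Optional[ReferenceData] = None,
    tfbs_lib: Optional[TFBSLibrary] = None,
    query: Optional[GenomicIntervalSet] = None,
) -> TFRanking:
    """Full single-mode run: term selection then TF ranking.

    Preloaded reference data / library / query may be passed to avoid
    re-reading files across a grid of runs. Writes reports when
    ``config.out_dir`` is set.
    """
    refs = refs if refs is not None else load_reference(config)
    tfbs_lib = tfbs_lib if tfbs_lib is not None else load_library(config)
    query = query if query is not None else read_bed(config.query)
    query.validate_against_sizes(refs.chrom_sizes)
    logger.info("query: %d elements", len(query))
    selection = select_top_terms(
        query,
        tfbs_lib,
        refs,
        K=config.top_terms,
        min_genes=config.min_term_genes,
        max_genes=config.max_term_genes,
    )
    logger.info("terms kept: %d", len(selection))
    ranking = rank_tfs(
        query, tfbs_lib, selection, refs, top_m=config.adaptive_top_m
    )
    if config.out_dir is not None:
        config.out_dir.mkdir(parents=True, exist_ok=True)
        write_ranking_report(
            ranking, config.out_dir / "whichtf_report.tsv", config
        )
        write_term_report(ranking, config.out_dir / "term_report.tsv")
    return ranking


def run_robustness(
    config: RunConfig,
    fractions: Sequence[float] = (),
    max_lens: Sequence[Optional[int]] = (),
    Ks: Sequence[int] = (),
    refs: Optional[ReferenceData] = None,
    tfbs_lib: Optional[TFBSLibrary] = None,
) -> pd.DataFrame:
    """Vary one input-perturbation axis at a time; tabulate top-5 TFs.

    Axes: query subsampling by SCORE at each fraction, midpoint-preserving
    trimming at each maximum length (None = untrimmed), and the number of
    selected top terms K. Empty grids reduce to the base run only.
    """
    refs = refs if refs is not None else load_reference(config)
    tfbs_lib = tfbs_lib if tfbs_lib is not None else load_library(config)
    base_query = read_bed(config.query)
    quiet = replace(config, out_dir=None)

    rows = []

    def record(condition: str, value, query: GenomicIntervalSet, K: int):
        cfg = replace(quiet, top_terms=K)
        ranking = run_single(cfg, refs=refs, tfbs_lib=tfbs_lib, query=query)
        top5 = ranking.tf_order[:5]
        rows.append(
            {
                "condition": condition,
                "value": value,
                "K": K,
                **{f"rank{i + 1}": tf for i, tf in enumerate(top5)},
            }
        )

    record("base", "-", base_query, config.top_terms)
    for f in fractions:
        q = subsample_by_score(base_query, f, seed=config.seed)
        record("subsample_fraction", f, q, config.top_terms)
    for L in max_lens:
        q = base_query if L is None else trim_to_midpoint(base_query, L)
        record("trim_max_len", "none" if L is None else L, q, config.top_terms)
    for K in Ks:
        record("top_terms", K, base_query, K)

    table = pd.DataFrame(rows)
    if config.out_dir is not None:
        config.out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(config.out_dir / "robustness.tsv", sep="\t", index=False)
    return table


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _loop_str(flag: Optional[bool]) -> str:
    return "unavailable" if flag is None else ("yes" if flag else "no")


def write_ranking_report(
    ranking: TFRanking, path: str | Path, config: Optional[RunConfig] = None
) -> None:
    """Main report: rank, TF, score, -log10 conditional p, driving terms.

    The display column rounds -log10(CP) to one decimal; `cond_p_exact`
    keeps the exact rational for machine reading.
    """
    with open(path, "w") as fh:
        if config is not None:
            for k, v in sorted(config.resolved().items()):
                fh.write(f"# {k}: {v}\n")
        fh.write(
            "rank\ttf\twhichtf_score\tneg_log10_cond_p\tcond_p_exact\t"
            "score_exact\ttop_terms\tclosed_loop\n"
        )
        for row in ranking.rows:
            terms = ";".join(
                f"{t}:{float(p):.6g}" for t, p in row.top_terms
            )
            loops = ";".join(_loop_str(f) for f in row.closed_loop)
            fh.write(
                f"{row.rank}\t{row.tf}\t{row.score_float:.6g}\t"
                f"{row.neglog10_cond_p:.1f}\t"
                f"{row.cond_p.numerator}/{row.cond_p.denominator}\t"
                f"{row.score.numerator}/{row.score.denominator}\t"
                f"{terms or '-'}\t{loops or '-'}\n"
            )


def read_ranking_report(path: str | Path) -> pd.DataFrame:
    """Parse a ranking report back; exact columns become Fractions."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df["cond_p"] = df["cond_p_exact"].map(Fraction)
    df["score"] = df["score_exact"].map(Fraction)
    return df


def write_term_report(ranking: TFRanking, path: str | Path) -> None:
    """Per-term diagnostics of the selection stage."""
    with open(path, "w") as fh:
        fh.write(
            "term_rank\tterm_id\tbinom_p\thyper_p\tn_genes_term\t"
            "n_genes_hit\tregion_hits\tp_pi\n"
        )
        for j, te in enumerate(ranking.selection.terms, start=1):
            fh.write(
                f"{j}\t{te.term_id}\t{te.binom_p:.6g}\t{te.hyper_p:.6g}\t"
                f"{te.n_genes_term}\t{te.n_genes_hit}\t{te.region_hits}\t"
                f"{te.p_pi:.6g}\n"
            )


def write_score_vector(
    rankings: dict[str, TFRanking], path: str | Path
) -> None:
    """TF x sample matrix of scores, for downstream embedding by other tools."""
    tfs = sorted({tf for r in rankings.values() for tf in r.tf_order})
    with open(path, "w") as fh:
        fh.write("tf\t" + "\t".join(sorted(rankings)) + "\n")
        for tf in tfs:
            vals = []
            for s in sorted(rankings):
                try:
                    vals.append(f"{rankings[s].row_for(tf).score_float:.6g}")
                except KeyError:
                    vals.append("0")
            fh.write(tf + "\t" + "\t".join(vals) + "\n")
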