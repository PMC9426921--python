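"""Regulatory domains, annotation propagation, p_pi, and library loading."""

import numpy as np
import pytest

from whichtf.intervals import GenomicInterval, GenomicIntervalSet, write_bed
from whichtf.refdata import (
    GeneModel,
    OntologyGraph,
    build_regulatory_domains,
    load_tfbs_library,
    propagate_annotations,
    term_base_probability,
)

CHROM = {"chr1": 1_000_000}


class TestRegulatoryDomains:
    def test_single_gene_extends_full_megabase(self):
        genes = [GeneModel("g", "chr1", "+", 100_000)]
        dom = build_regulatory_domains(genes, CHROM)["g"]
        assert (dom.start, dom.end) == (0, 1_000_000)

    def test_two_genes_stop_at_neighbour_basal(self):
        genes = [
            GeneModel("A", "chr1", "+", 100_000),
            GeneModel("B", "chr1", "+", 200_000),
        ]
        doms = build_regulatory_domains(genes, CHROM)
        assert (doms["A"].start, doms["A"].end) == (0, 195_000)
        assert (doms["B"].start, doms["B"].end) == (101_000, 1_000_000)

    def test_basal_clipped_at_chromosome_start(self):
        genes = [
            GeneModel("near", "chr1", "+", 3_000),
            GeneModel("blocker", "chr1", "+", 9_000),  # basal [4000, 10000)
        ]
        doms = build_regulatory_domains(genes, CHROM, max_extension=0)
        assert (doms["near"].start, doms["near"].end) == (0, 4_000)

    def test_minus_strand_mirrored_basal(self):
        genes = [GeneModel("m", "chr1", "-", 100_000)]
        dom = build_regulatory_domains(genes, CHROM, max_extension=0)["m"]
        assert (dom.start, dom.end) == (99_000, 105_000)

    def test_domain_contains_basal_even_with_overlapping_neighbour(self, rng):
        tsss = sorted(int(t) for t in rng.integers(10_000, 990_000, 30))
        genes = [
            GeneModel(f"g{i}", "chr1", "+-"[i % 2], t) for i, t in enumerate(tsss)
        ]
        doms = build_regulatory_domains(genes, CHROM)
        for g in genes:
            bs = g.tss - (5000 if g.strand == "+" else 1000)
            be = g.tss + (1000 if g.strand == "+" else 5000)
            d = doms[g.gene_id]
            assert d.start <= max(0, bs) and d.end >= min(1_000_000, be)
            assert 0 <= d.start < d.end <= 1_000_000

    def test_gene_beyond_chromosome_raises(self):
        with pytest.raises(ValueError, match="beyond"):
            build_regulatory_domains(
                [GeneModel("x", "chr1", "+", 2_000_000)], CHROM
            )


class TestPropagation:
    def test_leaf_to_root(self):
        graph = OntologyGraph([("t", "r")])
        table = propagate_annotations([("g", "t")], graph)
        assert table.gene_to_terms["g"] == {"t", "r"}

    def test_no_edges_identity(self):
        graph = OntologyGraph([], terms=["t1", "t2"])
        table = propagate_annotations([("g", "t1")], graph)
        assert table.gene_to_terms["g"] == {"t1"}

    def test_random_dag_matches_bfs_closure(self, rng):
        # 30 terms, random forward edges (i -> j only when i < j: acyclic)
        n = 30
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.1:
                    edges.append((f"T{i}", f"T{j}"))
        graph = OntologyGraph(edges, terms=[f"T{i}" for i in range(n)])
        pairs = [("g1", f"T{int(i)}") for i in rng.integers(0, n, 5)]
        table = propagate_annotations(pairs, graph)

        adj = {}
        for c, p in edges:
            adj.setdefault(c, set()).add(p)
        want = set()
        frontier = [t for _, t in pairs]
        while frontier:
            t = frontier.pop()
            if t in want:
                continue
            want.add(t)
            frontier.extend(adj.get(t, ()))
        assert table.gene_to_terms["g1"] == want

    def test_propagation_idempotent(self):
        graph = OntologyGraph([("a", "b"), ("b", "c")])
        once = propagate_annotations([("g", "a")], graph)
        pairs_again = [
            (g, t) for g, ts in once.gene_to_terms.items() for t in sorted(ts)
        ]
        twice = propagate_annotations(pairs_again, graph)
        assert once.gene_to_terms == twice.gene_to_terms

    def test_cycle_raises_with_witness(self):
        with pytest.raises(ValueError, match="cycle"):
            OntologyGraph([("a", "b"), ("b", "a")])


class TestTermBaseProbability:
    def build(self, domains, pairs, nongap):
        graph = OntologyGraph([], terms=sorted({t for _, t in pairs}))
        table = propagate_annotations(pairs, graph)
        from whichtf.refdata import RegulatoryDomainMap

        regdom = RegulatoryDomainMap(
            {g: GenomicInterval("chr1", s, e) for g, (s, e) in domains.items()}
        )
        return regdom, table, nongap

    def test_fraction_of_nongap(self):
        regdom, table, nongap = self.build(
            {"g": (0, 1000)},
            [("g", "t")],
            GenomicIntervalSet([GenomicInterval("chr1", 0, 10_000)]),
        )
        assert term_base_probability("t", regdom, table, nongap) == 0.1

    def test_full_coverage_is_one(self):
        regdom, table, nongap = self.build(
            {"g": (0, 10_000)},
            [("g", "t")],
            GenomicIntervalSet([GenomicInterval("chr1", 0, 10_000)]),
        )
        assert term_base_probability("t", regdom, table, nongap) == 1.0

    def test_bitvector_oracle(self, rng):
        G = 10_000
        domains = {}
        pairs = []
        for i in range(6):
            s = int(rng.integers(0, G - 500))
            domains[f"g{i}"] = (s, s + int(rng.integers(100, 500)))
            pairs.append((f"g{i}", "t" if i < 4 else "u"))
        gap_s = int(rng.integers(0, G - 1000))
        nongap = GenomicIntervalSet(
            [GenomicInterval("chr1", 0, gap_s), GenomicInterval("chr1", gap_s + 1000, G)]
        ) if gap_s + 1000 < G else GenomicIntervalSet([GenomicInterval("chr1", 0, gap_s)])
        regdom, table, nongap = self.build(domains, pairs, nongap)

        vec_ng = np.zeros(G, dtype=bool)
        for iv in nongap:
            vec_ng[iv.start : iv.end] = True
        vec_t = np.zeros(G, dtype=bool)
        for g, (s, e) in domains.items():
            if ("t" in table.gene_to_terms[g]):
                vec_t[s:e] = True
        want = (vec_t & vec_ng).sum() / vec_ng.sum()
        assert term_base_probability("t", regdom, table, nongap) == pytest.approx(want)

    def test_monotone_in_gene_set(self):
        nongap = GenomicIntervalSet([GenomicInterval("chr1", 0, 10_000)])
        small = self.build({"g1": (0, 1000)}, [("g1", "t")], nongap)
        big = self.build(
            {"g1": (0, 1000), "g2": (5000, 6000)},
            [("g1", "t"), ("g2", "t")],
            nongap,
        )
        assert term_base_probability("t", *big) >= term_base_probability("t", *small)

    def test_empty_nongap_raises(self):
        regdom, table, _ = self.build(
            {"g": (0, 1000)}, [("g", "t")], GenomicIntervalSet()
        )
        with pytest.raises(ValueError, match="non-gap"):
            term_base_probability("t", regdom, table, GenomicIntervalSet())


class TestTFBSLibrary:
    def write_track(self, path, n, scores=True):
        ivs = [
            GenomicInterval(
                "chr1", 10 * i, 10 * i + 8, f"s{i}", float(i % 100) if scores else None
            )
            for i in range(n)
        ]
        write_bed(GenomicIntervalSet(ivs), path)

    def test_under_cap_kept_whole(self, tmp_path):
        self.write_track(tmp_path / "TFA.bed", 100)
        lib = load_tfbs_library(tmp_path, per_tf_cap=5000)
        assert len(lib.tracks["TFA"]) == 100

    def test_cap_keeps_best_scores(self, tmp_path):
        self.write_track(tmp_path / "TFA.bed", 600)
        lib = load_tfbs_library(tmp_path, per_tf_cap=500)
        kept = lib.tracks["TFA"]
        assert len(kept) == 500
        # 600 sites score i%100: scores 0..99 each appear 6x; the 100 lowest
        # -scoring sites dropped means no score < 17 fully retained
        assert min(iv.score for iv in kept) >= 16

    def test_tie_truncation_deterministic(self, tmp_path):
        self.write_track(tmp_path / "TFA.bed", 600)
        a = load_tfbs_library(tmp_path, per_tf_cap=500).tracks["TFA"]
        b = load_tfbs_library(tmp_path, per_tf_cap=500).tracks["TFA"]
        assert a == b

    def test_unreadable_track_names_tf(self, tmp_path):
        (tmp_path / "BAD.bed").write_text("chr1\tnot_an_int\t5\n")
        with pytest.raises(ValueError, match="BAD"):
            load_tfbs_library(tmp_path)

    def test_union_track_dedupes_exact_coordinates(self, tmp_path):
        self.write_track(tmp_path / "TFA.bed", 10)
        self.write_track(tmp_path / "TFB.bed", 10)  # identical coordinates
        lib = load_tfbs_library(tmp_path)
        assert len(lib.union_track()) == 10
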