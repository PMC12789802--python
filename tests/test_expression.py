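"""Closest-gene assignment, FPKM, NB Wald test, six-category hierarchy."""

import math

import numpy as np
import pandas as pd
import pytest

from imprintscan.expression import (CATEGORIES, assign_closest_genes,
                                    classify_expression_categories,
                                    differential_expression, expression_flags,
                                    fpkm, gene_category_enrichment, size_factors)
from imprintscan.io import GeneModel
from imprintscan.stats import hypergeometric_tail


def gene(gene_id, start, end, strand="+", chrom="chr1", coding=True):
    return GeneModel(gene_id, chrom, strand, start, end, (start,), (end,),
                     coding=coding, cds_start=start + 10 if coding else None,
                     cds_end=end - 10 if coding else None)


class TestClosestGene:
    def cpg(self, pos, chrom="chr1"):
        return pd.DataFrame({"chrom": [chrom], "pos": [pos]}, index=["c"])

    def test_intragenic_host(self):
        genes = [gene("host", 500, 2_000), gene("far", 10_000, 12_000)]
        out = assign_closest_genes(self.cpg(1_000), genes)
        assert out.loc["c", "gene"] == "host"
        assert out.loc["c", "relation"] == "intragenic-host"
        assert out.loc["c", "distance"] == 0

    def test_strand_aware_nearest_tss(self):
        # minus-strand gene ending at 800 has TSS 799 (distance 201),
        # plus-strand gene with TSS 1300 is farther (distance 300)
        genes = [gene("plus", 1_300, 2_000, "+"), gene("minus", 200, 800, "-")]
        out = assign_closest_genes(self.cpg(1_000), genes)
        assert out.loc["c", "gene"] == "minus"
        assert out.loc["c", "relation"] == "intergenic-nearest-TSS"
        assert out.loc["c", "distance"] == 201

    def test_noncoding_genes_ignored(self):
        genes = [gene("nc", 900, 1_100, coding=False), gene("pc", 5_000, 6_000)]
        out = assign_closest_genes(self.cpg(1_000), genes)
        assert out.loc["c", "gene"] == "pc"

    def test_contig_without_genes_unassigned(self):
        out = assign_closest_genes(self.cpg(1_000, chrom="chrZ"),
                                   [gene("g", 0, 100)])
        assert out.loc["c", "relation"] == "unassigned"

    def test_overlapping_hosts_match_brute_force(self, rng):
        genes = [gene(f"g{i}", int(s), int(s + rng.integers(500, 3_000)),
                      "+" if rng.random() < 0.5 else "-")
                 for i, s in enumerate(rng.integers(0, 20_000, size=40))]
        positions = rng.integers(0, 25_000, size=200)
        cpgs = pd.DataFrame({"chrom": "chr1", "pos": positions},
                            index=[f"c{i}" for i in range(200)])
        out = assign_closest_genes(cpgs, genes)
        for probe_id, pos in zip(cpgs.index, positions):
            hosts = [g for g in genes if g.start <= pos < g.end]
            pool = hosts if hosts else genes
            best = min(pool, key=lambda g: (abs(g.tss - pos), g.gene_id))
            assert out.loc[probe_id, "gene"] == best.gene_id


class TestFpkm:
    def test_unit_definition(self):
        counts = pd.DataFrame({"s": [100, 999_900]}, index=["g", "rest"])
        lengths = pd.Series({"g": 1_000, "rest": 1_000})
        out = fpkm(counts, lengths)
        assert out.loc["g", "s"] == pytest.approx(100.0)

    def test_zero_count_zero_fpkm(self):
        counts = pd.DataFrame({"s": [0, 10]}, index=["g", "rest"])
        out = fpkm(counts, pd.Series({"g": 500, "rest": 500}))
        assert out.loc["g", "s"] == 0.0

    def test_library_size_invariance(self):
        counts = pd.DataFrame({"s": [10, 90]}, index=["a", "b"])
        lengths = pd.Series({"a": 1_000, "b": 2_000})
        np.testing.assert_allclose(fpkm(counts, lengths)["s"],
                                   fpkm(counts * 2, lengths)["s"])

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s": [0]}, index=["g"])
        with pytest.raises(ValueError):
            fpkm(counts, pd.Series({"g": 100}))


class TestExpressionFlags:
    def sheet(self, samples, pop):
        return pd.DataFrame({"sample": samples, "population": pop,
                             "assay": "rnaseq"})

    def test_expressed_above_unity(self):
        mat = pd.DataFrame({"a": [10.0], "b": [10.0]}, index=["g"])
        sheet = self.sheet(["a", "b"], ["cMCL", "cMCL"])
        flags = expression_flags(mat, sheet)
        assert flags.loc["g", "expressed_cMCL"]

    def test_low_fpkm_not_expressed(self):
        mat = pd.DataFrame({"a": [0.5], "b": [0.5]}, index=["g"])
        flags = expression_flags(mat, self.sheet(["a", "b"], ["cMCL", "cMCL"]))
        assert not flags.loc["g", "expressed_cMCL"]

    def test_boundary_is_strict(self):
        mat = pd.DataFrame({"a": [0.99]}, index=["g"])
        flags = expression_flags(mat, self.sheet(["a"], ["cMCL"]))
        assert flags.loc["g", "meanlog_cMCL"] == pytest.approx(0.0, abs=1e-12)
        assert not flags.loc["g", "expressed_cMCL"]


class TestDifferentialExpression:
    def test_size_factors_proportional_to_depth(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]},
                              index=list("abc"))
        sf = size_factors(counts)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)

    def test_identical_groups_give_zero_fold_change(self, rng):
        base = rng.negative_binomial(20, 20 / 220.0, size=(300, 5))
        counts = pd.DataFrame(np.hstack([base, base]),
                              columns=[f"r{i}" for i in range(5)]
                              + [f"t{i}" for i in range(5)])
        groups = pd.Series(["ref"] * 5 + ["trt"] * 5, index=counts.columns)
        de = differential_expression(counts, groups, "ref", "trt")
        assert (de["log2fc"].abs() < 0.1).mean() >= 0.95

    def test_planted_fold_change_recovered(self, rng):
        # 4-fold change planted in a minority of genes; median-of-ratios
        # normalization assumes most genes are unchanged
        n, n_up = 400, 50
        mu_ref, disp = 200.0, 0.05
        r = 1 / disp
        mu_trt = np.full(n, mu_ref)
        mu_trt[:n_up] = 4 * mu_ref
        ref = rng.negative_binomial(r, r / (r + mu_ref), size=(n, 5))
        trt = rng.negative_binomial(r, r / (r + mu_trt[:, None]), size=(n, 5))
        counts = pd.DataFrame(np.hstack([ref, trt]),
                              columns=[f"r{i}" for i in range(5)]
                              + [f"t{i}" for i in range(5)])
        groups = pd.Series(["ref"] * 5 + ["trt"] * 5, index=counts.columns)
        de = differential_expression(counts, groups, "ref", "trt")
        assert 1.7 <= de["log2fc"][:n_up].mean() <= 2.3
        assert (de["padj"][:n_up] < 0.1).mean() > 0.9

    def test_small_group_rejected(self):
        counts = pd.DataFrame({"a": [1], "b": [2], "c": [3]}, index=["g"])
        groups = pd.Series({"a": "x", "b": "x", "c": "y"})
        with pytest.raises(ValueError):
            differential_expression(counts, groups, "x", "y")


class TestCategoryHierarchy:
    def frame(self, expr_t, expr_n, log2fc=np.nan, padj=np.nan):
        flags = pd.DataFrame({"expressed_cMCL": [expr_t],
                              "expressed_NBC-B": [expr_n]}, index=["g"])
        de = pd.DataFrame({"log2fc": [log2fc], "padj": [padj]}, index=["g"])
        return flags, de

    @pytest.mark.parametrize("expr_t,expr_n,fc,padj,expected", [
        (False, False, np.nan, np.nan, "not expressed"),
        (True, True, 0.5, 0.001, "stable expression"),
        (True, False, 2.5, 0.01, "de novo expression"),
        (True, True, -2.0, 0.01, "downregulated"),
        (True, True, 2.0, 0.01, "upregulated"),
        (False, True, -3.0, 0.001, "lost expression"),
        # literal rule order: non-significant loss is captured by "stable"
        (False, True, -0.5, 0.5, "stable expression"),
    ])
    def test_rule_order(self, expr_t, expr_n, fc, padj, expected):
        flags, de = self.frame(expr_t, expr_n, fc, padj)
        assert classify_expression_categories(flags, de).loc["g"] == expected

    def test_strict_loss_precedence_flag(self):
        flags, de = self.frame(False, True, -0.5, 0.5)
        out = classify_expression_categories(flags, de,
                                             strict_loss_precedence=True)
        assert out.loc["g"] == "lost expression"

    def test_missing_de_stats_rejected(self):
        flags, de = self.frame(True, True)
        with pytest.raises(ValueError):
            classify_expression_categories(flags, de)

    def test_partition_on_random_inputs(self, rng):
        n = 500
        flags = pd.DataFrame({
            "expressed_cMCL": rng.random(n) < 0.6,
            "expressed_NBC-B": rng.random(n) < 0.6,
        }, index=[f"g{i}" for i in range(n)])
        de = pd.DataFrame({
            "log2fc": rng.normal(0, 2, n),
            "padj": rng.random(n),
        }, index=flags.index)
        cats = classify_expression_categories(flags, de)
        assert cats.isin(CATEGORIES).all()
        assert cats.notna().all()


class TestGeneCategoryEnrichment:
    def setup_toy(self):
        cpg_ids = [f"c{i}" for i in range(400)]
        genes = [f"g{i}" for i in range(400)]
        assignments = pd.DataFrame({"gene": genes}, index=cpg_ids)
        cats = pd.Series(["de novo expression"] * 100
                         + ["stable expression"] * 300,
                         index=genes)
        return cpg_ids, assignments, cats

    def test_duplicate_cpgs_count_gene_once(self):
        assignments = pd.DataFrame({"gene": ["gA", "gA", "gB", "gC"]},
                                   index=["c1", "c2", "c3", "c4"])
        cats = pd.Series({"gA": "de novo expression",
                          "gB": "stable expression",
                          "gC": "stable expression"})
        res = {r.label: r for r in gene_category_enrichment(
            ["c1", "c2", "c3"], ["c1", "c2", "c3", "c4"], assignments, cats,
            n_sims=200, seed=0)}
        # unique genes of the selection are {gA, gB}: fraction 1/2 each
        assert res["de novo expression"].observed == pytest.approx(0.5)

    def test_selection_equal_background_is_null(self):
        cpg_ids, assignments, cats = self.setup_toy()
        res = gene_category_enrichment(cpg_ids, cpg_ids, assignments, cats,
                                       n_sims=300, seed=1)
        for r in res:
            if r.observed > 0:
                assert r.p_enrich == 1.0 and r.fold == 1.0

    def test_matches_hypergeometric_on_bijective_toy(self):
        # one gene per CpG: the unique-gene fraction reduces to a count
        cpg_ids, assignments, cats = self.setup_toy()
        rng = np.random.default_rng(2)
        sel = list(rng.choice(cpg_ids[:100], 30, replace=False)) \
            + list(rng.choice(cpg_ids[100:], 70, replace=False))
        n_sims = 20_000
        res = {r.label: r for r in gene_category_enrichment(
            sel, cpg_ids, assignments, cats, n_sims=n_sims, seed=3)}
        p_exact = hypergeometric_tail(30, 100, 100, 400)
        r_hat = res["de novo expression"].r_enrich / n_sims
        se = math.sqrt(p_exact * (1 - p_exact) / n_sims)
        assert abs(r_hat - p_exact) <= 3 * se
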