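import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from te_spread import CLASS_BOTH, CLASS_NONE
from te_spread import expression_proximity as ep
from te_spread._stats import ranksum
from te_spread.formats_io import GenomicInterval, GeneModel, \
    RepeatAnnotation


def make_gene(gene_id, chrom, start, end, strand):
    iv = GenomicInterval(chrom, start, end, strand)
    return GeneModel(gene_id, iv, (iv,), end - start)


def make_repeat(copy_id, chrom, start, end, family="fam"):
    return RepeatAnnotation(GenomicInterval(chrom, start, end, "+"),
                            family, "RLG", copy_id)


class TestRpkm:
    def test_formula(self):
        assert ep.rpkm(100, 2000, 10_000_000) == pytest.approx(5.0)

    def test_zero_count(self):
        assert ep.rpkm(0, 2000, 10_000_000) == 0.0

    def test_doubling_library_halves(self):
        assert ep.rpkm(100, 2000, 20_000_000) == \
            pytest.approx(ep.rpkm(100, 2000, 10_000_000) / 2)

    @pytest.mark.parametrize("exon,lib", [(0, 10), (10, 0), (-5, 10)])
    def test_invalid_inputs(self, exon, lib):
        with pytest.raises(ValueError):
            ep.rpkm(1, exon, lib)

    def test_exact_against_rational_arithmetic(self, rng):
        for _ in range(50):
            count = int(rng.integers(0, 10_000))
            exon = int(rng.integers(1, 50_000))
            lib = int(rng.integers(1, 10**8))
            exact = Fraction(10**9) * count / (Fraction(exon) * lib)
            assert ep.rpkm(count, exon, lib) == \
                pytest.approx(float(exact), rel=1e-12)


class TestNearestUpstreamTe:
    def test_plus_strand(self):
        gene = make_gene("g", "chr1", 10_000, 10_600, "+")
        repeats = [make_repeat("A", "chr1", 9_000, 9_600)]
        rec = ep.nearest_upstream_te(gene, repeats)
        assert rec.distance_bp == 400
        assert rec.nearest_upstream_family == "fam"

    def test_minus_strand(self):
        gene = make_gene("g", "chr1", 9_400, 10_000, "-")
        repeats = [make_repeat("A", "chr1", 10_450, 11_000)]
        rec = ep.nearest_upstream_te(gene, repeats)
        assert rec.distance_bp == 450

    def test_tss_inside_repeat_distance_zero(self):
        gene = make_gene("g", "chr1", 10_000, 10_600, "+")
        repeats = [make_repeat("A", "chr1", 9_500, 10_200)]
        rec = ep.nearest_upstream_te(gene, repeats)
        assert rec.distance_bp == 0.0
        assert rec.stratum() == 500

    def test_downstream_repeat_ignored_on_plus(self):
        gene = make_gene("g", "chr1", 10_000, 10_600, "+")
        repeats = [make_repeat("A", "chr1", 11_000, 12_000)]
        rec = ep.nearest_upstream_te(gene, repeats)
        assert math.isinf(rec.distance_bp)
        assert rec.stratum() is None

    def test_no_repeat_on_chrom(self):
        gene = make_gene("g", "chr1", 10_000, 10_600, "+")
        repeats = [make_repeat("A", "chr9", 1_000, 2_000)]
        rec = ep.nearest_upstream_te(gene, repeats)
        assert math.isinf(rec.distance_bp)

    def test_unstranded_gene_errors(self):
        iv = GenomicInterval("chr1", 0, 100, ".")
        gene = GeneModel("g", iv, (iv,), 100)
        with pytest.raises(ValueError):
            ep.nearest_upstream_te(gene, [make_repeat("A", "chr1", 0, 10)])


class TestWilcoxonExactOracle:
    """ranksum must equal full enumeration of rank-sum assignments."""

    @staticmethod
    def _enumerated_p(a, b):
        pooled = sorted(a + b)
        ranks = {v: i + 1 for i, v in enumerate(pooled)}
        n, m = len(a), len(b)
        u_obs = sum(ranks[v] for v in a) - n * (n + 1) / 2
        count_le = 0
        count_ge = 0
        total = 0
        for combo in itertools.combinations(range(n + m), n):
            u = sum(r + 1 for r in combo) - n * (n + 1) / 2
            total += 1
            if u <= u_obs:
                count_le += 1
            if u >= u_obs:
                count_ge += 1
        return min(1.0, 2 * min(count_le, count_ge) / total)

    @pytest.mark.parametrize("n,m,seed", [(3, 3, 0), (5, 4, 1), (8, 8, 2),
                                          (2, 8, 3), (6, 7, 4)])
    def test_matches_enumeration(self, n, m, seed):
        rng = np.random.default_rng(seed)
        a = list(rng.uniform(0, 1, size=n))
        b = list(rng.uniform(0, 1, size=m))
        expected = self._enumerated_p(a, b)
        observed = float(ranksum(a, b).pvalue)
        assert observed == pytest.approx(expected, rel=1e-9)


class TestStratifiedComparison:
    @pytest.fixture
    def dataset(self):
        repeats = [make_repeat("S", "chr1", 10_000, 11_000, "famS"),
                   make_repeat("N", "chr1", 50_000, 51_000, "famN")]
        classes = {"famS": CLASS_BOTH, "famN": CLASS_NONE}
        genes = []
        expression = {}
        rng = np.random.default_rng(0)
        for i in range(20):
            # 10 genes near the spreading TE at 300 bp, 10 near the
            # non-spreading TE
            rep_end = 11_000 if i < 10 else 51_000
            tss = rep_end + 300 + i
            g = make_gene(f"g{i}", "chr1", tss, tss + 400, "+")
            genes.append(g)
            value = 1.0 + rng.uniform() if i < 10 else 10.0 + rng.uniform()
            expression[g.gene_id] = ep.GeneExpression(
                g.gene_id, {"s": 1}, {"s": value})
        proximity = ep.proximity_records(genes, repeats)
        return proximity, expression, classes

    def test_suppressed_class_lower(self, dataset):
        proximity, expression, classes = dataset
        out = ep.stratified_comparison(proximity, expression, classes, "s")
        row = out[(out["cutoff_bp"] == 500)
                  & (out["class"] == CLASS_BOTH)].iloc[0]
        non = out[(out["cutoff_bp"] == 500)
                  & (out["class"] == CLASS_NONE)].iloc[0]
        assert row["mean_rpkm"] < non["mean_rpkm"]
        assert row["p_vs_nonspreading"] < 0.001

    def test_nested_strata_accumulate(self, dataset):
        proximity, expression, classes = dataset
        out = ep.stratified_comparison(proximity, expression, classes, "s")
        n_500 = out[(out["cutoff_bp"] == 500)
                    & (out["class"] == CLASS_BOTH)]["n_genes"].iloc[0]
        n_5000 = out[(out["cutoff_bp"] == 5000)
                     & (out["class"] == CLASS_BOTH)]["n_genes"].iloc[0]
        assert n_5000 >= n_500

    def test_exclude_zeros_removes_exactly_zero_genes(self, dataset):
        proximity, expression, classes = dataset
        for gid in list(expression)[:3]:
            expression[gid].rpkm_values["s"] = 0.0
        full = ep.stratified_comparison(proximity, expression, classes,
                                        "s")
        trimmed = ep.stratified_comparison(proximity, expression, classes,
                                           "s", exclude_zeros=True)
        n_full = full[full["cutoff_bp"] == 5000]["n_genes"].sum()
        n_trim = trimmed[trimmed["cutoff_bp"] == 5000]["n_genes"].sum()
        assert n_full - n_trim == 3

    def test_stratification_is_partition(self, small_bundle):
        expression = ep.gene_expression(small_bundle.genes,
                                        small_bundle.counts,
                                        small_bundle.library_sizes)
        proximity = ep.proximity_records(small_bundle.genes,
                                         small_bundle.repeats)
        cutoffs = (500, 1000, 2500, 5000)
        strata = {}
        for gid, rec in proximity.items():
            strata.setdefault(rec.stratum(cutoffs), []).append(gid)
        assert sum(len(v) for v in strata.values()) == len(proximity)

    def test_null_distributions_similar(self):
        rng = np.random.default_rng(5)
        repeats = [make_repeat("S", "chr1", 10_000, 11_000, "famS"),
                   make_repeat("N", "chr1", 50_000, 51_000, "famN")]
        classes = {"famS": CLASS_BOTH, "famN": CLASS_NONE}
        genes, expression = [], {}
        for i in range(40):
            rep_end = 11_000 if i < 20 else 51_000
            tss = rep_end + 100 + 7 * i
            g = make_gene(f"g{i}", "chr1", tss, tss + 300, "+")
            genes.append(g)
            expression[g.gene_id] = ep.GeneExpression(
                g.gene_id, {"s": 1}, {"s": float(rng.lognormal(0, 1))})
        proximity = ep.proximity_records(genes, repeats)
        out = ep.stratified_comparison(proximity, expression, classes, "s")
        row = out[(out["cutoff_bp"] == 1000)
                  & (out["class"] == CLASS_BOTH)].iloc[0]
        assert row["p_vs_nonspreading"] > 0.001


class TestProportionExpressed:
    def test_fraction(self):
        repeats = [make_repeat("S", "chr1", 10_000, 11_000, "famS")]
        classes = {"famS": CLASS_BOTH}
        genes, expression = [], {}
        for i in range(10):
            tss = 11_000 + 200 + i
            g = make_gene(f"g{i}", "chr1", tss, tss + 300, "+")
            genes.append(g)
            expression[g.gene_id] = ep.GeneExpression(
                g.gene_id, {"s": 1}, {"s": 1.0 if i < 8 else 0.0})
        proximity = ep.proximity_records(genes, repeats)
        out = ep.proportion_expressed(proximity, expression, classes, "s")
        row = out[(out["cutoff_bp"] == 500)
                  & (out["class"] == CLASS_BOTH)].iloc[0]
        assert row["proportion_expressed"] == pytest.approx(0.8)
        assert row["n_expressed"] == 8

    def test_all_zero(self):
        repeats = [make_repeat("S", "chr1", 10_000, 11_000, "famS")]
        genes = [make_gene("g0", "chr1", 11_200, 11_500, "+")]
        expression = {"g0": ep.GeneExpression("g0", {"s": 0}, {"s": 0.0})}
        proximity = ep.proximity_records(genes, repeats)
        out = ep.proportion_expressed(proximity, expression,
                                      {"famS": CLASS_BOTH}, "s")
        row = out[(out["cutoff_bp"] == 500)
                  & (out["class"] == CLASS_BOTH)].iloc[0]
        assert row["proportion_expressed"] == 0.0


class TestGeneExpressionTable:
    def test_unknown_gene_errors(self, small_bundle):
        counts = pd.DataFrame([{"gene_id": "nope", "sample": "s",
                                "count": 1}])
        with pytest.raises(ValueError):
            ep.gene_expression(small_bundle.genes, counts, {"s": 100})

    def test_expressed_flag_tracks_rpkm(self, small_bundle):
        expr = ep.gene_expression(small_bundle.genes, small_bundle.counts,
                                  small_bundle.library_sizes)
        sample = small_bundle.config.genes.sample
        for e in expr.values():
            assert e.expressed(sample) == (e.rpkm_for(sample) > 0)
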