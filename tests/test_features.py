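"""Chromosome bootstrap, gene-region classes, structural and group tests."""

import numpy as np
import pandas as pd
import pytest

from irdm import features, qdmr
from irdm.types import MethylationMatrix, UndefinedResultError

from oracles import hypergeom_upper_tail


def _islands(n_a, n_b, chrom_a="chrA", chrom_b="chrB"):
    rows = []
    for i in range(n_a):
        rows.append((chrom_a, i * 10, i * 10 + 5, f"a{i}"))
    for i in range(n_b):
        rows.append((chrom_b, i * 10, i * 10 + 5, f"b{i}"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "island_id"])
    df["length"] = 5
    df["cpg_count"] = 1
    df["gc_fraction"] = 0.7
    df["obs_exp"] = 0.8
    return df


class TestChromosomeBootstrap:
    def test_full_universe_has_no_enrichment(self):
        isl = _islands(30, 20)
        rep = features.chromosome_bootstrap(
            set(isl["island_id"]), isl, n_boot=500, seed=0)
        assert np.allclose(rep["observed_prop"], rep["expected_prop"])
        assert (rep["p_value"] > 0.5).all()

    def test_extreme_concentration_matches_exact_tail(self):
        # 10 calls all on a chromosome holding 50 of 100 islands:
        # P(all 10 sampled from that chromosome) = C(50,10)/C(100,10)
        isl = _islands(50, 50)
        calls = {f"a{i}" for i in range(10)}
        rep = features.chromosome_bootstrap(calls, isl,
                                            n_boot=10_000, seed=1)
        exact = hypergeom_upper_tail(10, 100, 50, 10)
        assert exact == pytest.approx(5.93e-4, rel=1e-3)
        p = rep.set_index("chrom").loc["chrA", "p_value"]
        mc_se = np.sqrt(exact * (1 - exact) / 10_000)
        assert abs(p - exact) <= 3 * mc_se + 1 / 10_001

    def test_p_value_never_zero(self):
        isl = _islands(5, 995)
        rep = features.chromosome_bootstrap(
            {f"a{i}" for i in range(5)}, isl, n_boot=200, seed=2)
        assert (rep["p_value"] >= 1 / 201).all()

    def test_planted_chromosome_enriched(self, default_dataset,
                                         default_call_set):
        from irdm import overlap
        deg = overlap.overlap_degrees(default_call_set.calls_by_line)
        rep = features.chromosome_bootstrap(
            set(deg.index), default_dataset.islands,
            n_boot=10_000, seed=3)
        p_x = rep.set_index("chrom").loc["chrX", "p_value"]
        assert p_x < 1e-3


def _gene(gene_id, chrom, strand, exons, cds_start):
    starts = tuple(s for s, _ in exons)
    ends = tuple(e for _, e in exons)
    return (gene_id, chrom, strand, starts[0], ends[-1], cds_start,
            starts, ends)


GENES = pd.DataFrame([
    # + strand, 3 exons: [10000,10500) [12000,12400) [14000,15000)
    _gene("gplus", "chr1", "+",
          [(10_000, 10_500), (12_000, 12_400), (14_000, 15_000)], 10_100),
    # - strand, 2 exons: [40000,40600) [42000,43000), CDS start at 42800
    _gene("gminus", "chr1", "-", [(40_000, 40_600), (42_000, 43_000)],
          42_800),
], columns=["gene_id", "chrom", "strand", "tx_start", "tx_end",
            "cds_start", "exon_starts", "exon_ends"])


def _island_at(mid, island_id="q"):
    return pd.DataFrame(
        [("chr1", mid - 50, mid + 50, island_id, 100, 5, 0.7, 0.8)],
        columns=["chrom", "start", "end", "island_id", "length",
                 "cpg_count", "gc_fraction", "obs_exp"])


class TestGeneRegionClassification:
    @pytest.mark.parametrize("midpoint, expected", [
        (8_100, "five_prime"),       # 2 kb upstream of + CDS start
        (11_000, "five_prime"),      # first intron of + gene
        (12_200, "intragenic"),      # internal exon of + gene
        (14_500, "three_prime"),     # final exon of + gene
        (13_000, "three_prime"),     # final intron of + gene
        (25_000, "intergenic"),      # 10 kb from both genes
        (44_000, "five_prime"),      # upstream of - gene's CDS start
        (40_300, "three_prime"),     # final (leftmost) exon of - gene
        (16_000, "three_prime"),     # <3 kb downstream strip of + gene
    ])
    def test_midpoint_rules(self, midpoint, expected):
        classes = features.classify_gene_region(_island_at(midpoint), GENES)
        assert classes["q"] == expected

    def test_classification_is_total(self, default_dataset):
        classes = features.classify_gene_region(
            default_dataset.islands, default_dataset.genes)
        assert len(classes) == len(default_dataset.islands)
        assert set(classes.unique()) <= set(features.CLASSES)

    def test_no_genes_means_all_intergenic(self):
        classes = features.classify_gene_region(
            _island_at(1_000), GENES.iloc[:0])
        assert (classes == "intergenic").all()


class TestGeneRegionChisq:
    def test_identical_proportions_give_zero(self):
        classes = pd.Series(["five_prime"] * 10 + ["intragenic"] * 10)
        res = features.gene_region_chisq(classes, classes)
        assert res["statistic"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # observed (30,10,10,50) against uniform expected 25 each:
        # sum((O-E)^2/E) = (25+225+225+625)/25 = 44
        obs = pd.Series(["five_prime"] * 30 + ["intragenic"] * 10
                        + ["three_prime"] * 10 + ["intergenic"] * 50)
        ref = pd.Series(list(features.CLASSES) * 25)
        res = features.gene_region_chisq(obs, ref)
        assert res["statistic"] == pytest.approx(44.0)


class TestStructuralTests:
    def _frame(self, gc, n):
        return pd.DataFrame({
            "gc_fraction": gc, "length": np.full(n, 600.0),
            "obs_exp": np.full(n, 0.8)})

    def test_identical_groups_no_difference(self):
        rng = np.random.default_rng(0)
        g = self._frame(rng.normal(0.7, 0.05, 50), 50)
        res = features.structural_feature_tests(g, g.copy())
        gc = res.set_index("feature").loc["gc_fraction"]
        assert gc["p_value"] == pytest.approx(1.0)
        assert gc["mean_irdm"] == gc["mean_other"]

    def test_planted_difference_detected(self):
        rng = np.random.default_rng(1)
        a = self._frame(rng.normal(0.68, 0.05, 500), 500)
        b = self._frame(rng.normal(0.70, 0.05, 500), 500)
        res = features.structural_feature_tests(a, b).set_index("feature")
        assert res.loc["gc_fraction", "p_value"] < 0.001

    def test_label_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(2)
        a = self._frame(rng.normal(0.68, 0.05, 100), 100)
        b = self._frame(rng.normal(0.70, 0.05, 100), 100)
        r1 = features.structural_feature_tests(a, b).set_index("feature")
        r2 = features.structural_feature_tests(b, a).set_index("feature")
        assert r1.loc["gc_fraction", "t_statistic"] == pytest.approx(
            -r2.loc["gc_fraction", "t_statistic"])
        assert r1.loc["gc_fraction", "p_value"] == pytest.approx(
            r2.loc["gc_fraction", "p_value"])


class TestIcdm:
    def _matrix(self, arr, lines):
        levels = pd.DataFrame(arr, columns=lines)
        levels.index = [f"r{i}" for i in range(len(levels))]
        return MethylationMatrix(levels, pd.DataFrame(
            1.0, index=levels.index, columns=levels.columns))

    def test_low_sd_calls_superset_of_high_sd(self):
        # a larger assumed noise SD lowers the H_Q cutoff, so its calls
        # are nested inside those of the SD = 0.015 setting
        rng = np.random.default_rng(3)
        m = self._matrix(rng.random((300, 4)), list("abcd"))
        at_low_sd = features.call_icdm(m, sd=0.015, n_sim=20_000, seed=4)
        at_high_sd = features.call_icdm(m, sd=0.05, n_sim=20_000, seed=4)
        assert at_high_sd <= at_low_sd

    def test_cross_line_differences_enriched_in_irdm(
            self, default_dataset, default_call_set):
        from irdm import overlap, pipeline
        uni = default_call_set.intersection_universe()
        mat = pipeline.cell_line_mean_matrix(default_call_set, uni)
        icdm = features.call_icdm(mat, seed=5)
        deg = overlap.overlap_degrees(default_call_set.calls_by_line)
        tiers = overlap.define_tiers(deg, default_dataset.islands)
        rep = features.icdm_enrichment(
            {"all": set(deg.index) & uni, "common": tiers["common"] & uni},
            icdm, uni).set_index("tier")
        assert rep.loc["all", "p_value"] < 1e-10
        assert rep.loc["all", "odds_ratio"] > 1

    def test_degenerate_full_icdm_reported_not_raised(self):
        rep = features.icdm_enrichment(
            {"all": {"r1"}}, {"r1", "r2"}, {"r1", "r2"})
        assert np.isnan(rep.loc[0, "odds_ratio"])


class TestWelchGroupTest:
    def test_identical_values_defined_as_one(self):
        res = features.welch_group_test({"a": [5, 5], "b": [5, 5]})
        assert res["p_value"] == 1.0

    def test_separated_means_detected(self):
        res = features.welch_group_test({
            "a": [100, 95, 102, 99, 104], "b": [500, 505, 498, 503, 497]})
        assert res["p_value"] < 0.001

    def test_null_permutations_rarely_significant(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(100, 10, 12)
        ps = []
        for _ in range(200):
            perm = rng.permutation(vals)
            ps.append(features.welch_group_test(
                {"a": perm[:4], "b": perm[4:8], "c": perm[8:]})["p_value"])
        ps = np.array(ps)
        assert (ps < 0.05).mean() <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 200)

    def test_single_member_group_rejected(self):
        with pytest.raises(UndefinedResultError):
            features.welch_group_test({"a": [1, 2], "b": [3]})
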