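"""Exact Fisher, BH, projection test, LAD enrichment, gene-set machinery."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from senesceq.association_stats import (
    ContingencyTable2x2,
    bh_adjust,
    fisher_exact_2x2,
    gene_lad_association,
    gene_set_enrichment,
    list_overlap_test,
    projection_test,
    region_vs_domains_enrichment,
    select_de_genes,
)
from senesceq.genome_regions import GenomeSpec, GenomicInterval, RegionSet


def fisher_enumeration_oracle(a, b, c, d, sided):
    """Exact-rational hypergeometric enumeration."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    nums = [math.comb(c1, x) * math.comb(n - c1, r1 - x) for x in range(lo, hi + 1)]
    obs = nums[a - lo]
    if sided == "one-greater":
        tail = sum(nums[a - lo:])
    else:
        tail = sum(v for v in nums if v <= obs)
    return float(Fraction(tail, sum(nums)))


class TestFisher:
    def test_modal_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]], "two") == 1.0

    def test_perfect_separation_one_sided(self):
        p = fisher_exact_2x2([[10, 0], [0, 10]], "one-greater")
        assert p == pytest.approx(1 / math.comb(20, 10), rel=1e-12)

    def test_small_table_vs_enumeration(self):
        assert fisher_exact_2x2([[3, 7], [2, 8]], "two") == pytest.approx(
            fisher_enumeration_oracle(3, 7, 2, 8, "two"), rel=1e-12
        )

    @settings(max_examples=100, deadline=None)
    @given(t=st.tuples(*[st.integers(0, 30)] * 4))
    def test_matches_scipy(self, t):
        a, b, c, d = t
        if a + b + c + d == 0:
            return
        table = [[a, b], [c, d]]
        assert fisher_exact_2x2(table, "two") == pytest.approx(
            stats.fisher_exact(table, alternative="two-sided")[1], rel=1e-7, abs=1e-12
        )
        assert fisher_exact_2x2(table, "one-greater") == pytest.approx(
            stats.fisher_exact(table, alternative="greater")[1], rel=1e-7, abs=1e-12
        )

    def test_invalid_tables(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 0, 5)
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)


class TestBH:
    def test_step_up_arithmetic(self):
        assert list(bh_adjust([0.5])) == [0.5]
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert np.allclose(bh_adjust([0.05, 0.01]), [0.05, 0.02])

    def test_hand_computed_oracle(self, rng):
        p = rng.uniform(1e-6, 1, 25)
        got = bh_adjust(p)
        # hand step-up: sort, scale, enforce monotone from the top, restore
        order = np.argsort(p)
        scaled = p[order] * len(p) / np.arange(1, len(p) + 1)
        monotone = np.minimum.accumulate(scaled[::-1])[::-1]
        expected = np.empty_like(p)
        expected[order] = np.minimum(monotone, 1)
        assert np.allclose(got, expected)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=20), st.randoms())
    def test_permutation_invariant(self, p, rnd):
        idx = list(range(len(p)))
        rnd.shuffle(idx)
        base = bh_adjust(p)
        shuffled = bh_adjust([p[i] for i in idx])
        assert np.allclose([base[i] for i in idx], shuffled)
        assert np.all(base > 0) and np.all(base <= 1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([1.5])


def _query_regions(genome, k_inside, n, ref_end):
    """n length-2 query regions, k of them with midpoints inside [0, ref_end)."""
    ivs = []
    for i in range(k_inside):
        s = 10 + 20 * i
        ivs.append(GenomicInterval("chr1", s, s + 2))
    for i in range(n - k_inside):
        s = ref_end + 100 + 20 * i
        ivs.append(GenomicInterval("chr1", s, s + 2))
    return RegionSet(genome, ivs)


class TestProjection:
    def test_reference_covers_genome(self):
        genome = GenomeSpec(("chr1",), (1_000,))
        query = _query_regions(genome, 5, 5, 1_000)
        ref = RegionSet(genome, [GenomicInterval("chr1", 0, 1_000)])
        res = projection_test(query, ref, genome)
        assert (res.p0, res.k, res.p_value, res.direction) == (1.0, 5, 1.0, "none")

    def test_closed_form_all_hits(self):
        genome = GenomeSpec(("chr1",), (1_000,))
        ref = RegionSet(genome, [GenomicInterval("chr1", 0, 500)])
        query = _query_regions(genome, 10, 10, 500)
        res = projection_test(query, ref, genome)
        assert res.p0 == 0.5
        assert res.p_value == pytest.approx(2 / 1_024, rel=1e-12)
        assert res.direction == "enriched"

    def test_binomial_sum_oracle(self):
        genome = GenomeSpec(("chr1",), (10_000,))
        ref = RegionSet(genome, [GenomicInterval("chr1", 0, 2_500)])  # p0 = 0.25
        query = _query_regions(genome, 4, 6, 2_500)
        res = projection_test(query, ref, genome)
        upper = sum(
            math.comb(6, j) * 0.25**j * 0.75 ** (6 - j) for j in range(4, 7)
        )
        lower = sum(
            math.comb(6, j) * 0.25**j * 0.75 ** (6 - j) for j in range(0, 5)
        )
        assert res.k == 4
        assert res.p_value == pytest.approx(min(1.0, 2 * min(upper, lower)), rel=1e-9)

    def test_exhaustive_small_n_vs_binomial(self):
        """Two-sided p equals the explicit binomial tail sum for n <= 25."""
        genome = GenomeSpec(("chr1",), (100_000,))
        ref = RegionSet(genome, [GenomicInterval("chr1", 0, 30_000)])  # p0 = 0.3
        for n in range(1, 26):
            for k in range(0, n + 1):
                query = _query_regions(genome, k, n, 30_000)
                res = projection_test(query, ref, genome)
                upper = sum(
                    math.comb(n, j) * 0.3**j * 0.7 ** (n - j) for j in range(k, n + 1)
                )
                lower = sum(
                    math.comb(n, j) * 0.3**j * 0.7 ** (n - j) for j in range(0, k + 1)
                )
                expected = min(1.0, 2 * min(upper, lower))
                assert res.p_value == pytest.approx(expected, rel=1e-9), (n, k)

    def test_empty_query_rejected(self):
        genome = GenomeSpec(("chr1",), (1_000,))
        ref = RegionSet(genome, [GenomicInterval("chr1", 0, 500)])
        with pytest.raises(ValueError):
            projection_test(RegionSet(genome, []), ref, genome)


class TestRegionVsDomains:
    def test_all_inside_is_enriched(self):
        genome = GenomeSpec(("chr1",), (100_000,))
        domains = RegionSet(genome, [GenomicInterval("chr1", 0, 20_000)])
        regions = RegionSet(
            genome,
            [GenomicInterval("chr1", 100 + 50 * i, 140 + 50 * i) for i in range(50)],
        )
        res = region_vs_domains_enrichment(regions, domains, n_random=50, seed=0)
        assert res["observed_fraction"] == 1.0
        assert res["random_fraction"] < 0.5
        assert res["direction"] == "enriched"
        assert res["p_value"] < 1e-10

    def test_complement_symmetry(self):
        genome = GenomeSpec(("chr1",), (100_000,))
        domains = RegionSet(genome, [GenomicInterval("chr1", 0, 30_000)])
        complement = RegionSet(genome, [GenomicInterval("chr1", 30_000, 100_000)])
        regions = RegionSet(
            genome,
            [GenomicInterval("chr1", 100 + 50 * i, 140 + 50 * i) for i in range(60)],
        )
        r1 = region_vs_domains_enrichment(regions, domains, n_random=50, seed=1)
        r2 = region_vs_domains_enrichment(regions, complement, n_random=50, seed=1)
        assert r1["direction"] == "enriched"
        assert r2["direction"] == "depleted"
        assert r1["observed_fraction"] + r2["observed_fraction"] == 1.0

    def test_planted_lad_structure(self, default_bundle):
        truth = default_bundle.truth
        hypo = region_vs_domains_enrichment(truth.hypo_dmrs, truth.lads, seed=5)
        hyper = region_vs_domains_enrichment(truth.hyper_dmrs, truth.lads, seed=5)
        assert hypo["direction"] == "enriched"
        assert hyper["direction"] == "depleted"


class TestDeGenes:
    @pytest.mark.parametrize(
        "fdr,log2fc,expected",
        [(0.005, 2.5, "up"), (0.005, 1.5, None), (0.02, -3.0, None), (0.001, -2.5, "down")],
    )
    def test_rule(self, fdr, log2fc, expected):
        genes = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["chr1"], "tss": [100], "strand": ["+"],
             "expr": [1.0], "log2fc": [log2fc], "fdr": [fdr]}
        )
        out = select_de_genes(genes)
        got = "up" if len(out["up"]) else ("down" if len(out["down"]) else None)
        assert got == expected

    def test_missing_fields(self):
        with pytest.raises(ValueError):
            select_de_genes(pd.DataFrame({"gene_id": ["g"]}))


class TestGeneLad:
    def _genes(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "chrom", "tss", "strand", "expr", "log2fc", "fdr"]
        )

    def test_tss_at_lad_start_is_inside(self):
        genome = GenomeSpec(("chr1",), (100_000,))
        lads = RegionSet(genome, [GenomicInterval("chr1", 10_000, 20_000)])
        genes = self._genes(
            [
                ("at_start", "chr1", 10_000, "+", 1.0, 0.0, 1.0),
                ("at_end", "chr1", 20_000, "+", 1.0, 0.0, 1.0),
            ]
        )
        res = gene_lad_association(genes, lads)
        assert res["distances"][0] >= 0  # inside by convention
        assert res["distances"][1] <= 0  # end boundary is outside

    def test_all_inside_declines_fisher(self):
        genome = GenomeSpec(("chr1",), (100_000,))
        lads = RegionSet(genome, [GenomicInterval("chr1", 0, 100_000)])
        genes = self._genes(
            [
                ("u1", "chr1", 5_000, "+", 1.0, 3.0, 1e-4),
                ("d1", "chr1", 6_000, "+", 1.0, -3.0, 1e-4),
            ]
        )
        res = gene_lad_association(genes, lads)
        assert res["p_value"] is None
        assert res["table"].as_array().sum() == 2

    def test_expression_profile_low_inside(self, lad_bundle):
        res = gene_lad_association(lad_bundle.genes, lad_bundle.truth.lads)
        prof = res["profile"]
        inside = prof[(prof["dist_lo"] >= 0) & (prof["n"] > 5)]["mean_expr"]
        outside = prof[(prof["dist_hi"] <= 0) & (prof["n"] > 5)]["mean_expr"]
        assert inside.mean() < outside.mean()


class TestGeneSets:
    def test_closed_form(self):
        universe = {f"g{i}" for i in range(20)}
        hits = {f"g{i}" for i in range(5)}
        sets = {"s": {f"g{i}" for i in range(10)}}
        out = gene_set_enrichment(hits, universe, sets)
        assert out.loc[0, "overlap"] == 5
        assert out.loc[0, "p_value"] == pytest.approx(252 / 15_504, rel=1e-12)

    def test_same_proportion_not_enriched(self):
        universe = {f"g{i}" for i in range(100)}
        hits = {f"g{i}" for i in range(20)}  # 20% of universe
        sets = {"s": {f"g{i}" for i in list(range(4)) + list(range(20, 36))}}  # 20% hit rate
        out = gene_set_enrichment(hits, universe, sets)
        assert out.loc[0, "p_value"] >= 0.5

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            gene_set_enrichment({"x"}, {"a", "b"}, {"s": {"a"}})


class TestListOverlap:
    def test_identical_lists_minimal_p(self):
        a = {f"m{i}" for i in range(10)}
        p_same = list_overlap_test(a, a, 100)
        p_less = list_overlap_test(a, {f"m{i}" for i in range(9)} | {"z"}, 100)
        assert p_same < p_less < 1

    def test_disjoint_covering_universe(self):
        a = {f"m{i}" for i in range(10)}
        b = {f"n{i}" for i in range(10)}
        assert list_overlap_test(a, b, 20) == 1.0

    def test_motif_scale_enumeration(self):
        """51 vs 64 motifs with 22 shared in a universe of 300."""
        a = {f"a{i}" for i in range(29)} | {f"c{i}" for i in range(22)}
        b = {f"b{i}" for i in range(42)} | {f"c{i}" for i in range(22)}
        got = list_overlap_test(a, b, 300)
        # hypergeometric upper tail by explicit enumeration
        num = sum(
            math.comb(51, x) * math.comb(300 - 51, 64 - x) for x in range(22, 52)
        )
        assert got == pytest.approx(num / math.comb(300, 64), rel=1e-9)
        assert got < 1e-4

    def test_overflowing_lists_rejected(self):
        with pytest.raises(ValueError):
            list_overlap_test({"a"}, {"b"}, 1)
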