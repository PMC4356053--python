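"""Interval engine: standardisation, random sampling, promoters, overlap, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from senesceq.genome_regions import (
    GenomeSpec,
    GenomicInterval,
    RegionSet,
    interval_overlap_fraction,
    promoter_region,
    read_bed,
    read_chrom_sizes,
    sample_random_regions,
    standardize_region_length,
    write_bed,
    write_chrom_sizes,
)


class TestGenomeSpec:
    def test_total_length_and_lookup(self):
        g = GenomeSpec(("chr1", "chr2"), (100, 50))
        assert g.total_length == 150
        assert g.length_of("chr2") == 50
        with pytest.raises(KeyError):
            g.length_of("chrX")

    @pytest.mark.parametrize(
        "chroms,lengths",
        [(("a", "a"), (10, 20)), (("a", "b"), (10, 0)), (("a",), (10, 20))],
    )
    def test_invalid_specs_rejected(self, chroms, lengths):
        with pytest.raises(ValueError):
            GenomeSpec(chroms, lengths)


class TestIntervals:
    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 10, strand="x")

    def test_regionset_validates_against_genome(self, toy_genome):
        with pytest.raises(ValueError):
            RegionSet(toy_genome, [GenomicInterval("chr2", 0, 6_000)])
        with pytest.raises(ValueError):
            RegionSet(toy_genome, [GenomicInterval("chrZ", 0, 10)])

    def test_merged_unions_overlaps(self, toy_genome):
        rs = RegionSet(
            toy_genome,
            [
                GenomicInterval("chr1", 100, 300),
                GenomicInterval("chr1", 200, 400),
                GenomicInterval("chr1", 500, 600),
            ],
        )
        merged = rs.merged()
        assert [(iv.start, iv.end) for iv in merged] == [(100, 400), (500, 600)]
        assert rs.total_bp() == 400


class TestStandardize:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (100, 200, (130, 170)),  # centred on midpoint 150
            (10, 50, (10, 50)),  # already at target length
            (0, 6, (0, 40)),  # left-clipped, extended right
        ],
    )
    def test_examples(self, start, end, expected):
        g = GenomeSpec(("chr1",), (1_000,))
        out = standardize_region_length(GenomicInterval("chr1", start, end), 40, g)
        assert (out.start, out.end) == expected

    def test_right_clip_shifts_inward(self):
        g = GenomeSpec(("chr1",), (1_000,))
        out = standardize_region_length(GenomicInterval("chr1", 990, 1_000), 40, g)
        assert (out.start, out.end) == (960, 1_000)

    def test_chromosome_shorter_than_target(self):
        g = GenomeSpec(("tiny",), (30,))
        with pytest.raises(ValueError, match="tiny"):
            standardize_region_length(GenomicInterval("tiny", 0, 30), 40, g)

    @settings(max_examples=50, deadline=None)
    @given(start=st.integers(0, 900), length=st.integers(1, 100))
    def test_idempotent_at_target_length(self, start, length):
        g = GenomeSpec(("chr1",), (1_000,))
        iv = GenomicInterval("chr1", start, start + length)
        once = standardize_region_length(iv, 40, g)
        twice = standardize_region_length(once, 40, g)
        assert once.length == 40
        assert (once.start, once.end) == (twice.start, twice.end)


class TestRandomRegions:
    def test_reproducible_and_valid(self):
        g = GenomeSpec(("chr1",), (1_000,))
        a = sample_random_regions([40] * 10, g, n_sets=1, seed=7)[0]
        b = sample_random_regions([40] * 10, g, n_sets=1, seed=7)[0]
        assert len(a) == 10
        assert all(iv.length == 40 and 0 <= iv.start <= 960 for iv in a)
        assert [(x.start, x.end) for x in a] == [(x.start, x.end) for x in b]

    def test_forced_placement(self):
        g = GenomeSpec(("chr1",), (40,))
        (rs,) = sample_random_regions([40], g, n_sets=1, seed=0)
        assert (rs[0].start, rs[0].end) == (0, 40)

    def test_impossible_length_rejected(self):
        g = GenomeSpec(("chr1",), (100,))
        with pytest.raises(ValueError):
            sample_random_regions([200], g, n_sets=1, seed=0)

    def test_chromosome_weighting(self):
        # 10,000 length-1 draws on 900 + 100 bp chromosomes: expect 10% on
        # the small chromosome (placement-count weighting).
        g = GenomeSpec(("big", "small"), (900, 100))
        sets = sample_random_regions([1] * 10_000, g, n_sets=1, seed=3)
        frac = sum(1 for iv in sets[0] if iv.chrom == "small") / 10_000
        assert abs(frac - 0.100) <= 0.01

    def test_start_positions_uniform(self):
        g = GenomeSpec(("chr1",), (1_000,))
        (rs,) = sample_random_regions([10] * 10_000, g, n_sets=1, seed=5)
        starts = np.array([iv.start for iv in rs])
        counts, _ = np.histogram(starts, bins=10, range=(0, 991))
        p = stats.chisquare(counts).pvalue
        assert p > 0.01


class TestPromoter:
    def test_strand_conventions(self, toy_genome):
        plus = promoter_region(5_000, "+", "chr1", toy_genome)
        minus = promoter_region(5_000, "-", "chr1", toy_genome)
        assert (plus.start, plus.end) == (4_000, 5_000)
        assert (minus.start, minus.end) == (5_000, 6_000)

    def test_clipped_at_chrom_start(self, toy_genome):
        out = promoter_region(500, "+", "chr1", toy_genome)
        assert (out.start, out.end) == (0, 500)

    def test_unknown_strand(self, toy_genome):
        with pytest.raises(ValueError):
            promoter_region(5_000, ".", "chr1", toy_genome)


class TestOverlapFraction:
    def test_fractions(self, toy_genome):
        b = RegionSet(toy_genome, [GenomicInterval("chr1", 0, 1_000)])
        a_in = RegionSet(toy_genome, [GenomicInterval("chr1", 100, 200)])
        assert interval_overlap_fraction(a_in, b)["midpoint_fraction"] == 1.0
        a_out = RegionSet(toy_genome, [GenomicInterval("chr1", 2_000, 2_100)])
        assert interval_overlap_fraction(a_out, b)["midpoint_fraction"] == 0.0
        mixed = RegionSet(
            toy_genome,
            [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 600, 700)],
        )
        half = RegionSet(toy_genome, [GenomicInterval("chr1", 0, 500)])
        res = interval_overlap_fraction(mixed, half)
        assert res["midpoint_fraction"] == 0.5
        assert res["overlap_bp"] == [100, 0]

    def test_boundary_midpoint_is_outside(self, toy_genome):
        # half-open convention: midpoint exactly at a domain end is outside
        a = RegionSet(toy_genome, [GenomicInterval("chr1", 450, 550)])  # midpoint 500
        b = RegionSet(toy_genome, [GenomicInterval("chr1", 0, 500)])
        assert interval_overlap_fraction(a, b)["midpoint_fraction"] == 0.0
        b2 = RegionSet(toy_genome, [GenomicInterval("chr1", 500, 600)])
        assert interval_overlap_fraction(a, b2)["midpoint_fraction"] == 1.0

    def test_mismatched_genomes_rejected(self, toy_genome):
        other = GenomeSpec(("chr1",), (10_000,))
        a = RegionSet(toy_genome, [GenomicInterval("chr1", 0, 10)])
        b = RegionSet(other, [GenomicInterval("chr1", 0, 10)])
        with pytest.raises(ValueError):
            interval_overlap_fraction(a, b)


class TestFileIO:
    def test_bed_round_trip(self, toy_genome, tmp_path, rng):
        intervals = []
        for i in range(50):
            s = int(rng.integers(0, 9_000))
            intervals.append(
                GenomicInterval(
                    "chr1", s, s + int(rng.integers(1, 500)),
                    strand=rng.choice(["+", "-", "."]),
                    score=float(np.round(rng.uniform(0, 100), 3)),
                    label=f"region_{i}",
                )
            )
        rs = RegionSet(toy_genome, intervals, name="test")
        path = tmp_path / "regions.bed"
        write_bed(rs, path)
        back = read_bed(path, toy_genome)
        for orig, rt in zip(rs, back):
            assert (orig.chrom, orig.start, orig.end) == (rt.chrom, rt.start, rt.end)
            assert orig.strand == rt.strand
            assert orig.label == rt.label
            assert rt.score == pytest.approx(orig.score)

    def test_chrom_sizes_round_trip(self, toy_genome, tmp_path):
        path = tmp_path / "genome.sizes"
        write_chrom_sizes(toy_genome, path)
        assert read_chrom_sizes(path) == toy_genome
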