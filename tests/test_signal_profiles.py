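"""RPKM normalisation, metaprofiles, LAD comparisons, CpG selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from senesceq.dmr_calling import FragmentSet
from senesceq.genome_regions import GenomeSpec, GenomicInterval, RegionSet
from senesceq.signal_profiles import (
    CoverageTrack,
    inside_outside_test,
    lad_border_profile,
    metaprofile,
    neighborhood_beta_profile,
    rpkm_normalize,
    select_significant_cpgs,
)


def _track(genome, bin_, values_chr1, **others):
    values = {"chr1": np.asarray(values_chr1, dtype=float)}
    values.update({k: np.asarray(v, dtype=float) for k, v in others.items()})
    return CoverageTrack(genome, bin_, values)


class TestRpkm:
    @pytest.mark.parametrize(
        "bin_,n_in_bin,total,expected",
        [
            (1_000, 10, 1_000_000, 10.0),
            (500, 5, 2_000_000, 5.0),
        ],
    )
    def test_closed_form(self, bin_, n_in_bin, total, expected):
        genome = GenomeSpec(("chr1", "filler"), (bin_, 4_000_000))
        rng = np.random.default_rng(0)
        # n_in_bin fragments fully inside the first bin; the rest elsewhere
        in_bin = np.column_stack(
            [np.zeros(n_in_bin, dtype=int) + 2, np.full(n_in_bin, bin_ - 2)]
        )
        starts = rng.integers(0, 3_000_000, size=total - n_in_bin)
        filler = np.column_stack([starts, starts + 1])
        track = rpkm_normalize(
            FragmentSet(genome, {"chr1": in_bin, "filler": filler}), bin_
        )
        assert track.values["chr1"][0] == pytest.approx(expected)

    def test_empty_bin_is_zero(self, toy_genome):
        frags = FragmentSet(toy_genome, {"chr1": np.array([[0, 50]])})
        track = rpkm_normalize(frags, 100)
        assert track.values["chr1"][5] == 0.0

    def test_empty_set_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            rpkm_normalize(FragmentSet(toy_genome, {}), 100)

    def test_mass_conservation(self, small_bundle):
        """Summing value*(bin/1e3)*(total/1e6) over bins >= fragment count."""
        frags = small_bundle.fragments_early
        track = rpkm_normalize(frags, 100)
        total = frags.total_count
        mass = sum(v.sum() for v in track.values.values()) * (100 / 1_000) * (total / 1e6)
        assert mass >= total - 1e-6


class TestMetaprofile:
    def test_constant_track(self):
        genome = GenomeSpec(("chr1",), (10_000,))
        track = _track(genome, 100, np.full(100, 7.5))
        anchors = RegionSet(genome, [GenomicInterval("chr1", 4_000, 4_200)])
        prof = metaprofile(track, anchors, half_window=1_000, step=100)
        assert np.allclose(prof.mean, 7.5)

    def test_single_anchor_reads_off_track(self):
        genome = GenomeSpec(("chr1",), (10_000,))
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 10, 100)
        track = _track(genome, 100, vals)
        mid = 5_050  # anchor midpoint
        anchors = RegionSet(genome, [GenomicInterval("chr1", 5_000, 5_100)])
        prof = metaprofile(track, anchors, half_window=500, step=100)
        expected = [vals[(mid + o) // 100] for o in prof.offsets]
        assert np.allclose(prof.mean, expected)

    def test_two_anchor_average(self):
        genome = GenomeSpec(("chr1",), (10_000,))
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 10, 100)
        track = _track(genome, 100, vals)
        anchors = RegionSet(
            genome,
            [GenomicInterval("chr1", 3_000, 3_100), GenomicInterval("chr1", 6_000, 6_100)],
        )
        prof = metaprofile(track, anchors, half_window=300, step=100)
        for i, o in enumerate(prof.offsets):
            v1 = vals[(3_050 + o) // 100]
            v2 = vals[(6_050 + o) // 100]
            assert prof.mean[i] == pytest.approx((v1 + v2) / 2)

    def test_edge_anchors_excluded(self):
        genome = GenomeSpec(("chr1",), (10_000,))
        track = _track(genome, 100, np.arange(100, dtype=float))
        anchors = RegionSet(genome, [GenomicInterval("chr1", 0, 100)])
        with pytest.raises(ValueError):
            metaprofile(track, anchors, half_window=1_000, step=100)

    def test_global_mean_at_own_midpoints(self):
        genome = GenomeSpec(("chr1",), (10_000,))
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 5, 100)
        track = _track(genome, 100, vals)
        anchors = RegionSet(
            genome,
            [GenomicInterval("chr1", i * 100, (i + 1) * 100) for i in range(5, 95)],
        )
        prof = metaprofile(track, anchors, half_window=500, step=100)
        at0 = prof.mean[np.where(prof.offsets == 0)[0][0]]
        assert at0 == pytest.approx(vals[5:95].mean(), abs=1e-9)


class TestNeighborhoodBeta:
    def test_single_neighbor_lookup(self):
        probes = pd.DataFrame(
            {
                "probe_id": ["a", "b"],
                "chrom": ["chr1", "chr1"],
                "position": [1_000, 1_120],
                "beta_early": [0.3, 0.6],
                "beta_late": [0.4, 0.8],
            }
        )
        anchors = probes.iloc[[0]]
        prof = neighborhood_beta_profile(probes, anchors, window=500, bin=50)
        row = prof[prof["offset"] == 100].iloc[0]
        assert row["mean_beta_late"] == pytest.approx(0.8)
        assert row["n"] == 1

    def test_quadratic_oracle(self, rng):
        """Nested-loop oracle over all (anchor, probe) pairs reproduces bins."""
        n = 200
        pos = np.sort(rng.choice(50_000, size=n, replace=False))
        probes = pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(n)],
                "chrom": "chr1",
                "position": pos,
                "beta_early": rng.uniform(0, 1, n),
                "beta_late": rng.uniform(0, 1, n),
            }
        )
        anchors = probes.iloc[rng.choice(n, size=40, replace=False)]
        window, bin_ = 500, 50
        prof = neighborhood_beta_profile(probes, anchors, window=window, bin=bin_)
        sums = {}
        for a in anchors.itertuples(index=False):
            for p in probes.itertuples(index=False):
                d = p.position - a.position
                if -window <= d < window:
                    b = (d // bin_) * bin_
                    s = sums.setdefault(b, [0.0, 0.0, 0])
                    s[0] += p.beta_early
                    s[1] += p.beta_late
                    s[2] += 1
        for row in prof.itertuples(index=False):
            if row.n == 0:
                assert row.offset not in sums
                assert np.isnan(row.mean_beta_early)
            else:
                se, sl, c = sums[row.offset]
                assert row.n == c
                assert row.mean_beta_early == pytest.approx(se / c)
                assert row.mean_beta_late == pytest.approx(sl / c)

    def test_no_neighbors_rejected(self):
        probes = pd.DataFrame(
            {
                "probe_id": ["a"], "chrom": ["chr1"], "position": [100],
                "beta_early": [0.5], "beta_late": [0.5],
            }
        )
        anchors = pd.DataFrame(
            {
                "probe_id": ["b"], "chrom": ["chr2"], "position": [100],
                "beta_early": [0.5], "beta_late": [0.5],
            }
        )
        with pytest.raises(ValueError):
            neighborhood_beta_profile(probes, anchors)


class TestInsideOutside:
    def test_constant_track_total_tie(self):
        genome = GenomeSpec(("chr1",), (2_000,))
        track = _track(genome, 100, np.full(20, 3.0))
        domains = RegionSet(genome, [GenomicInterval("chr1", 0, 1_000)])
        res = inside_outside_test(track, domains)
        assert res["mean_inside"] == res["mean_outside"]
        assert res["p_value"] == 1.0

    def test_exact_p_matches_rank_enumeration(self):
        """10+10 bins, inside = outside - 1: exact MW p from enumeration."""
        genome = GenomeSpec(("chr1",), (2_000,))
        outside = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0])
        inside = outside - 1.0
        track = _track(genome, 100, np.concatenate([inside, outside]))
        domains = RegionSet(genome, [GenomicInterval("chr1", 0, 1_000)])
        res = inside_outside_test(track, domains)
        # brute force: U statistic null distribution over all rank splits
        pooled = np.concatenate([inside, outside])
        ranks = pooled.argsort().argsort() + 1
        obs_u = ranks[:10].sum() - 10 * 11 / 2
        us = []
        for comb in itertools.combinations(range(20), 10):
            u = ranks[list(comb)].sum() - 10 * 11 / 2
            us.append(u)
        us = np.array(us)
        p_oracle = np.mean(np.minimum(us, 100 - us) <= min(obs_u, 100 - obs_u))
        assert res["mean_inside"] < res["mean_outside"]
        assert res["p_value"] == pytest.approx(p_oracle, rel=1e-9)

    def test_complement_swaps_means(self):
        genome = GenomeSpec(("chr1",), (2_000,))
        rng = np.random.default_rng(4)
        track = _track(genome, 100, rng.uniform(0, 1, 20))
        dom = RegionSet(genome, [GenomicInterval("chr1", 0, 700)])
        comp = RegionSet(genome, [GenomicInterval("chr1", 700, 2_000)])
        r1 = inside_outside_test(track, dom)
        r2 = inside_outside_test(track, comp)
        assert r1["mean_inside"] == pytest.approx(r2["mean_outside"])
        assert r1["mean_outside"] == pytest.approx(r2["mean_inside"])
        assert r1["p_value"] == pytest.approx(r2["p_value"])

    def test_planted_lad_attenuation_detected(self, lad_bundle):
        from senesceq.signal_profiles import rpkm_normalize

        track = rpkm_normalize(lad_bundle.fragments_early, 100)
        res = inside_outside_test(track, lad_bundle.truth.lads)
        assert res["mean_inside"] < res["mean_outside"]
        assert res["p_value"] < 1e-10


class TestLadBorderProfile:
    def test_constant_track(self):
        genome = GenomeSpec(("chr1",), (1_000_000,))
        track = _track(genome, 1_000, np.full(1_000, 2.0))
        lads = RegionSet(genome, [GenomicInterval("chr1", 400_000, 600_000)])
        prof = lad_border_profile(track, lads, flank=50_000, step=1_000)
        assert np.allclose(prof.mean[prof.n > 0], 2.0)

    def test_step_track_oracle(self):
        """Track = 1 outside LADs, 0 inside: profile is a step at offset 0."""
        genome = GenomeSpec(("chr1",), (1_000_000,))
        lads = RegionSet(genome, [GenomicInterval("chr1", 400_000, 600_000)])
        vals = np.ones(1_000)
        vals[400:600] = 0.0
        track = _track(genome, 1_000, vals)
        prof = lad_border_profile(track, lads, flank=50_000, step=1_000)
        neg = prof.mean[(prof.offsets < 0) & (prof.n > 0)]
        pos = prof.mean[(prof.offsets > 0) & (prof.n > 0)]
        assert np.allclose(neg, 1.0)
        assert np.allclose(pos, 0.0)

    def test_mirrored_borders_of_symmetric_track(self):
        genome = GenomeSpec(("chr1",), (1_000_000,))
        lads = RegionSet(genome, [GenomicInterval("chr1", 400_000, 600_000)])
        # track symmetric about the LAD center
        centers = np.arange(1_000) * 1_000 + 500
        vals = np.abs(centers - 500_000).astype(float)
        track = _track(genome, 1_000, vals)
        prof = lad_border_profile(track, lads, flank=50_000, step=1_000)
        # each offset is the average of two identical border contributions
        ok = prof.n == 2
        assert ok.sum() > 50

    def test_no_usable_borders(self):
        genome = GenomeSpec(("chr1",), (10_000,))
        track = _track(genome, 1_000, np.ones(10))
        lads = RegionSet(genome, [GenomicInterval("chr1", 100, 600)])  # < step
        with pytest.raises(ValueError):
            lad_border_profile(track, lads, flank=5_000, step=1_000)


class TestSelectCpgs:
    @pytest.mark.parametrize(
        "adj_p,delta,expected",
        [
            (0.04, 0.25, "hyper"),
            (0.04, 0.15, None),
            (0.06, -0.50, None),
            (0.04, -0.25, "hypo"),
        ],
    )
    def test_rule(self, adj_p, delta, expected):
        probes = pd.DataFrame(
            {
                "probe_id": ["x"], "chrom": ["chr1"], "position": [10],
                "beta_early": [0.4], "beta_late": [0.4 + delta], "adj_p": [adj_p],
            }
        )
        out = select_significant_cpgs(probes)
        got = None
        if len(out["hyper"]):
            got = "hyper"
        elif len(out["hypo"]):
            got = "hypo"
        assert got == expected

    def test_missing_fields_rejected(self):
        with pytest.raises(ValueError):
            select_significant_cpgs(pd.DataFrame({"probe_id": ["x"]}))

    def test_planted_probes_recovered(self, small_bundle):
        out = select_significant_cpgs(small_bundle.probes)
        truth = small_bundle.probes["truth"]
        assert set(out["hyper"]["truth"]) == {"hyper"}
        assert set(out["hypo"]["truth"]) == {"hypo"}
        assert len(out["hyper"]) >= 0.95 * (truth == "hyper").sum()
        assert len(out["hypo"]) >= 0.95 * (truth == "hypo").sum()
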