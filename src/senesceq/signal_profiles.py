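"""RPKM normalisation and windowed signal summaries.

Covers: differential capture signal in 600-bp windows around array CpGs,
500-bp neighbourhood beta profiles around significant CpGs, RPKM
metaprofiles in windows around DMR midpoints, the LAD inside/outside
Mann-Whitney comparison, LAD border profiles, and the selection of
significant array CpGs (adjusted p < 0.05 and methylation change > 20%).

Empty profile bins are reported as missing values, never zeros, to avoid
biasing means.  The Mann-Whitney sampling unit is the track bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from senesceq.dmr_calling import FragmentSet
from senesceq.genome_regions import GenomeSpec, RegionSet

PROBE_COLUMNS = ["probe_id", "chrom", "position", "beta_early", "beta_late", "adj_p"]


class CoverageTrack:
    """Fixed-bin per-chromosome signal, raw counts or RPKM."""

    def __init__(
        self,
        genome: GenomeSpec,
        bin: int,
        values: Mapping[str, np.ndarray],
        units: str = "raw",
    ):
        self.genome = genome
        self.bin = int(bin)
        self.units = units
        self.values: dict[str, np.ndarray] = {}
        for chrom, length in zip(genome.chroms, genome.lengths):
            nb = -(-length // bin)
            arr = np.asarray(values[chrom], dtype=float)
            if arr.size != nb:
                raise ValueError(
                    f"track for {chrom} has {arr.size} bins, expected {nb}"
                )
            self.values[chrom] = arr

    def value_at(self, chrom: str, pos: int) -> float:
        return float(self.values[chrom][pos // self.bin])

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        return self.values[chrom][np.asarray(positions) // self.bin]

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        """bp-weighted mean of the track over [start, end), clipped to bounds."""
        length = self.genome.length_of(chrom)
        start, end = max(0, start), min(length, end)
        if end <= start:
            raise ValueError("empty window")
        v = self.values[chrom]
        b0, b1 = start // self.bin, (end - 1) // self.bin
        if b0 == b1:
            return float(v[b0])
        edges = np.arange(b0, b1 + 2) * self.bin
        edges[0], edges[-1] = start, end
        weights = np.diff(edges)
        return float(np.average(v[b0 : b1 + 1], weights=weights))

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, length in zip(self.genome.chroms, self.genome.lengths):
                v = self.values[chrom]
                for i, val in enumerate(v):
                    s = i * self.bin
                    e = min(length, s + self.bin)
                    fh.write(f"{chrom}\t{s}\t{e}\t{val:.6g}\n")

    @classmethod
    def from_bedgraph(
        cls, path: str | Path, genome: GenomeSpec, bin: int, units: str = "raw"
    ) -> "CoverageTrack":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
        values = {}
        for chrom, length in zip(genome.chroms, genome.lengths):
            nb = -(-length // bin)
            arr = np.zeros(nb)
            sub = df[df["chrom"] == chrom]
            arr[sub["start"].to_numpy() // bin] = sub["value"].to_numpy()
            values[chrom] = arr
        return cls(genome, bin, values, units=units)


def rpkm_normalize(fragments: FragmentSet, bin: int) -> CoverageTrack:
    """Reads per kilobase per million mapped reads, per fixed-size bin.

    ``value = count / ((bin/1000) * (total/1e6))``; a fragment increments
    every bin it overlaps.
    """
    total = fragments.total_count
    if total == 0:
        raise ValueError("cannot RPKM-normalize an empty fragment set")
    denom = (bin / 1_000) * (total / 1_000_000)
    counts = fragments.bin_counts(bin)
    values = {c: v / denom for c, v in counts.items()}
    return CoverageTrack(fragments.genome, bin, values, units="RPKM")


def raw_track(fragments: FragmentSet, bin: int) -> CoverageTrack:
    return CoverageTrack(
        fragments.genome, bin,
        {c: v.astype(float) for c, v in fragments.bin_counts(bin).items()},
        units="raw",
    )


@dataclass
class MetaProfile:
    """Mean signal at signed offsets around anchor points."""

    offsets: np.ndarray
    mean: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean": self.mean, "n": self.n})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def metaprofile(
    track: CoverageTrack,
    anchors: RegionSet,
    half_window: int,
    step: int | None = None,
) -> MetaProfile:
    """Mean track value at signed offsets around anchor midpoints.

    Anchors whose full window would leave the chromosome are excluded.
    """
    step = step or track.bin
    if half_window % step:
        raise ValueError("half_window must be a multiple of step")
    if len(anchors) == 0:
        raise ValueError("no anchors")
    offsets = np.arange(-half_window, half_window + 1, step)
    sums = np.zeros(offsets.size)
    used = 0
    for chrom, mids in anchors.midpoints().items():
        length = track.genome.length_of(chrom)
        ok = (mids - half_window >= 0) & (mids + half_window < length)
        mids = mids[ok]
        if mids.size == 0:
            continue
        pos = mids[:, None] + offsets[None, :]
        sums += track.values[chrom][pos // track.bin].sum(axis=0)
        used += mids.size
    if used == 0:
        raise ValueError("all anchors excluded (windows exceed chromosome bounds)")
    return MetaProfile(offsets, sums / used, np.full(offsets.size, used))


def differential_signal_at_sites(
    early: CoverageTrack,
    late: CoverageTrack,
    sites: pd.DataFrame,
    window: int = 600,
) -> pd.DataFrame:
    """Late-minus-early mean RPKM in a window centred on each probe position.

    ``sites`` needs columns ``probe_id``, ``chrom``, ``position`` (0-based).
    """
    if early.genome != late.genome or early.bin != late.bin:
        raise ValueError("tracks must share genome and bin size")
    diffs = []
    half = window // 2
    for row in sites.itertuples(index=False):
        chrom, pos = row.chrom, int(row.position)
        length = early.genome.length_of(chrom)
        if not (0 <= pos < length):
            raise ValueError(f"probe {row.probe_id} at {chrom}:{pos} is off-genome")
        d = late.window_mean(chrom, pos - half, pos + half) - early.window_mean(
            chrom, pos - half, pos + half
        )
        diffs.append(d)
    out = sites[["probe_id"]].copy()
    out["differential"] = diffs
    return out


def group_mean_differential(
    diff: pd.DataFrame, groups: Mapping[str, Sequence[str]]
) -> dict[str, float]:
    """Mean differential per named probe group (e.g. hyper / hypo CpG lists)."""
    indexed = diff.set_index("probe_id")["differential"]
    return {
        name: float(indexed.loc[indexed.index.intersection(ids)].mean())
        for name, ids in groups.items()
    }


def neighborhood_beta_profile(
    probes: pd.DataFrame,
    anchor_probes: pd.DataFrame,
    window: int = 500,
    bin: int = 50,
) -> pd.DataFrame:
    """Mean beta of probes binned by signed distance to anchor probes.

    For each anchor CpG, neighbouring probes within ``[-window, window)`` are
    binned by ``floor(distance / bin)``; means are taken across all
    (anchor, probe) pairs, separately for early and late beta.  Empty bins
    are missing (NaN), not zero.
    """
    n_bins = 2 * (window // bin)
    offsets = (np.arange(n_bins) - window // bin) * bin
    sums_e = np.zeros(n_bins)
    sums_l = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    total_pairs = 0
    for chrom in anchor_probes["chrom"].unique():
        anch = anchor_probes.loc[anchor_probes["chrom"] == chrom, "position"].to_numpy()
        sub = probes[probes["chrom"] == chrom].sort_values("position")
        pos = sub["position"].to_numpy()
        be = sub["beta_early"].to_numpy()
        bl = sub["beta_late"].to_numpy()
        for a in anch:
            lo = np.searchsorted(pos, a - window, side="left")
            hi = np.searchsorted(pos, a + window, side="left")
            if hi <= lo:
                continue
            b = (pos[lo:hi] - a) // bin + window // bin
            np.add.at(sums_e, b, be[lo:hi])
            np.add.at(sums_l, b, bl[lo:hi])
            np.add.at(counts, b, 1)
            total_pairs += hi - lo
    if total_pairs == 0:
        raise ValueError("no probes in the neighbourhood of any anchor")
    with np.errstate(invalid="ignore"):
        mean_e = np.where(counts > 0, sums_e / np.maximum(counts, 1), np.nan)
        mean_l = np.where(counts > 0, sums_l / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "offset": offsets,
            "mean_beta_early": mean_e,
            "mean_beta_late": mean_l,
            "n": counts,
        }
    )


def inside_outside_test(track: CoverageTrack, domains: RegionSet) -> dict:
    """Compare per-bin track values inside vs outside a domain set.

    Bin membership by bin midpoint; Mann-Whitney with tie correction, exact
    enumeration when both groups have <= 50 bins and the values are tie-free.
    A totally tied comparison returns p = 1.0 by convention.
    """
    inside_vals: list[np.ndarray] = []
    outside_vals: list[np.ndarray] = []
    for chrom, length in zip(track.genome.chroms, track.genome.lengths):
        v = track.values[chrom]
        starts = np.arange(v.size) * track.bin
        ends = np.minimum(starts + track.bin, length)
        mids = (starts + ends) // 2
        member = domains.contains_points(chrom, mids)
        inside_vals.append(v[member])
        outside_vals.append(v[~member])
    inside = np.concatenate(inside_vals)
    outside = np.concatenate(outside_vals)
    if inside.size == 0 or outside.size == 0:
        raise ValueError("one of the groups is empty")
    if np.all(inside == inside[0]) and np.all(outside == inside[0]):
        u = inside.size * outside.size / 2
        return {
            "mean_inside": float(inside.mean()),
            "mean_outside": float(outside.mean()),
            "U": float(u),
            "p_value": 1.0,
        }
    pooled = np.concatenate([inside, outside])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (max(inside.size, outside.size) <= 50 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(inside, outside, alternative="two-sided", method=method)
    return {
        "mean_inside": float(inside.mean()),
        "mean_outside": float(outside.mean()),
        "U": float(res.statistic),
        "p_value": float(res.pvalue),
    }


def lad_border_profile(
    track: CoverageTrack,
    lads: RegionSet,
    flank: int = 100_000,
    step: int = 1_000,
) -> MetaProfile:
    """Mean signal at signed offsets from LAD borders.

    Negative offsets are outside the LAD, positive inside; right borders are
    mirrored.  Offsets reaching past the LAD midpoint or off the chromosome
    are excluded from that border's contribution.
    """
    offsets = np.arange(-flank, flank + 1, step)
    sums = np.zeros(offsets.size)
    counts = np.zeros(offsets.size, dtype=np.int64)
    for iv in lads:
        if iv.length <= step:
            continue
        length = track.genome.length_of(iv.chrom)
        half = iv.length // 2
        for border_pos, sign in ((iv.start, 1), (iv.end, -1)):
            pos = border_pos + sign * offsets
            ok = (pos >= 0) & (pos < length)
            ok &= np.where(offsets > 0, offsets <= half, True)
            if not ok.any():
                continue
            vals = track.values[iv.chrom][pos[ok] // track.bin]
            sums[ok] += vals
            counts[ok] += 1
    if counts.max() == 0:
        raise ValueError("no usable LAD borders")
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return MetaProfile(offsets, mean, counts)


def read_probe_table(path: str | Path) -> pd.DataFrame:
    """Read a 450k-style probe TSV; 1-based positions are converted to 0-based."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    df = df.copy()
    df["position"] = df["position"].astype(int) - 1
    df["delta"] = df["beta_late"] - df["beta_early"]
    return df


def write_probe_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write probe records with 1-based positions (the array convention)."""
    out = df[PROBE_COLUMNS].copy()
    out["position"] = out["position"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def select_significant_cpgs(
    probes: pd.DataFrame,
    alpha: float = 0.05,
    min_delta: float = 0.20,
    adjust: bool = False,
) -> dict[str, pd.DataFrame]:
    """Significant senescence-associated CpGs: adj p < alpha and |delta| > min_delta."""
    required = {"beta_early", "beta_late"}
    if not required <= set(probes.columns):
        raise ValueError("probe table lacks beta columns")
    df = probes.copy()
    if "delta" not in df.columns:
        df["delta"] = df["beta_late"] - df["beta_early"]
    if adjust:
        if "p" not in df.columns:
            raise ValueError("raw p column required for BH adjustment")
        from senesceq.association_stats import bh_adjust

        df["adj_p"] = bh_adjust(df["p"].to_numpy())
    if "adj_p" not in df.columns:
        raise ValueError("probe table lacks adj_p column")
    sig = df["adj_p"] < alpha
    return {
        "hyper": df[sig & (df["delta"] > min_delta)].reset_index(drop=True),
        "hypo": df[sig & (df["delta"] < -min_delta)].reset_index(drop=True),
    }
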