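"""Association machinery: exact Fisher tests, BH correction, the projection
test for region-gene association, LAD enrichment against size-matched random
regions, gene-LAD association, flat gene-set enrichment, and the motif-list
overlap test.

``fisher_exact_2x2`` evaluates the conditional hypergeometric distribution in
exact integer arithmetic, so the two-sided definition ("sum of all tables
with probability <= observed, conditional on margins") involves no floating
point tie tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from senesceq.genome_regions import (
    GenomeSpec,
    RegionSet,
    sample_random_regions,
)

GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand", "expr", "log2fc", "fdr"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = in-set / not, columns = condition / not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact_2x2(table: ContingencyTable2x2 | Sequence[Sequence[int]], sided: str = "two") -> float:
    """Exact Fisher p-value for a 2x2 table.

    ``sided``: ``"two"`` (sum of tables with conditional probability <=
    observed) or ``"one-greater"`` (upper tail on the [0,0] cell).
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1 = a + b  # row margin
    c1 = a + c  # column margin
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    if hi < lo:
        raise ValueError("degenerate margins")
    # unnormalised hypergeometric weights share the denominator C(n, r1)
    nums = [math.comb(c1, x) * math.comb(n - c1, r1 - x) for x in range(lo, hi + 1)]
    total = sum(nums)
    obs = nums[a - lo]
    if sided == "one-greater":
        tail = sum(nums[a - lo :])
    elif sided == "two":
        tail = sum(v for v in nums if v <= obs)
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return tail / total


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ProjectionResult:
    """Projection-test outcome for a query region set against a reference."""

    n: int
    k: int
    p0: float
    p_value: float
    direction: str  # enriched / depleted / none

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n):
            raise ValueError("need 0 <= k <= n")
        if not (0.0 <= self.p0 <= 1.0):
            raise ValueError("p0 must be in [0, 1]")


def projection_test(
    query: RegionSet, reference: RegionSet, genome: GenomeSpec | None = None
) -> ProjectionResult:
    """Project query midpoints onto a reference set under a binomial null.

    The null hit probability is the merged reference's share of the genome;
    the p-value is the two-sided exact binomial (twice the smaller tail,
    capped at 1).  Direction is labelled when p < 0.05.
    """
    genome = genome or query.genome
    if len(query) == 0:
        raise ValueError("empty query set")
    if len(reference) == 0:
        raise ValueError("empty reference set")
    merged = reference.merged()
    p0 = merged.total_bp() / genome.total_length
    n = len(query)
    k = 0
    for chrom, mids in query.midpoints().items():
        k += int(merged.contains_points(chrom, mids).sum())
    if p0 >= 1.0:
        return ProjectionResult(n, k, 1.0, 1.0, "none")
    if p0 <= 0.0:
        return ProjectionResult(n, k, 0.0, 1.0 if k == 0 else 0.0, "enriched" if k else "none")
    lower = float(stats.binom.cdf(k, n, p0))
    upper = float(stats.binom.sf(k - 1, n, p0))
    p = min(1.0, 2.0 * min(lower, upper))
    direction = "none"
    if p < 0.05:
        direction = "enriched" if k / n > p0 else "depleted"
    return ProjectionResult(n, k, p0, p, direction)


def region_vs_domains_enrichment(
    regions: RegionSet,
    domains: RegionSet,
    n_random: int = 100,
    seed: int = 0,
) -> dict:
    """Midpoint membership of regions in domains vs pooled size-matched random sets.

    All random sets are pooled into one integer column of the 2x2 table
    (rows = inside/outside, columns = observed/random); two-sided Fisher.
    """
    if len(regions) == 0:
        raise ValueError("no regions")
    if len(domains) == 0:
        raise ValueError("no domains")
    merged = domains.merged()
    obs_in = 0
    for chrom, mids in regions.midpoints().items():
        obs_in += int(merged.contains_points(chrom, mids).sum())
    obs_out = len(regions) - obs_in
    rand_in = rand_total = 0
    for rs in sample_random_regions(regions.lengths(), regions.genome, n_random, seed):
        for chrom, mids in rs.midpoints().items():
            rand_in += int(merged.contains_points(chrom, mids).sum())
        rand_total += len(rs)
    rand_out = rand_total - rand_in
    table = ContingencyTable2x2(obs_in, rand_in, obs_out, rand_out)
    p = fisher_exact_2x2(table, sided="two")
    obs_frac = obs_in / len(regions)
    rand_frac = rand_in / rand_total
    direction = "none"
    if p < 0.05:
        direction = "enriched" if obs_frac > rand_frac else "depleted"
    return {
        "observed_fraction": obs_frac,
        "random_fraction": rand_frac,
        "table": table,
        "p_value": p,
        "direction": direction,
    }


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Gene TSV: id, chrom, tss (0-based), strand, expr, log2fc, fdr."""
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return df


def select_de_genes(
    genes: pd.DataFrame, fdr_cut: float = 0.01, lfc_cut: float = 2.0
) -> dict[str, pd.DataFrame]:
    """Differentially expressed genes: fdr < fdr_cut and |log2fc| > lfc_cut."""
    if not {"fdr", "log2fc"} <= set(genes.columns):
        raise ValueError("gene table lacks fdr/log2fc columns")
    sig = genes["fdr"] < fdr_cut
    return {
        "up": genes[sig & (genes["log2fc"] > lfc_cut)].reset_index(drop=True),
        "down": genes[sig & (genes["log2fc"] < -lfc_cut)].reset_index(drop=True),
    }


def tss_lad_distances(genes: pd.DataFrame, lads: RegionSet) -> np.ndarray:
    """Signed bp distance of each TSS to the nearest LAD border.

    Positive inside a LAD (TSS at a LAD start is inside, at an end outside),
    negative outside.
    """
    merged = lads.merged()
    spans_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in merged:
        spans_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = np.empty(len(genes))
    tss_all = genes["tss"].to_numpy(dtype=np.int64)
    chrom_all = genes["chrom"].to_numpy()
    for chrom in np.unique(chrom_all):
        sel = chrom_all == chrom
        tss = tss_all[sel]
        spans = spans_by_chrom.get(chrom)
        if not spans:
            out[sel] = -np.inf
            continue
        starts = np.array([s for s, _ in spans])
        ends = np.array([e for _, e in spans])
        borders = np.sort(np.concatenate([starts, ends]))
        j = np.clip(np.searchsorted(borders, tss), 1, borders.size - 1)
        dist = np.minimum(
            np.abs(tss - borders[j - 1]), np.abs(borders[j] - tss)
        ).astype(float)
        dist = np.minimum(dist, np.abs(tss - borders[0]))
        dist = np.minimum(dist, np.abs(tss - borders[-1]))
        i = np.searchsorted(starts, tss, side="right") - 1
        inside = (i >= 0) & (tss < ends[np.clip(i, 0, None)])
        out[sel] = np.where(inside, dist, -dist)
    return out


def gene_lad_association(
    genes: pd.DataFrame,
    lads: RegionSet,
    de: Mapping[str, pd.DataFrame] | None = None,
    dist_bin: int = 10_000,
    max_dist: int = 100_000,
) -> dict:
    """Expression vs LAD-border distance plus a DE-gene x LAD-membership table.

    The profile bins mean expression by signed TSS-to-border distance.  The
    2x2 table counts up/down-regulated genes by TSS LAD membership; if either
    membership column is empty the table is reported and the Fisher test
    declined (p None).
    """
    if len(lads) == 0:
        raise ValueError("no LADs")
    dist = tss_lad_distances(genes, lads)
    edges = np.arange(-max_dist, max_dist + dist_bin, dist_bin)
    idx = np.digitize(dist, edges) - 1
    prof_rows = []
    expr = genes["expr"].to_numpy(dtype=float)
    for b in range(edges.size - 1):
        sel = idx == b
        prof_rows.append(
            {
                "dist_lo": edges[b],
                "dist_hi": edges[b + 1],
                "mean_expr": float(expr[sel].mean()) if sel.any() else np.nan,
                "n": int(sel.sum()),
            }
        )
    profile = pd.DataFrame(prof_rows)

    if de is None:
        de = select_de_genes(genes)
    inside = dist >= 0
    gene_inside = dict(zip(genes["gene_id"], inside))
    up_ids = set(de["up"]["gene_id"])
    down_ids = set(de["down"]["gene_id"])
    up_in = sum(1 for g in up_ids if gene_inside.get(g, False))
    down_in = sum(1 for g in down_ids if gene_inside.get(g, False))
    if not up_ids and not down_ids:
        return {"profile": profile, "table": None, "p_value": None, "distances": dist}
    table = ContingencyTable2x2(
        up_in, len(up_ids) - up_in, down_in, len(down_ids) - down_in
    )
    arr = table.as_array()
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        p = None
    else:
        p = fisher_exact_2x2(table, sided="two")
    return {"profile": profile, "table": table, "p_value": p, "distances": dist}


def gene_set_enrichment(
    hits: set[str],
    universe: set[str],
    sets: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Flat gene-set over-representation: one-sided Fisher + BH across sets."""
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    rows = []
    for name, members in sets.items():
        members = set(members) & universe
        ov = len(hits & members)
        table = ContingencyTable2x2(
            ov,
            len(hits) - ov,
            len(members) - ov,
            len(universe) - len(hits) - len(members) + ov,
        )
        rows.append(
            {
                "set": name,
                "set_size": len(members),
                "overlap": ov,
                "p_value": fisher_exact_2x2(table, sided="one-greater"),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["adj_p"] = bh_adjust(df["p_value"].to_numpy())
        df = df.sort_values("p_value", kind="stable").reset_index(drop=True)
    return df


def list_overlap_test(list_a: set[str], list_b: set[str], universe_size: int) -> float:
    """One-sided Fisher test for the overlap of two id lists in a universe.

    The universe size (total candidates from which both lists were drawn)
    must be supplied by the caller.
    """
    a, b = set(list_a), set(list_b)
    ov = len(a & b)
    union = len(a | b)
    if union > universe_size:
        raise ValueError("lists exceed the stated universe")
    table = ContingencyTable2x2(
        ov, len(a) - ov, len(b) - ov, universe_size - union
    )
    return fisher_exact_2x2(table, sided="one-greater")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT-style gene sets: name <tab> description <tab> id..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, ids in sets.items():
            fh.write("\t".join([name, "."] + sorted(ids)) + "\n")
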