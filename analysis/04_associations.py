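#!/usr/bin/env python
"""Region-set association statistics.

LAD enrichment of called DMRs against 100 size-matched random region sets,
projection tests of DMRs against up-/down-regulated gene neighbourhoods,
the gene-LAD association, and a flat gene-set enrichment of the
upregulated genes.  Tables land in results/associations/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from senesceq.association_stats import (
    gene_lad_association,
    gene_set_enrichment,
    projection_test,
    region_vs_domains_enrichment,
    read_gene_table,
    select_de_genes,
)
from senesceq.dmr_calling import FragmentSet, call_dmrs, dmrs_to_regionset
from senesceq.genome_regions import (
    GenomicInterval,
    RegionSet,
    read_bed,
    read_chrom_sizes,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data/default"))
    ap.add_argument("--out", type=Path, default=Path("results/associations"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-random", type=int, default=100)
    ap.add_argument("--gene-vicinity", type=int, default=5_000)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    genome = read_chrom_sizes(args.data / "genome.chrom.sizes")
    lads = read_bed(args.data / "lads.bed", genome)
    early = FragmentSet.from_bed(args.data / "fragments_early.bed", genome)
    late = FragmentSet.from_bed(args.data / "fragments_late.bed", genome)
    calls = {
        "hyper": call_dmrs(late, early, direction="hyper"),
        "hypo": call_dmrs(early, late, direction="hypo"),
    }
    genes = read_gene_table(args.data / "genes.tsv")
    de = select_de_genes(genes)
    print(f"differentially expressed genes: {len(de['up'])} up, {len(de['down'])} down")

    lad_rows = []
    for direction, called in calls.items():
        rs = dmrs_to_regionset(called, genome, direction)
        res = region_vs_domains_enrichment(
            rs, lads, n_random=args.n_random, seed=args.seed
        )
        lad_rows.append(
            {
                "regions": f"{direction} DMRs",
                "observed_fraction": res["observed_fraction"],
                "random_fraction": res["random_fraction"],
                "p_value": res["p_value"],
                "direction": res["direction"],
            }
        )
        print(
            f"{direction} DMRs in LADs: {100 * res['observed_fraction']:.0f}% vs "
            f"{100 * res['random_fraction']:.0f}% random "
            f"(Fisher p = {res['p_value']:.3g}, {res['direction']})"
        )
    pd.DataFrame(lad_rows).to_csv(args.out / "lad_enrichment.tsv", sep="\t", index=False)

    proj_rows = []
    for direction, called in calls.items():
        rs = dmrs_to_regionset(called, genome, direction)
        for which, table in de.items():
            ref = RegionSet(
                genome,
                [
                    GenomicInterval(
                        r.chrom,
                        max(0, r.tss - args.gene_vicinity),
                        min(genome.length_of(r.chrom), r.tss + args.gene_vicinity),
                    )
                    for r in table.itertuples(index=False)
                ],
            )
            res = projection_test(rs, ref, genome)
            proj_rows.append(
                {
                    "dmrs": direction, "genes": which, "n": res.n, "k": res.k,
                    "p0": res.p0, "p_value": res.p_value, "direction": res.direction,
                }
            )
            print(
                f"projection {direction} DMRs vs {which} genes: k={res.k}/{res.n}, "
                f"p0={res.p0:.3f}, p={res.p_value:.3g} ({res.direction})"
            )
    pd.DataFrame(proj_rows).to_csv(args.out / "projection_tests.tsv", sep="\t", index=False)

    gl = gene_lad_association(genes, lads, de)
    gl["profile"].to_csv(args.out / "expression_vs_lad_border.tsv", sep="\t", index=False)
    p = gl["p_value"]
    print(f"up/down genes vs LAD membership: Fisher p = {p if p is None else f'{p:.3g}'}")

    universe = set(genes["gene_id"])
    lad_members = {
        r.gene_id
        for r in genes.itertuples(index=False)
        if lads.contains_points(r.chrom, np.array([r.tss]))[0]
    }
    sets = {
        "lad_genes": lad_members,
        "planted_up": set(de["up"]["gene_id"]),
        "planted_down": set(de["down"]["gene_id"]),
    }
    gse = gene_set_enrichment(set(de["up"]["gene_id"]), universe, sets)
    gse.to_csv(args.out / "gene_set_enrichment_up.tsv", sep="\t", index=False)
    print(gse.to_string(index=False))


if __name__ == "__main__":
    main()
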