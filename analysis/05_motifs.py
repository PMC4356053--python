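#!/usr/bin/env python
"""Transcription-factor motif enrichment.

Standardises called hypermethylated DMRs to 40 bp, scans them and the 1-kb
promoters of differentially expressed genes with the FDR-calibrated motif
library against 100 size-matched random region sets, and tests the overlap
of the two enriched-motif lists.  Tables land in results/motifs/.
"""

import argparse
from pathlib import Path

from senesceq.association_stats import list_overlap_test, read_gene_table, select_de_genes
from senesceq.dmr_calling import FragmentSet, call_dmrs, dmrs_to_regionset
from senesceq.genome_regions import (
    GenomeSequence,
    GenomicInterval,
    RegionSet,
    read_chrom_sizes,
    standardize_region_length,
)
from senesceq.motif_enrichment import motif_enrichment_test, read_jaspar


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data/default"))
    ap.add_argument("--out", type=Path, default=Path("results/motifs"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-random", type=int, default=100)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    genome = read_chrom_sizes(args.data / "genome.chrom.sizes")
    sequence = GenomeSequence.from_fasta(args.data / "genome.fa")
    motifs = read_jaspar(args.data / "motifs.jaspar")

    early = FragmentSet.from_bed(args.data / "fragments_early.bed", genome)
    late = FragmentSet.from_bed(args.data / "fragments_late.bed", genome)
    hyper = dmrs_to_regionset(call_dmrs(late, early, direction="hyper"), genome)
    std = RegionSet(
        genome, [standardize_region_length(iv, 40, genome) for iv in hyper]
    )
    seqs = [sequence.fetch_interval(iv) for iv in std]
    dmr_table = motif_enrichment_test(
        seqs, genome, std, motifs, sequence, n_random=args.n_random, seed=args.seed
    )
    dmr_table.to_csv(args.out / "motif_enrichment_dmrs.tsv", sep="\t", index=False)
    top = dmr_table.iloc[0]
    print(
        f"top motif in 40-bp DMRs: {top['motif_id']} "
        f"({top['target_with_match']}/{top['n_target']} regions with a match vs "
        f"{top['random_with_match']}/{top['n_random']} random; adj p = {top['adj_p']:.3g})"
    )

    genes = read_gene_table(args.data / "genes.tsv")
    de = select_de_genes(genes)
    de_genes = genes[
        genes["gene_id"].isin(
            set(de["up"]["gene_id"]) | set(de["down"]["gene_id"])
        )
    ]
    prom_ivs, prom_seqs = [], []
    for r in de_genes.itertuples(index=False):
        if r.strand == "+":
            lo, hi = max(0, r.tss - 1_000), r.tss
        else:
            lo, hi = r.tss, min(genome.length_of(r.chrom), r.tss + 1_000)
        prom_ivs.append(GenomicInterval(r.chrom, lo, hi, strand=r.strand))
        prom_seqs.append(sequence.fetch(r.chrom, lo, hi))
    prom_table = motif_enrichment_test(
        prom_seqs, genome, RegionSet(genome, prom_ivs), motifs, sequence,
        n_random=args.n_random, seed=args.seed + 1,
    )
    prom_table.to_csv(args.out / "motif_enrichment_promoters.tsv", sep="\t", index=False)

    dmr_hits = set(dmr_table.loc[dmr_table["adj_p"] < 0.05, "motif_id"])
    prom_hits = set(prom_table.loc[prom_table["adj_p"] < 0.05, "motif_id"])
    shared = dmr_hits & prom_hits
    p = list_overlap_test(dmr_hits, prom_hits, len(motifs)) if dmr_hits or prom_hits else 1.0
    print(
        f"motifs enriched in DMRs: {len(dmr_hits)}; in DE promoters: "
        f"{len(prom_hits)}; shared: {len(shared)} "
        f"(one-sided Fisher p = {p:.3g}, universe = {len(motifs)} motifs)"
    )


if __name__ == "__main__":
    main()
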