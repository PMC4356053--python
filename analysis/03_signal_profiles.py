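#!/usr/bin/env python
"""Windowed signal summaries around CpGs, DMRs and LAD borders.

Uses the LAD-signal bundle for the lamina analyses (inside/outside
Mann-Whitney, border profile) and the default bundle for the CpG-level
differential signal, the neighbourhood beta profiles and the histone-mark
metaprofiles around called DMRs.  Tables land in results/profiles/.
"""

import argparse
from pathlib import Path

import pandas as pd

from senesceq.dmr_calling import FragmentSet, call_dmrs, dmrs_to_regionset
from senesceq.genome_regions import read_bed, read_chrom_sizes
from senesceq.signal_profiles import (
    differential_signal_at_sites,
    group_mean_differential,
    inside_outside_test,
    lad_border_profile,
    metaprofile,
    neighborhood_beta_profile,
    read_probe_table,
    rpkm_normalize,
    select_significant_cpgs,
)

MARKS = ("H3K27me3", "H3K4me3", "H3K4me1", "H3K9me3")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/profiles"))
    ap.add_argument("--bin", type=int, default=100)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    # --- default bundle: CpG-level and histone-mark analyses -------------
    data = args.data / "default"
    genome = read_chrom_sizes(data / "genome.chrom.sizes")
    early = rpkm_normalize(FragmentSet.from_bed(data / "fragments_early.bed", genome), args.bin)
    late = rpkm_normalize(FragmentSet.from_bed(data / "fragments_late.bed", genome), args.bin)

    probes = read_probe_table(data / "probes.tsv")
    sig = select_significant_cpgs(probes)
    print(f"significant CpGs: {len(sig['hyper'])} hyper, {len(sig['hypo'])} hypo")
    diff = differential_signal_at_sites(
        early, late, pd.concat([sig["hyper"], sig["hypo"]], ignore_index=True)
    )
    diff.to_csv(args.out / "differential_at_cpgs.tsv", sep="\t", index=False)
    means = group_mean_differential(
        diff, {"hyper": sig["hyper"]["probe_id"], "hypo": sig["hypo"]["probe_id"]}
    )
    print(
        "600-bp differential capture signal (late - early): "
        f"{means['hyper']:+.2f} RPKM at hyper CpGs, {means['hypo']:+.2f} at hypo CpGs"
    )

    for name, anchors in (("hyper", sig["hyper"]), ("hypo", sig["hypo"])):
        prof = neighborhood_beta_profile(probes, anchors, window=500, bin=50)
        prof.to_csv(args.out / f"beta_profile_{name}.tsv", sep="\t", index=False)

    hyper_calls = call_dmrs(
        FragmentSet.from_bed(data / "fragments_late.bed", genome),
        FragmentSet.from_bed(data / "fragments_early.bed", genome),
        direction="hyper",
    )
    anchors = dmrs_to_regionset(hyper_calls, genome, "hyper")
    for mark in MARKS:
        track = rpkm_normalize(
            FragmentSet.from_bed(data / f"fragments_{mark}.bed", genome), args.bin
        )
        prof = metaprofile(track, anchors, half_window=1_000, step=args.bin)
        prof.to_tsv(args.out / f"metaprofile_{mark}_around_hyper_dmrs.tsv")

    # --- LAD-signal bundle: methylation vs lamina -------------------------
    lad_data = args.data / "lad_signal"
    lgenome = read_chrom_sizes(lad_data / "genome.chrom.sizes")
    ltrack = rpkm_normalize(
        FragmentSet.from_bed(lad_data / "fragments_early.bed", lgenome), args.bin
    )
    lads = read_bed(lad_data / "lads.bed", lgenome)
    io = inside_outside_test(ltrack, lads)
    print(
        f"methylation signal inside LADs {io['mean_inside']:.2f} vs outside "
        f"{io['mean_outside']:.2f} RPKM (Mann-Whitney p = {io['p_value']:.3g})"
    )
    border = lad_border_profile(ltrack, lads)
    border.to_tsv(args.out / "lad_border_profile.tsv")
    pd.DataFrame([io]).to_csv(args.out / "lad_inside_outside.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
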