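# senesceq

Integrative analysis of the epigenomic reorganisation that accompanies
**replicative senescence** — the irreversible growth arrest primary cells
(fibroblasts, mesenchymal stromal cells) reach after extended culture — built
so that every stage runs and is validated on a synthetic genome with planted
ground truth.

During long-term culture, DNA methylation (DNAm) changes accumulate at
specific genomic sites: hypomethylation concentrates in lamina-associated
domains (LADs) and H3K9me3 heterochromatin, hypermethylation outside LADs
near differentially expressed genes and in territories carrying H3K27me3,
H3K4me3 and H3K4me1 marks; telomeres shorten and shift from the nuclear rim
toward the center. `senesceq` re-creates the full analysis chain behind those
observations:

| stage | method |
|---|---|
| DMR calling | local-Poisson signal/control test on binned methyl-capture fragment counts, run in both orientations (late-vs-early = hyper, swap = hypo), with changepoint edge refinement |
| signal profiles | RPKM normalisation, metaprofiles around anchor midpoints, 600-bp differential signal at array CpGs, 500-bp neighbourhood beta profiles, LAD inside/outside Mann-Whitney, LAD border profiles |
| associations | exact Fisher 2x2 (integer hypergeometric), Benjamini-Hochberg, projection test (binomial null on region-midpoint hits), LAD enrichment vs 100 size-matched random region sets, gene-LAD association, flat gene-set enrichment |
| motifs | PWM log-odds scan with a threshold calibrated by exact dynamic programming to a background FDR of 1e-4; per-region match enrichment vs 100 random region sets, one-tailed Fisher, BH across motifs |
| imaging | Q-FISH quantification: Otsu nucleus segmentation, three-zone partition by normalised boundary distance, matched-filter spot detection, intensity-based telomere length proxy |
| synthetic data | genome bundles (fragments, probe tables, gene tables, sequences, motif libraries) and two-channel nucleus images, all with recorded planted truth |

The key statistics in the field's notation: a bin with signal count *k* is
kept when `P(X >= k) < 1e-5` for `X ~ Poisson(lambda_local)`, with
`lambda_local = max(lambda_BG, lambda_bin, lambda_1k, lambda_5k, lambda_10k)`
estimated from the depth-scaled control. The projection test scores
`k ~ Binomial(n, p0)` where `p0` is the reference set's genome fraction and
`k` counts query midpoints inside it. A motif match is a window whose
log-odds score `sum_j log2(p_j(b)/q(b))` reaches the smallest threshold `t`
with background tail probability `P(S >= t) <= 1e-4`, computed exactly by
convolving the discretised per-column score distributions.

## Worked example

```bash
python analysis/01_simulate.py --seed 1      # synthetic bundles + images
python analysis/02_call_dmrs.py              # DMR calling + truth recovery
python analysis/03_signal_profiles.py        # CpG/LAD/histone profiles
python analysis/04_associations.py           # LAD + projection + gene sets
python analysis/05_motifs.py                 # motif enrichment
python analysis/06_imaging.py                # Q-FISH quantification
```

`02_call_dmrs.py` prints, for the default bundle (3 x 2 Mb genome, 100+100
planted DMRs at fold 4, 200,000 fragments per passage, seed 1):

```
hyper: called 100 regions, recovered 93/100 planted (93% at >= 0.8 reciprocal overlap), 0 false
hypo: called 100 regions, recovered 93/100 planted (93% at >= 0.8 reciprocal overlap), 0 false
hyper/hypo call overlap (should be ~0): 0.00%
```

i.e. 93 of the 100 planted hypermethylated regions are recovered with at
least 80% reciprocal overlap and no called region lands outside the planted
truth. `04_associations.py` then reports the planted LAD asymmetry on the
called regions — hypomethylated DMRs enriched inside LADs, hypermethylated
ones depleted — and `05_motifs.py` shows the planted EGR1-like motif ranked
first among the library with a vanishing adjusted p-value, echoing the
structure of senescence methylomes where hypomethylation tracks
lamina-associated heterochromatin and hypermethylated regions concentrate
transcription-factor binding motifs.

The same pipeline is exposed as a CLI (`senesceq run --out results/pipeline`,
with `generate`, `dmr`, `profiles`, `enrich`, `motifs` and `imaging`
subcommands for individual stages) driven by a YAML configuration; every
stage writes a JSON manifest with content hashes so a rerun with the same
seed is verifiably bit-identical.

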