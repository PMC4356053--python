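# Methods

This note documents the models, parameter choices and numerical decisions
behind `senesceq`, and what the synthetic-data experiments do and do not
establish about real data.

## Coordinate conventions

All coordinates are 0-based half-open (BED dialect). Probe positions in
450k-style TSV inputs are 1-based and converted on read. Point-in-region
questions (a DMR inside a LAD, a TSS inside a domain) use the region
**midpoint**, `floor((start+end)/2)`, under the half-open rule: a midpoint at
a domain start is inside, at a domain end outside. Midpoint membership was
chosen over any-overlap because DMRs (0.3–1 kb) are small relative to LADs
(tens of kb), which makes counts unambiguous; the any-overlap alternative
changes counts by at most the handful of regions straddling a border.

## DMR calling

Two fragment samples are compared on a fixed grid of 100-bp bins; a fragment
increments every bin it overlaps (capture fragments directly represent
methylated DNA, so no 5'-end shifting or extension model is applied).
Control counts are scaled by the depth ratio. The local rate for each bin is

```
lambda_local = max(lambda_BG, lambda_bin, lambda_1k, lambda_5k, lambda_10k)
```

— the genome-wide scaled-control rate, the scaled control count of the bin
itself, and centred moving averages over 1/5/10-kb windows. Including the
bin itself is essential: with only the broader windows, a sharp feature
present in *both* samples appears self-enriched because the 1-kb window
dilutes the control peak (the degenerate signal==control comparison then
produces calls). Bins with Poisson upper-tail probability below 1e-5 are
kept, kept bins within 200 bp merged, and regions shorter than 200 bp
dropped. Hypermethylated regions come from late-as-signal/early-as-control;
the swapped orientation yields hypomethylated regions.

**Edge refinement.** Bin-level boundaries carry ~1 bin of quantisation plus
fragment-length smearing. Each merged region's edges are therefore
re-estimated at bp resolution as the maximum-likelihood changepoint of a
two-rate Poisson process over the signal fragment *midpoints* (rates
estimated from the candidate core and its 500-bp flanks, each edge optimised
over a +/-500-bp grid). Under the generative model used here — fragment
midpoints drawn from a piecewise-constant intensity — the midpoint process
has a true step at the region edge, and the changepoint MLE has typical
error of a few tens of bp at the default coverage. Refinement can be
disabled (`refine=False`), which restores the pure bin-merge contract.

The parameterisation is deliberately explicit rather than a re-creation of
any particular external caller's defaults: the analysis needs a defined,
testable procedure. There is no q-value step; the per-bin p cutoff is the
operative threshold and a config knob. Region-level statistics (p-value,
fold = signal/lambda over the covering bins, summit = densest bin centre)
are reported per region.

## Signal profiles

RPKM is `count / ((bin/1000) * (total/1e6))` with the every-overlapped-bin
counting rule, so summing `value * bin/1000 * total/1e6` over bins is at
least the fragment count (equality only without boundary-spanning
fragments). Metaprofiles average track values at signed offsets around
anchor midpoints; anchors whose window leaves the chromosome are excluded
and counted. The 600-bp differential signal at array CpGs is the difference
of bp-weighted window means (late minus early) — a difference, not a
log-ratio, because RPKM can be zero. Neighbourhood beta profiles bin
(anchor, probe) pairs by signed distance with empty bins reported as
missing, never zero, to avoid biasing means. The LAD inside/outside
comparison uses the track **bin** as its sampling unit (midpoint
membership), Mann-Whitney with tie correction, exact enumeration when both
groups hold at most 50 tie-free bins and the normal approximation otherwise;
a fully tied comparison returns p = 1. Border profiles mirror right borders
so positive offsets always point into the LAD, and exclude offsets past the
LAD midpoint or the chromosome end. A per-region (rather than per-bin)
inside/outside comparison is available by aggregating upstream of the test.

## Association statistics

`fisher_exact_2x2` evaluates the conditional hypergeometric distribution in
exact integer arithmetic: unnormalised weights `C(c1,x) * C(n-c1, r1-x)`
share a denominator, so the two-sided definition — the total probability of
tables no more likely than the observed one — reduces to integer
comparisons with no floating-point tie tolerance. The projection test
projects query midpoints onto the merged reference; hits follow
`Binomial(n, p0)` with `p0` the reference's genome fraction, the p-value is
twice the smaller exact tail (capped at 1), and direction labels use
p < 0.05, with a two-sided default because depletion is as informative as
enrichment here. Random-region enrichment pools all 100 size-matched random
sets into one integer column of the 2x2 table (pooling keeps the table
integer-valued; fractions would not be counts). TSS membership of a
half-open LAD `[s, e)` places `s` inside and `e` outside. Gene sets are
flat id sets (GMT-style); no ontology structure is modelled. The
motif-list overlap test requires the caller to state the universe size
(the number of motifs scanned), since the overlap's significance is
meaningless without it.

## Motif scanning and calibration

A motif's log-odds matrix is
`log2((counts + pc*bg) / (coltotal + pc) / bg)` with pseudocount 0.1,
discretised to 0.01 score units. The match threshold is **analytic**: the
exact background score distribution is built by convolving per-column score
mass functions over the integer grid (dynamic programming), and the
threshold is the smallest score whose tail probability is at or below the
FDR (default 1e-4). Scanning uses the same discretised matrix, so the
empirical false-match rate on background sequence matches the calibration
(verified at 1e6 positions). Both strands are scanned; windows containing N
are skipped; an unattainable FDR (all words tied at the top) yields the
maximum score with a warning flag. Enrichment counts **regions with at
least one match** — this keeps the Fisher table's unit countable and its
margins fixed — against the pooled random regions; per-site counting can be
recovered from the raw match lists. Random regions are size-matched only;
no composition matching is attempted.

## Q-FISH imaging

Nuclei are segmented by Otsu thresholding and connected components
(components under 200 px^2 discarded); elongation is the square root of the
ratio of the pixel-coordinate covariance eigenvalues, i.e. the axis ratio
of the second-moment ellipse. Zones partition each nucleus by normalised
distance-to-boundary `d = EDT/max(EDT)`: border `d < 1/3`, middle
`1/3 <= d < 2/3`, center `d >= 2/3` — equal thirds in normalised depth,
with the cutoffs configurable (equal-area rings are a defensible
alternative; thirds are the simplest reading of border/middle/center).
A degenerate mask whose maximal depth does not exceed one pixel is all
border. Spot detection finds local maxima of a Gaussian-smoothed copy of
the Cy3 channel (sigma 1 px — a matched filter for diffraction-limited
spots; with thousands of masked pixels, a raw k-sigma cut alone is
statistically guaranteed to admit noise maxima) with minimum separation
3 px, thresholded at background mean + 3 sd on both the smoothed and raw
scales, where the background is re-estimated once after masking 5-px discs
around candidates. The telomere length proxy is the mean raw spot peak
minus the nucleus background mean, in arbitrary units; nuclei with fewer
than three detected spots are excluded from group summaries. Analysis is
2D only.

## Synthetic data: what is emulated

The default bundle plants, on a 3 x 2 Mb genome: 20 LADs of 60–180 kb
(~40% genome share, the share lamina-associated domains occupy in human
fibroblast maps — note this share is what makes depletion of
hypermethylation from LADs detectable at all); 100 hyper- and 100
hypomethylated regions of 300–1,000 bp with at least 2 kb separation
(hypo midpoints inside LADs with probability 0.8 and preferentially in
H3K9me3 territory, hyper midpoints outside with probability 0.8, half of
them within 5 kb of a differentially expressed gene's TSS and otherwise
biased into active-mark territory); 40 domains per histone mark (5–50 kb,
80% associated with their expected LAD side); 500 genes with 10% up- and
10% downregulated (|log2FC| > 2, FDR < 0.01) and lognormal expression
attenuated 0.3x inside LADs; 200,000 fragments of 200–400 bp per passage
with midpoint intensity multiplied by fold 4 over the planted regions of
the appropriate passage; ~5,000 array CpGs, eight per DMR with planted
|delta| ~ 0.25 (noise sd 0.02, always above the 0.2 selection cutoff) and
uniform-noise background probes; an i.i.d. uniform-base genome sequence
with an EGR1-like GC-rich consensus (`GCGTGGGCG`) inserted on a random
strand into the central 40 bp of half the hyper-DMRs and into half the DE
promoters, next to nine fixed decoy motifs.

`lad_signal_config()` adds one change: fragment intensity multiplied by 0.5
inside LADs in **both** passages, emulating the lower methylation of
lamina-associated heterochromatin. This is kept out of the default bundle
deliberately — it is the stated condition for the inside/outside and
border-profile analyses, while DMR-recovery experiments run on the uniform
background (the genome-wide rate floor in the caller otherwise halves
detection power inside LADs, which is a property of real capture data too,
but is not part of the recovery experiment's conditions).

Nucleus images (160 px canvas, 16-bit, two channels) draw early nuclei as
ellipses with semi-major axis 24–32 px and axis ratio 1.05–1.35, late
38–48 px and 1.5–2.2; 5–12 telomere spots per nucleus (Gaussian, sigma
1.5 px, at least 6 px apart so planted spots are optically resolvable) with
amplitudes ~N(9000, 1200) early vs ~N(4500, 700) late on a 500 +/- 80
background, at normalised radii 0.60–0.90 (early, rim) vs 0.05–0.65 (late,
toward the center).

What passing these experiments does **not** show about real data: the
generator has no CpG-density or composition structure (capture efficiency
bias toward CpG-rich fragments is absent), no fragment-length/GC coupling,
no replicate-to-replicate heterogeneity (the low between-donor DMR overlap
seen in real capture data has no synthetic counterpart), no probe
cross-reactivity, no 3D nuclear structure or z-stack selection, and uniform
background sequence rather than repeat/low-complexity structure. Results on
it validate the statistical machinery and its calibration, not the
biology-facing robustness of any step.

## Problem sizes and runtime choices

The default bundle (6 Mb, 4e5 fragments) makes every analysis exact-scale
rather than genome-scale; recovery, enrichment and motif analyses complete
in seconds to tens of seconds. Null calibrations use 500 effect-free
simulations (100 query regions vs 100 random sets each; 300 genes with
40+40 DE for the gene-LAD test) — enough to place a ~0.035–0.04 empirical
type-I level inside [0.02, 0.08] with high probability. Exact Fisher on
pooled tables (margins ~100 vs 10,000) runs in integer arithmetic in a few
hundred milliseconds. Imaging experiments use 50 nuclei per passage.

## Known limitations

* The caller's genome-wide rate floor costs power in genuinely attenuated
  compartments (LADs); this matches standard peak-caller behaviour but
  means recovery figures quoted for the uniform background do not transfer
  to attenuated regions.
* Fisher-based enrichment with pooled random sets is mildly conservative
  (empirical level ~0.035–0.04 at nominal 0.05), inherent to exact
  conditional tests.
* The projection test treats query regions as points; very long queries
  relative to the reference would need interval-aware nulls.
* Zone geometry is equal-thirds in normalised depth; biological border
  definitions differ between studies and the cutoffs should be treated as
  a convention, not a measurement.
* The two-sided exact binomial uses the 2-min-tail convention; minlike-style
  two-sided definitions give slightly different values near ties.
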