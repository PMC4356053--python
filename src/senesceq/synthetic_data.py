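"""Synthetic genome bundles and nucleus images with planted ground truth.

The generator emulates the statistical structure of a replicative-senescence
methylome study so that every pipeline stage is testable without external
downloads:

* a toy genome (default 3 chromosomes x 2 Mb) with non-overlapping
  lamina-associated domains (LADs) and histone-mark territories;
* planted hyper- and hypomethylated regions (DMRs): hypomethylated region
  midpoints fall inside LADs with probability ``p_hypo_in_lad`` (default
  0.8) and inside H3K9me3 territory preferentially; hypermethylated region
  midpoints fall outside LADs with probability ``p_hyper_out_lad`` and are
  drawn near differentially expressed gene TSSs with probability
  ``p_hyper_near_de``;
* methyl-capture fragment samples for early and late passage where fragment
  midpoint density is multiplied by ``fold`` over hyper-DMRs (late) or
  hypo-DMRs (early), and attenuated by ``lad_attenuation`` inside LADs in
  both samples (methylation is lower in lamina-associated heterochromatin);
* a 450k-style probe table with planted beta-value deltas > 0.2 at probes
  inside DMRs;
* a gene table with planted up/down-regulated genes (|log2FC| > 2,
  FDR < 0.01) and expression attenuated inside LADs;
* an i.i.d. background genome sequence with a planted motif consensus
  inserted into the central 40 bp of hyper-DMRs and into promoters of
  differentially expressed genes, plus a fixed decoy motif library;
* two-channel nucleus images whose planted contrasts (area, elongation,
  spot amplitude, radial spot position) reverse between early and late
  passage.

All randomness flows through a single ``numpy`` generator seeded by the
caller, so outputs are byte-identical for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from senesceq.dmr_calling import FragmentSet
from senesceq.genome_regions import (
    GenomeSequence,
    GenomeSpec,
    GenomicInterval,
    RegionSet,
    write_bed,
    write_chrom_sizes,
    write_fasta,
)
from senesceq.motif_enrichment import (
    MotifModel,
    build_motif,
    reverse_complement,
    write_jaspar,
)
from senesceq.signal_profiles import write_probe_table

ACTIVE_MARKS = ("H3K27me3", "H3K4me3", "H3K4me1")
REPRESSIVE_MARK = "H3K9me3"
MARKS = ACTIVE_MARKS + (REPRESSIVE_MARK,)

PLANTED_MOTIF_ID = "SYN_EGR1"
PLANTED_CONSENSUS = "GCGTGGGCG"  # EGR1-like GC-rich zinc-finger site


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic genome bundle."""

    n_chroms: int = 3
    chrom_length: int = 2_000_000
    # 20 LADs of 60-180 kb cover ~40% of the default genome, matching the
    # genome share of lamina-associated domains in human fibroblasts
    n_lads: int = 20
    lad_length: tuple[int, int] = (60_000, 180_000)
    n_hyper: int = 100
    n_hypo: int = 100
    dmr_length: tuple[int, int] = (300, 1_000)
    n_genes: int = 500
    frac_up: float = 0.10
    frac_down: float = 0.10
    fragments_per_sample: int = 200_000
    fragment_length: tuple[int, int] = (200, 400)
    fold: float = 4.0
    p_hypo_in_lad: float = 0.8
    p_hyper_out_lad: float = 0.8
    p_hyper_near_de: float = 0.5
    de_vicinity: int = 5_000
    # Fragment-intensity multiplier inside LADs (both passages).  The default
    # bundle leaves it off; lad_signal_config() enables it for the analyses
    # of methylation level relative to lamina-associated domains.
    lad_attenuation: float = 1.0
    n_mark_domains: int = 40
    mark_length: tuple[int, int] = (5_000, 50_000)
    p_mark_assoc: float = 0.8
    mark_fragments: int = 100_000
    mark_fold: float = 4.0
    n_probes: int = 5_000
    probes_per_dmr: int = 8
    probe_delta: float = 0.25
    probe_noise_sd: float = 0.03
    p_motif_in_dmr: float = 0.5
    p_motif_in_promoter: float = 0.5
    promoter_width: int = 1_000
    n_decoy_motifs: int = 9


def lad_signal_config(**overrides) -> SyntheticConfig:
    """Study conditions for LAD-methylation analyses.

    Identical to the default bundle except that methyl-capture fragment
    intensity is attenuated to 0.5 inside LADs in both passages, emulating
    the lower methylation level of lamina-associated heterochromatin that
    the inside/outside comparison and the LAD border profile measure.
    """
    overrides.setdefault("lad_attenuation", 0.5)
    return SyntheticConfig(**overrides)


@dataclass
class SyntheticTruth:
    """Planted features of a synthetic bundle."""

    hyper_dmrs: RegionSet
    hypo_dmrs: RegionSet
    lads: RegionSet
    marks: dict[str, RegionSet]
    up_genes: list[str]
    down_genes: list[str]
    planted_motif_id: str
    motif_insertions: list[dict]


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    seed: int
    genome: GenomeSpec
    sequence: GenomeSequence
    truth: SyntheticTruth
    fragments_early: FragmentSet
    fragments_late: FragmentSet
    mark_fragments: dict[str, FragmentSet]
    probes: pd.DataFrame
    genes: pd.DataFrame
    motifs: list[MotifModel]
    promoters: dict[str, str]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit every pipeline input format plus a JSON truth manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def _p(name: str) -> Path:
            paths[name] = out / name
            return paths[name]

        write_chrom_sizes(self.genome, _p("genome.chrom.sizes"))
        write_fasta(self.sequence.seqs, _p("genome.fa"))
        write_bed(self.truth.lads, _p("lads.bed"))
        write_bed(self.truth.hyper_dmrs, _p("truth_dmrs_hyper.bed"))
        write_bed(self.truth.hypo_dmrs, _p("truth_dmrs_hypo.bed"))
        for mark, rs in self.truth.marks.items():
            write_bed(rs, _p(f"marks_{mark}.bed"))
        self.fragments_early.to_bed(_p("fragments_early.bed"))
        self.fragments_late.to_bed(_p("fragments_late.bed"))
        for mark, fs in self.mark_fragments.items():
            fs.to_bed(_p(f"fragments_{mark}.bed"))
        write_probe_table(self.probes, _p("probes.tsv"))
        self.genes.to_csv(_p("genes.tsv"), sep="\t", index=False, float_format="%.6g")
        write_fasta(self.promoters, _p("promoters.fa"))
        write_jaspar(self.motifs, _p("motifs.jaspar"))
        manifest = {
            "seed": self.seed,
            "config": asdict(self.config),
            "planted_motif_id": self.truth.planted_motif_id,
            "planted_consensus": PLANTED_CONSENSUS,
            "up_genes": self.truth.up_genes,
            "down_genes": self.truth.down_genes,
            "motif_insertions": self.truth.motif_insertions,
        }
        with open(_p("truth.json"), "w") as fh:
            json.dump(manifest, fh, sort_keys=True, indent=1)
        return paths


# ---------------------------------------------------------------------------
# placement helpers
# ---------------------------------------------------------------------------

class _Spans:
    """Merged spans per chromosome with membership and uniform sampling."""

    def __init__(self, regions: RegionSet, genome: GenomeSpec, complement: bool = False):
        self.genome = genome
        self.spans: dict[str, np.ndarray] = {}
        merged = regions.merged() if len(regions) else regions
        by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chroms}
        for iv in merged:
            by_chrom[iv.chrom].append((iv.start, iv.end))
        for chrom, length in zip(genome.chroms, genome.lengths):
            spans = sorted(by_chrom[chrom])
            if complement:
                comp, prev = [], 0
                for s, e in spans:
                    if s > prev:
                        comp.append((prev, s))
                    prev = e
                if prev < length:
                    comp.append((prev, length))
                spans = comp
            self.spans[chrom] = np.array(spans, dtype=np.int64).reshape(-1, 2)
        flat = [
            (c, s, e) for c in genome.chroms for s, e in self.spans[c]
        ]
        self.flat = flat
        self.weights = np.array([e - s for _, s, e in flat], dtype=float)
        self.total = float(self.weights.sum())

    def contains(self, chrom: str, pos: int) -> bool:
        spans = self.spans[chrom]
        if spans.size == 0:
            return False
        i = np.searchsorted(spans[:, 0], pos, side="right") - 1
        return i >= 0 and pos < spans[i, 1]

    def sample_position(self, rng: np.random.Generator) -> tuple[str, int]:
        i = rng.choice(len(self.flat), p=self.weights / self.total)
        chrom, s, e = self.flat[i]
        return chrom, int(rng.integers(s, e))


class _Occupancy:
    """Tracks placed intervals to enforce a minimum separation."""

    def __init__(self, gap: int = 2_000):
        self.gap = gap
        self.placed: dict[str, list[tuple[int, int]]] = {}

    def free(self, chrom: str, start: int, end: int) -> bool:
        return all(
            not (s - self.gap < end and start < e + self.gap)
            for s, e in self.placed.get(chrom, [])
        )

    def add(self, chrom: str, start: int, end: int) -> None:
        self.placed.setdefault(chrom, []).append((start, end))


def _place_nonoverlapping(
    rng: np.random.Generator,
    genome: GenomeSpec,
    n: int,
    length_range: tuple[int, int],
    occupancy: _Occupancy,
    margin: int = 2_000,
    max_tries: int = 10_000,
) -> list[GenomicInterval]:
    sizes = genome.as_dict()
    chroms = genome.chroms
    lengths = np.array(genome.lengths, dtype=float)
    out: list[GenomicInterval] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place features; genome too crowded")
        l = int(rng.integers(length_range[0], length_range[1] + 1))
        ci = rng.choice(len(chroms), p=lengths / lengths.sum())
        chrom = chroms[ci]
        hi = sizes[chrom] - margin - l
        if hi <= margin:
            continue
        s = int(rng.integers(margin, hi))
        if occupancy.free(chrom, s, s + l):
            occupancy.add(chrom, s, s + l)
            out.append(GenomicInterval(chrom, s, s + l))
    return out


def _place_dmrs(
    rng: np.random.Generator,
    genome: GenomeSpec,
    cfg: SyntheticConfig,
    n: int,
    target_inside_p: float,
    inside_pool: _Spans,
    outside_pool: _Spans,
    proposal_pools: list[tuple[float, _Spans]],
    de_tss: np.ndarray | None,
    de_chroms: list[str] | None,
    occupancy: _Occupancy,
) -> list[GenomicInterval]:
    """Place DMRs honouring a target LAD-membership probability.

    Midpoint proposals come from the DE-gene vicinity (hyper only), from
    associated mark territory, or directly from the matching membership
    pool; a proposal is accepted when its midpoint membership matches the
    Bernoulli target and the region does not collide with previous
    placements.
    """
    sizes = genome.as_dict()
    out: list[GenomicInterval] = []
    margin = 1_500
    for _ in range(n):
        want_inside = bool(rng.random() < target_inside_p)
        pool = inside_pool if want_inside else outside_pool
        l = int(rng.integers(cfg.dmr_length[0], cfg.dmr_length[1] + 1))
        placed = False
        for attempt in range(60):
            u = rng.random()
            chrom: str | None = None
            if de_tss is not None and len(de_tss) and u < cfg.p_hyper_near_de:
                gi = int(rng.integers(len(de_tss)))
                chrom = de_chroms[gi]
                mid = int(de_tss[gi] + rng.integers(-cfg.de_vicinity, cfg.de_vicinity + 1))
            else:
                v = rng.random()
                acc = 0.0
                src = None
                for p, sp in proposal_pools:
                    acc += p
                    if v < acc and sp.total > 0:
                        src = sp
                        break
                if src is None:
                    src = pool
                chrom, mid = src.sample_position(rng)
            s = mid - l // 2
            e = s + l
            if s < margin or e > sizes[chrom] - margin:
                continue
            is_inside = inside_pool.contains(chrom, (s + e) // 2)
            if is_inside != want_inside:
                continue
            if not occupancy.free(chrom, s, e):
                continue
            occupancy.add(chrom, s, e)
            out.append(GenomicInterval(chrom, s, e))
            placed = True
            break
        if not placed:
            # guaranteed-membership fallback
            for attempt in range(200):
                chrom, mid = pool.sample_position(rng)
                s, e = mid - l // 2, mid - l // 2 + l
                if s < margin or e > sizes[chrom] - margin:
                    continue
                if inside_pool.contains(chrom, (s + e) // 2) != want_inside:
                    continue
                if occupancy.free(chrom, s, e):
                    occupancy.add(chrom, s, e)
                    out.append(GenomicInterval(chrom, s, e))
                    placed = True
                    break
            if not placed:
                raise RuntimeError("DMR placement failed; genome too crowded")
    return out


# ---------------------------------------------------------------------------
# fragment sampling
# ---------------------------------------------------------------------------

def _piecewise_segments(
    genome: GenomeSpec,
    factor_sets: list[tuple[RegionSet, float]],
) -> list[tuple[str, int, int, float]]:
    """Split the genome into segments of constant sampling intensity."""
    segments: list[tuple[str, int, int, float]] = []
    for chrom, length in zip(genome.chroms, genome.lengths):
        points = {0, length}
        per_set: list[tuple[np.ndarray, float]] = []
        for rs, factor in factor_sets:
            spans = np.array(
                [(iv.start, iv.end) for iv in rs.merged() if iv.chrom == chrom],
                dtype=np.int64,
            ).reshape(-1, 2)
            per_set.append((spans, factor))
            for s, e in spans:
                points.update((int(s), int(e)))
        bounds = sorted(points)
        for s, e in zip(bounds[:-1], bounds[1:]):
            f = 1.0
            for spans, factor in per_set:
                if spans.size:
                    i = np.searchsorted(spans[:, 0], s, side="right") - 1
                    if i >= 0 and s < spans[i, 1]:
                        f *= factor
            segments.append((chrom, s, e, f))
    return segments


def _sample_fragments(
    rng: np.random.Generator,
    genome: GenomeSpec,
    n_fragments: int,
    factor_sets: list[tuple[RegionSet, float]],
    length_range: tuple[int, int],
) -> FragmentSet:
    """Sample fragment midpoints from a piecewise-constant intensity map."""
    segments = _piecewise_segments(genome, factor_sets)
    masses = np.array([(e - s) * f for _, s, e, f in segments])
    counts = rng.multinomial(n_fragments, masses / masses.sum())
    sizes = genome.as_dict()
    frags: dict[str, list[np.ndarray]] = {c: [] for c in genome.chroms}
    for (chrom, s, e, _f), cnt in zip(segments, counts):
        if cnt == 0:
            continue
        mids = rng.integers(s, e, size=cnt)
        lens = rng.integers(length_range[0], length_range[1] + 1, size=cnt)
        starts = np.clip(mids - lens // 2, 0, np.maximum(sizes[chrom] - lens, 0))
        frags[chrom].append(np.column_stack([starts, starts + lens]))
    arrays = {}
    for chrom, parts in frags.items():
        if parts:
            arr = np.concatenate(parts)
            arrays[chrom] = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    return FragmentSet(genome, arrays)


# ---------------------------------------------------------------------------
# motif library
# ---------------------------------------------------------------------------

def _consensus_pfm(consensus: str, strength: int = 97) -> np.ndarray:
    mat = np.ones((4, len(consensus)))
    for j, base in enumerate(consensus):
        mat["ACGT".index(base), j] = strength
    return mat


def default_motif_library(n_decoys: int = 9) -> list[MotifModel]:
    """The planted EGR1-like motif plus a fixed library of decoy PFMs.

    The decoys are generated from a fixed internal seed so the library is
    identical across bundles regardless of the bundle seed.
    """
    motifs = [
        build_motif(
            _consensus_pfm(PLANTED_CONSENSUS),
            motif_id=PLANTED_MOTIF_ID,
            name="EGR1_like_planted",
        )
    ]
    rng = np.random.default_rng(20_150_304)
    for i in range(n_decoys):
        w = int(rng.integers(8, 13))
        consensus = "".join("ACGT"[c] for c in rng.integers(0, 4, size=w))
        motifs.append(
            build_motif(
                _consensus_pfm(consensus),
                motif_id=f"SYN_TF{i + 1:02d}",
                name=f"decoy_{consensus}",
            )
        )
    return motifs


# ---------------------------------------------------------------------------
# bundle generation
# ---------------------------------------------------------------------------

def generate_genome_bundle(
    config: SyntheticConfig | None = None,
    seed: int = 1,
    out_dir: str | Path | None = None,
) -> SyntheticBundle:
    """Generate a full synthetic bundle with planted truth.

    Deterministic for a fixed seed; when ``out_dir`` is given every pipeline
    input file plus a JSON truth manifest is written there.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    genome = GenomeSpec(
        tuple(f"chr{i + 1}" for i in range(cfg.n_chroms)),
        tuple([cfg.chrom_length] * cfg.n_chroms),
    )
    total_planted = (cfg.n_lads * cfg.lad_length[1]) + (
        (cfg.n_hyper + cfg.n_hypo) * cfg.dmr_length[1]
    )
    if cfg.lad_length[1] + 4_000 > cfg.chrom_length or total_planted > 0.9 * genome.total_length:
        raise ValueError("planted features exceed the genome; enlarge it or plant less")

    # --- LADs and histone-mark territories -------------------------------
    lad_occ = _Occupancy(gap=5_000)
    lads = RegionSet(
        genome,
        _place_nonoverlapping(rng, genome, cfg.n_lads, cfg.lad_length, lad_occ),
        name="lads",
    )
    inside_lads = _Spans(lads, genome)
    outside_lads = _Spans(lads, genome, complement=True)

    marks: dict[str, RegionSet] = {}
    for mark in MARKS:
        assoc_inside = mark == REPRESSIVE_MARK
        occ = _Occupancy(gap=1_000)
        intervals: list[GenomicInterval] = []
        sizes = genome.as_dict()
        while len(intervals) < cfg.n_mark_domains:
            want_inside = rng.random() < (
                cfg.p_mark_assoc if assoc_inside else 1 - cfg.p_mark_assoc
            )
            pool = inside_lads if want_inside else outside_lads
            l = int(rng.integers(cfg.mark_length[0], cfg.mark_length[1] + 1))
            for attempt in range(200):
                chrom, mid = pool.sample_position(rng)
                s = mid - l // 2
                e = s + l
                if s < 0 or e > sizes[chrom]:
                    continue
                if inside_lads.contains(chrom, (s + e) // 2) != want_inside:
                    continue
                if occ.free(chrom, s, e):
                    occ.add(chrom, s, e)
                    intervals.append(GenomicInterval(chrom, s, e))
                    break
            else:
                raise RuntimeError(f"could not place {mark} domains")
        marks[mark] = RegionSet(genome, intervals, name=mark)

    # --- genes ------------------------------------------------------------
    n_up = round(cfg.n_genes * cfg.frac_up)
    n_down = round(cfg.n_genes * cfg.frac_down)
    gene_rows = []
    sizes = genome.as_dict()
    chrom_p = np.array(genome.lengths, dtype=float)
    chrom_p /= chrom_p.sum()
    for i in range(cfg.n_genes):
        chrom = genome.chroms[rng.choice(cfg.n_chroms, p=chrom_p)]
        tss = int(rng.integers(2_000, sizes[chrom] - 2_000))
        strand = "+" if rng.random() < 0.5 else "-"
        status = "up" if i < n_up else ("down" if i < n_up + n_down else "ns")
        if status == "up":
            log2fc = float(rng.uniform(2.2, 5.0))
            fdr = float(10 ** -rng.uniform(3, 10))
        elif status == "down":
            log2fc = float(-rng.uniform(2.2, 5.0))
            fdr = float(10 ** -rng.uniform(3, 10))
        else:
            log2fc = float(np.clip(rng.normal(0, 0.6), -1.9, 1.9))
            fdr = float(rng.uniform(0.011, 1.0))
        expr = float(rng.lognormal(mean=3.0, sigma=1.0))
        if inside_lads.contains(chrom, tss):
            expr *= 0.3  # lamina-associated chromatin is poorly expressed
        gene_rows.append(
            {
                "gene_id": f"GENE{i + 1:04d}",
                "chrom": chrom,
                "tss": tss,
                "strand": strand,
                "expr": round(expr, 4),
                "log2fc": round(log2fc, 4),
                "fdr": fdr,
                "status": status,
            }
        )
    order = np.lexsort(
        (
            [g["tss"] for g in gene_rows],
            [genome.chroms.index(g["chrom"]) for g in gene_rows],
        )
    )
    genes = pd.DataFrame([gene_rows[i] for i in order]).reset_index(drop=True)
    up_genes = genes.loc[genes["status"] == "up", "gene_id"].tolist()
    down_genes = genes.loc[genes["status"] == "down", "gene_id"].tolist()
    de_mask = genes["status"].isin(["up", "down"])
    de_tss = genes.loc[de_mask, "tss"].to_numpy()
    de_chroms = genes.loc[de_mask, "chrom"].tolist()

    # --- DMRs -------------------------------------------------------------
    dmr_occ = _Occupancy(gap=2_000)
    active_pools = [
        (0.3 / len(ACTIVE_MARKS), _Spans(marks[m], genome)) for m in ACTIVE_MARKS
    ]
    hyper = RegionSet(
        genome,
        _place_dmrs(
            rng, genome, cfg, cfg.n_hyper,
            target_inside_p=1 - cfg.p_hyper_out_lad,
            inside_pool=inside_lads, outside_pool=outside_lads,
            proposal_pools=active_pools,
            de_tss=de_tss, de_chroms=de_chroms,
            occupancy=dmr_occ,
        ),
        name="truth_hyper",
    )
    k9_pool = [(0.5, _Spans(marks[REPRESSIVE_MARK], genome))]
    hypo = RegionSet(
        genome,
        _place_dmrs(
            rng, genome, cfg, cfg.n_hypo,
            target_inside_p=cfg.p_hypo_in_lad,
            inside_pool=inside_lads, outside_pool=outside_lads,
            proposal_pools=k9_pool,
            de_tss=None, de_chroms=None,
            occupancy=dmr_occ,
        ),
        name="truth_hypo",
    )

    # --- genome sequence + motif planting ---------------------------------
    codes = {
        chrom: rng.integers(0, 4, size=length, dtype=np.int8)
        for chrom, length in zip(genome.chroms, genome.lengths)
    }
    motifs = default_motif_library(cfg.n_decoy_motifs)
    consensus_codes = np.array(
        ["ACGT".index(b) for b in PLANTED_CONSENSUS], dtype=np.int8
    )
    rc_codes = np.array(
        ["ACGT".index(b) for b in reverse_complement(PLANTED_CONSENSUS)], dtype=np.int8
    )
    insertions: list[dict] = []
    w = len(PLANTED_CONSENSUS)

    def _plant(chrom: str, lo: int, hi: int, context: str) -> None:
        """Insert the consensus at a uniform offset/strand within [lo, hi)."""
        if hi - lo < w:
            return
        pos = int(rng.integers(lo, hi - w + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        word = consensus_codes if strand == "+" else rc_codes
        codes[chrom][pos : pos + w] = word
        insertions.append(
            {"chrom": chrom, "position": pos, "strand": strand, "context": context}
        )

    for iv in hyper:
        if rng.random() < cfg.p_motif_in_dmr:
            mid = iv.midpoint
            _plant(iv.chrom, mid - 20, mid + 20, "hyper_dmr")
    for row in genes[de_mask].itertuples(index=False):
        if rng.random() < cfg.p_motif_in_promoter:
            if row.strand == "+":
                lo, hi = max(0, row.tss - cfg.promoter_width), row.tss
            else:
                lo, hi = row.tss, min(sizes[row.chrom], row.tss + cfg.promoter_width)
            _plant(row.chrom, lo, hi, "promoter")

    base_arr = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequence = GenomeSequence(
        {
            chrom: base_arr[codes[chrom].astype(np.intp)].tobytes().decode()
            for chrom in genome.chroms
        }
    )

    promoters: dict[str, str] = {}
    for row in genes.itertuples(index=False):
        if row.strand == "+":
            lo, hi = max(0, row.tss - cfg.promoter_width), row.tss
        else:
            lo, hi = row.tss, min(sizes[row.chrom], row.tss + cfg.promoter_width)
        promoters[row.gene_id] = sequence.fetch(row.chrom, lo, hi)

    # --- fragments ---------------------------------------------------------
    fragments_early = _sample_fragments(
        rng, genome, cfg.fragments_per_sample,
        [(lads, cfg.lad_attenuation), (hypo, cfg.fold)],
        cfg.fragment_length,
    )
    fragments_late = _sample_fragments(
        rng, genome, cfg.fragments_per_sample,
        [(lads, cfg.lad_attenuation), (hyper, cfg.fold)],
        cfg.fragment_length,
    )
    mark_frags = {
        mark: _sample_fragments(
            rng, genome, cfg.mark_fragments,
            [(marks[mark], cfg.mark_fold)],
            cfg.fragment_length,
        )
        for mark in MARKS
    }

    # --- probes ------------------------------------------------------------
    probe_rows = []
    for direction, regions in (("hyper", hyper), ("hypo", hypo)):
        for iv in regions:
            pos = np.sort(rng.integers(iv.start, iv.end, size=cfg.probes_per_dmr))
            for p in pos:
                if direction == "hyper":
                    be = float(rng.uniform(0.10, 0.50))
                    delta = float(max(0.21, cfg.probe_delta + rng.normal(0, 0.02)))
                else:
                    be = float(rng.uniform(0.50, 0.90))
                    delta = -float(max(0.21, cfg.probe_delta + rng.normal(0, 0.02)))
                probe_rows.append(
                    {
                        "chrom": iv.chrom,
                        "position": int(p),
                        "beta_early": be,
                        "beta_late": float(np.clip(be + delta, 0.0, 1.0)),
                        "adj_p": float(10 ** -rng.uniform(3, 8)),
                        "truth": direction,
                    }
                )
    n_background = cfg.n_probes - len(probe_rows)
    dmr_spans = _Spans(
        RegionSet(genome, list(hyper) + list(hypo), name="all_dmrs"), genome
    )
    placed = 0
    while placed < n_background:
        chrom = genome.chroms[rng.choice(cfg.n_chroms, p=chrom_p)]
        p = int(rng.integers(0, sizes[chrom]))
        if dmr_spans.contains(chrom, p):
            continue
        be = float(rng.uniform(0.05, 0.95))
        bl = float(np.clip(be + rng.normal(0, cfg.probe_noise_sd), 0.0, 1.0))
        probe_rows.append(
            {
                "chrom": chrom,
                "position": p,
                "beta_early": be,
                "beta_late": bl,
                "adj_p": float(rng.uniform(0, 1)),
                "truth": "none",
            }
        )
        placed += 1
    probes = pd.DataFrame(probe_rows)
    probes = probes.sort_values(
        ["chrom", "position"],
        key=lambda s: s.map({c: i for i, c in enumerate(genome.chroms)})
        if s.name == "chrom"
        else s,
        kind="stable",
    ).reset_index(drop=True)
    probes.insert(0, "probe_id", [f"cg{i + 1:07d}" for i in range(len(probes))])
    probes["delta"] = probes["beta_late"] - probes["beta_early"]

    truth = SyntheticTruth(
        hyper_dmrs=hyper,
        hypo_dmrs=hypo,
        lads=lads,
        marks=marks,
        up_genes=up_genes,
        down_genes=down_genes,
        planted_motif_id=PLANTED_MOTIF_ID,
        motif_insertions=insertions,
    )
    bundle = SyntheticBundle(
        config=cfg,
        seed=seed,
        genome=genome,
        sequence=sequence,
        truth=truth,
        fragments_early=fragments_early,
        fragments_late=fragments_late,
        mark_fragments=mark_frags,
        probes=probes,
        genes=genes,
        motifs=motifs,
        promoters=promoters,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


# ---------------------------------------------------------------------------
# nucleus images
# ---------------------------------------------------------------------------

@dataclass
class NucleusImageParams:
    """Rendering parameters for synthetic Q-FISH nuclei."""

    canvas: int = 160
    # semi-major axis and axis-ratio ranges per passage
    early_axis: tuple[float, float] = (24.0, 32.0)
    early_ratio: tuple[float, float] = (1.05, 1.35)
    late_axis: tuple[float, float] = (38.0, 48.0)
    late_ratio: tuple[float, float] = (1.5, 2.2)
    dapi_fill: float = 3_000.0
    dapi_background: float = 300.0
    dapi_noise_sd: float = 100.0
    cy3_background: float = 500.0
    cy3_noise_sd: float = 80.0
    spot_sigma: float = 1.5
    spot_count: tuple[int, int] = (5, 12)
    early_amplitude: tuple[float, float] = (9_000.0, 1_200.0)  # mean, sd
    late_amplitude: tuple[float, float] = (4_500.0, 700.0)
    early_radial: tuple[float, float] = (0.60, 0.90)  # uniform range of r/rmax
    late_radial: tuple[float, float] = (0.05, 0.65)
    min_spot_separation: float = 6.0
    amplitude_scale: float = 1.0


def generate_nucleus_images(
    n_nuclei: int,
    passage: str,
    seed: int = 1,
    params: NucleusImageParams | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Render two-channel 16-bit nucleus images with planted spot truth.

    Late-passage nuclei are larger and more elongated, their telomere spots
    dimmer and radially shifted toward the nuclear center.  Returns one
    (2, H, W) uint16 array per nucleus plus a truth table with spot centers,
    amplitudes and normalised radial positions (0 = center, 1 = rim).
    """
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    if passage not in ("early", "late"):
        raise ValueError("passage must be 'early' or 'late'")
    p = params or NucleusImageParams()
    rng = np.random.default_rng(seed)
    h = w = p.canvas
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    images: list[np.ndarray] = []
    truth_rows = []
    axis_rng = p.early_axis if passage == "early" else p.late_axis
    ratio_rng = p.early_ratio if passage == "early" else p.late_ratio
    amp_mean, amp_sd = p.early_amplitude if passage == "early" else p.late_amplitude
    r_lo, r_hi = p.early_radial if passage == "early" else p.late_radial

    for ni in range(n_nuclei):
        a = rng.uniform(*axis_rng)
        ratio = rng.uniform(*ratio_rng)
        b = a / ratio
        theta = rng.uniform(0, np.pi)
        cy, cx = h / 2 + rng.uniform(-5, 5), w / 2 + rng.uniform(-5, 5)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0

        dapi = p.dapi_background + rng.normal(0, p.dapi_noise_sd, size=(h, w))
        dapi[mask] += p.dapi_fill
        cy3 = p.cy3_background + rng.normal(0, p.cy3_noise_sd, size=(h, w))

        n_spots = int(rng.integers(p.spot_count[0], p.spot_count[1] + 1))
        centers: list[tuple[float, float]] = []
        tries = 0
        while len(centers) < n_spots and tries < 500:
            tries += 1
            r = rng.uniform(r_lo, r_hi)
            phi = rng.uniform(0, 2 * np.pi)
            su = r * a * np.cos(phi)
            sv = r * b * np.sin(phi)
            sx = cx + su * ct - sv * st
            sy = cy + su * st + sv * ct
            if any(
                (sy - oy) ** 2 + (sx - ox) ** 2 < p.min_spot_separation**2
                for oy, ox in centers
            ):
                continue
            centers.append((sy, sx))
            amp = max(500.0, rng.normal(amp_mean, amp_sd)) * p.amplitude_scale
            truth_rows.append(
                {
                    "nucleus_index": ni,
                    "passage": passage,
                    "y": sy,
                    "x": sx,
                    "amplitude": amp,
                    "radial_position": r,
                    "area_planted": float(np.pi * a * b),
                    "elongation_planted": ratio,
                }
            )
            iy, ix = int(round(sy)), int(round(sx))
            lo_y, hi_y = max(0, iy - 8), min(h, iy + 9)
            lo_x, hi_x = max(0, ix - 8), min(w, ix + 9)
            py, px = np.mgrid[lo_y:hi_y, lo_x:hi_x].astype(float)
            cy3[lo_y:hi_y, lo_x:hi_x] += amp * np.exp(
                -((py - sy) ** 2 + (px - sx) ** 2) / (2 * p.spot_sigma**2)
            )
        img = np.stack(
            [
                np.clip(dapi, 0, 65_535).astype(np.uint16),
                np.clip(cy3, 0, 65_535).astype(np.uint16),
            ]
        )
        images.append(img)
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for ni, img in enumerate(images):
            tifffile.imwrite(out / f"{passage}_nucleus_{ni:03d}.tif", img)
        truth.to_csv(out / f"{passage}_truth.tsv", sep="\t", index=False)
    return images, truth
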