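"""Interval engine and file I/O.

Coordinates are 0-based half-open (BED dialect) throughout the package.
Probe positions in 450k-style TSV inputs are 1-based and converted on read
(see :mod:`senesceq.signal_profiles`).

Midpoint membership (``midpoint = floor((start+end)/2)``, half-open interval
test) defines "inside" for point-like region assignment: DMRs are small
relative to LADs, so the midpoint rule makes counts unambiguous.  A midpoint
exactly at a domain end is outside; at a domain start it is inside.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomeSpec:
    """Named chromosomes with lengths; the coordinate system everything runs on."""

    chroms: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chroms) != len(set(self.chroms)):
            raise ValueError("chromosome names must be unique")
        if len(self.chroms) != len(self.lengths):
            raise ValueError("chroms and lengths differ in length")
        if any(int(l) <= 0 for l in self.lengths):
            raise ValueError("all chromosome lengths must be positive")
        object.__setattr__(self, "lengths", tuple(int(l) for l in self.lengths))

    @classmethod
    def from_dict(cls, sizes: Mapping[str, int]) -> "GenomeSpec":
        return cls(tuple(sizes), tuple(sizes.values()))

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[self.chroms.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.chroms, self.lengths))


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval; strand defaults to '.'."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class RegionSet:
    """A list of intervals validated against a genome."""

    def __init__(
        self,
        genome: GenomeSpec,
        intervals: Iterable[GenomicInterval],
        name: str = "",
    ) -> None:
        self.genome = genome
        self.intervals = list(intervals)
        self.name = name
        sizes = genome.as_dict()
        for iv in self.intervals:
            if iv.chrom not in sizes:
                raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
            if iv.end > sizes[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {sizes[iv.chrom]}"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def lengths(self) -> list[int]:
        return [iv.length for iv in self.intervals]

    def midpoints(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv.midpoint)
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}

    def merged(self) -> "RegionSet":
        """Union of the intervals as sorted, disjoint intervals (strand-blind)."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        merged: list[GenomicInterval] = []
        for chrom in self.genome.chroms:
            spans = sorted(by_chrom.get(chrom, []))
            for s, e in spans:
                if merged and merged[-1].chrom == chrom and s <= merged[-1].end:
                    if e > merged[-1].end:
                        merged[-1] = replace(merged[-1], end=e)
                else:
                    merged.append(GenomicInterval(chrom, s, e))
        return RegionSet(self.genome, merged, name=f"{self.name}.merged")

    def total_bp(self) -> int:
        return sum(iv.length for iv in self.merged())

    def contains_points(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Half-open membership of points in the merged set (vectorised)."""
        m = [iv for iv in self.merged() if iv.chrom == chrom]
        positions = np.asarray(positions, dtype=np.int64)
        if not m:
            return np.zeros(positions.shape, dtype=bool)
        starts = np.array([iv.start for iv in m])
        ends = np.array([iv.end for iv in m])
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(positions.shape, dtype=bool)
        inside[ok] = positions[ok] < ends[idx[ok]]
        return inside


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def standardize_region_length(
    region: GenomicInterval, target_len: int = 40, genome: GenomeSpec | None = None
) -> GenomicInterval:
    """Recentre ``region`` to exactly ``target_len`` bp around its midpoint.

    Clipped to chromosome bounds by shifting inward so the length is
    preserved.  The 40-bp default standardises DMRs before motif scanning.
    """
    if target_len <= 0:
        raise ValueError("target_len must be positive")
    chrom_len = genome.length_of(region.chrom) if genome is not None else None
    if chrom_len is not None and chrom_len < target_len:
        raise ValueError(
            f"chromosome {region.chrom} ({chrom_len} bp) shorter than "
            f"target length {target_len}"
        )
    mid = region.midpoint
    start = mid - target_len // 2
    end = start + target_len
    if start < 0:
        start, end = 0, target_len
    if chrom_len is not None and end > chrom_len:
        end = chrom_len
        start = end - target_len
    return replace(region, start=start, end=end)


def sample_random_regions(
    lengths: Sequence[int],
    genome: GenomeSpec,
    n_sets: int,
    seed: int,
) -> list[RegionSet]:
    """Size-matched random region sets: the null used throughout the pipeline.

    For each requested length, a chromosome is chosen with probability
    proportional to its number of valid placements (``L - l + 1``) and the
    start uniformly among them.  Regions may overlap each other; only size
    matching is imposed.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    lengths = np.asarray(lengths, dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("no lengths supplied")
    chrom_lens = np.asarray(genome.lengths, dtype=np.int64)
    if lengths.max() > chrom_lens.max():
        raise ValueError(
            f"region length {int(lengths.max())} exceeds longest chromosome "
            f"({int(chrom_lens.max())} bp)"
        )
    rng = np.random.default_rng(seed)
    sets: list[RegionSet] = []
    for i in range(n_sets):
        # placements: (n_lengths, n_chroms) valid start counts
        placements = np.maximum(chrom_lens[None, :] - lengths[:, None] + 1, 0)
        totals = placements.sum(axis=1)
        cum = np.cumsum(placements, axis=1)
        u = rng.random(lengths.size)
        pick = (u[:, None] * totals[:, None] < cum).argmax(axis=1)
        starts = rng.integers(0, placements[np.arange(lengths.size), pick])
        intervals = [
            GenomicInterval(genome.chroms[c], int(s), int(s + l))
            for c, s, l in zip(pick, starts, lengths)
        ]
        sets.append(RegionSet(genome, intervals, name=f"random_{i}"))
    return sets


def promoter_region(
    gene_tss: int,
    strand: str,
    chrom: str,
    genome: GenomeSpec,
    width: int = 1000,
) -> GenomicInterval:
    """1-kb (default) region upstream of a TSS; clipped at chromosome bounds."""
    chrom_len = genome.length_of(chrom)
    if not (0 <= gene_tss < chrom_len):
        raise ValueError(f"TSS {gene_tss} not on chromosome {chrom}")
    if strand == "+":
        start, end = max(0, gene_tss - width), gene_tss
    elif strand == "-":
        start, end = gene_tss, min(chrom_len, gene_tss + width)
    else:
        raise ValueError(f"unknown strand {strand!r}")
    if start == end:  # TSS at the very edge; keep a 1-bp stub
        raise ValueError(f"promoter for TSS {gene_tss} ({strand}) is empty")
    return GenomicInterval(chrom, start, end, strand=strand)


def interval_overlap_fraction(a: RegionSet, b: RegionSet) -> dict:
    """Per-interval overlap of ``a`` with ``b`` plus midpoint-membership fraction."""
    if a.genome != b.genome:
        raise ValueError("region sets are on different genomes")
    merged_b = b.merged()
    per_interval: list[int] = []
    inside = 0
    for iv in a:
        bp = 0
        for m in merged_b:
            if m.chrom == iv.chrom:
                bp += max(0, min(iv.end, m.end) - max(iv.start, m.start))
        per_interval.append(bp)
        if merged_b.contains_points(iv.chrom, np.array([iv.midpoint]))[0]:
            inside += 1
    frac = inside / len(a) if len(a) else 0.0
    return {"overlap_bp": per_interval, "midpoint_fraction": frac, "n_inside": inside}


# ---------------------------------------------------------------------------
# file I/O: BED / bedGraph / chrom-sizes / FASTA
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> GenomeSpec:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeSpec(tuple(df["chrom"].astype(str)), tuple(df["length"].astype(int)))


def write_chrom_sizes(genome: GenomeSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, l in zip(genome.chroms, genome.lengths):
            fh.write(f"{c}\t{l}\n")


def read_bed(path: str | Path, genome: GenomeSpec, name: str = "") -> RegionSet:
    """BED3/BED6 (tab-separated, no header)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    intervals = []
    for row in df.itertuples(index=False):
        label = str(row[3]) if len(row) > 3 else None
        score = float(row[4]) if len(row) > 4 else None
        strand = str(row[5]) if len(row) > 5 else "."
        intervals.append(
            GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand, score, label)
        )
    return RegionSet(genome, intervals, name=name or Path(path).stem)


def write_bed(regions: RegionSet | Iterable[GenomicInterval], path: str | Path) -> None:
    ivs = regions.intervals if isinstance(regions, RegionSet) else list(regions)
    bed6 = any(
        iv.label is not None or iv.score is not None or iv.strand != "."
        for iv in ivs
    )
    with open(path, "w") as fh:
        for iv in ivs:
            if bed6:
                score = 0.0 if iv.score is None else iv.score
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t"
                    f"{score:g}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


class GenomeSequence:
    """Plain in-memory genome sequence with slice access."""

    def __init__(self, seqs: Mapping[str, str]):
        self.seqs = dict(seqs)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        return cls(read_fasta(path))

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.seqs[chrom][start:end]

    def fetch_interval(self, iv: GenomicInterval) -> str:
        return self.fetch(iv.chrom, iv.start, iv.end)

    def genome_spec(self) -> GenomeSpec:
        return GenomeSpec(tuple(self.seqs), tuple(len(s) for s in self.seqs.values()))
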