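"""PWM motif matching at an FDR-calibrated score threshold, and motif
enrichment in region sets against size-matched random-region nulls.

A motif is a position frequency matrix converted to a log-odds matrix
against a background base distribution.  The match threshold is calibrated
analytically: the exact distribution of the log-odds score of a random
background word is computed by dynamic programming over the discretised
per-column score mass functions (step 0.01 score units), and the threshold
is the smallest score whose background tail probability is at or below the
requested FDR (default 1e-4).  Scanning uses the same discretised matrix,
so empirical false-match rates agree with the calibration.

Enrichment follows the resampling design: the scan is repeated on 100
random genomic region sets of the same sizes, all pooled, and a one-tailed
Fisher test asks whether the proportion of regions with a match is higher
in the tested regions; p-values are Benjamini-Hochberg corrected across
motifs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from senesceq.association_stats import ContingencyTable2x2, bh_adjust, fisher_exact_2x2
from senesceq.genome_regions import (
    GenomeSequence,
    GenomeSpec,
    RegionSet,
    sample_random_regions,
)

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
SCORE_STEP = 0.01


@dataclass
class MotifModel:
    """PFM + background + discretised log-odds matrix + calibrated threshold."""

    motif_id: str
    counts: np.ndarray  # 4 x w, rows A,C,G,T
    pseudocount: float
    background: np.ndarray  # length 4, sums to 1
    lod: np.ndarray = field(init=False)  # 4 x w, multiples of SCORE_STEP
    lod_int: np.ndarray = field(init=False)  # integer score units
    threshold: float | None = None
    threshold_warning: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError("counts must be a 4 x w matrix")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be a length-4 probability vector")
        col_tot = counts.sum(axis=0)
        if np.any((col_tot == 0) & (self.pseudocount == 0)):
            raise ValueError("zero column total with zero pseudocount")
        probs = (counts + self.pseudocount * bg[:, None]) / (col_tot + self.pseudocount)
        lod = np.log2(probs / bg[:, None])
        self.counts = counts
        self.background = bg
        self.lod_int = np.round(lod / SCORE_STEP).astype(np.int64)
        self.lod = self.lod_int * SCORE_STEP

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    @property
    def max_score(self) -> float:
        return float(self.lod_int.max(axis=0).sum() * SCORE_STEP)

    @property
    def min_score(self) -> float:
        return float(self.lod_int.min(axis=0).sum() * SCORE_STEP)


@dataclass(frozen=True)
class MotifMatch:
    region_index: int
    offset: int
    strand: str
    score: float


def build_motif(
    counts: np.ndarray,
    pseudocount: float = 0.1,
    background: Sequence[float] | None = None,
    motif_id: str = "motif",
    name: str = "",
) -> MotifModel:
    """Standard log-odds construction from a position frequency matrix."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return MotifModel(motif_id, np.asarray(counts, float), pseudocount, bg, name=name)


def score_distribution(motif: MotifModel) -> tuple[np.ndarray, int]:
    """Exact background distribution of the discretised word score.

    Returns ``(pmf, offset)`` where ``pmf[i]`` is the probability of integer
    score ``i + offset`` for a random background word.
    """
    pmf = np.ones(1)
    offset = 0
    for j in range(motif.width):
        col = motif.lod_int[:, j]
        lo, hi = int(col.min()), int(col.max())
        new = np.zeros(pmf.size + hi - lo)
        for b in range(4):
            s = int(col[b]) - lo
            new[s : s + pmf.size] += motif.background[b] * pmf
        pmf = new
        offset += lo
    return pmf, offset


def calibrate_threshold(motif: MotifModel, fdr: float = 1e-4) -> float:
    """Smallest score t with background P(score >= t) <= fdr.

    If even the maximal score is attained with probability above ``fdr``
    (all words tie at the top), the threshold is the maximum score and a
    warning flag is set.
    """
    if not (0 < fdr < 1) and fdr != 1:
        raise ValueError("fdr must be in (0, 1]")
    pmf, offset = score_distribution(motif)
    sf = np.cumsum(pmf[::-1])[::-1]  # sf[i] = P(score_int >= i + offset)
    ok = np.flatnonzero(sf <= fdr)
    motif.threshold_warning = False
    if fdr >= 1.0:
        t_int = offset
    elif ok.size == 0:
        t_int = offset + pmf.size - 1
        motif.threshold_warning = True
        warnings.warn(
            f"motif {motif.motif_id}: FDR {fdr} unattainable; "
            "threshold set to the maximum score"
        )
    else:
        t_int = offset + int(ok[0])
    motif.threshold = float(t_int * SCORE_STEP)
    return motif.threshold


def encode_sequence(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.size, 4, dtype=np.int8)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    return codes


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _scan_codes(codes: np.ndarray, motif: MotifModel) -> tuple[np.ndarray, np.ndarray]:
    """Scores for every window; windows containing N are -inf."""
    w = motif.width
    n = codes.size - w + 1
    if n <= 0:
        return np.empty(0), np.empty(0, dtype=np.int64)
    lod = np.vstack([motif.lod, np.full(motif.width, -np.inf)])  # row 4 = N
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    scores = lod[windows, np.arange(w)].sum(axis=1)
    return scores, np.arange(n)


def scan_sequences(
    sequences: Sequence[str], motif: MotifModel, threshold: float | None = None
) -> list[MotifMatch]:
    """Both-strand scan; matches are windows scoring >= the motif threshold.

    A reverse-strand match at forward offset ``o`` covers the same window
    ``[o, o+w)`` as a forward match there.
    """
    thr = motif.threshold if threshold is None else threshold
    if thr is None:
        raise ValueError("motif threshold not calibrated; call calibrate_threshold")
    matches: list[MotifMatch] = []
    w = motif.width
    for idx, seq in enumerate(sequences):
        codes = encode_sequence(seq)
        n = len(seq)
        fwd, offs = _scan_codes(codes, motif)
        for o in offs[fwd >= thr]:
            matches.append(MotifMatch(idx, int(o), "+", float(fwd[o])))
        rc = encode_sequence(reverse_complement(seq))
        rev, offs_r = _scan_codes(rc, motif)
        for o in offs_r[rev >= thr]:
            matches.append(MotifMatch(idx, int(n - w - o), "-", float(rev[o])))
    return matches


def motif_enrichment_test(
    target_sequences: Sequence[str],
    genome: GenomeSpec,
    source_regions: RegionSet,
    motifs: Sequence[MotifModel],
    sequence: GenomeSequence,
    n_random: int = 100,
    seed: int = 0,
    fdr: float = 1e-4,
) -> pd.DataFrame:
    """Per-motif enrichment of matches in target regions vs pooled random sets.

    The 2x2 unit is regions-with->=1-match; the test is one-tailed Fisher
    (greater in target), BH-corrected across motifs.  Random regions are
    size-matched to ``source_regions`` and their sequences drawn from the
    supplied genome sequence.
    """
    if not motifs:
        raise ValueError("no motifs supplied")
    if len(target_sequences) != len(source_regions):
        raise ValueError("target sequences and source regions must correspond 1:1")
    random_sets = sample_random_regions(
        source_regions.lengths(), genome, n_random, seed
    )
    random_seqs = [
        sequence.fetch_interval(iv) for rs in random_sets for iv in rs
    ]
    n_target = len(target_sequences)
    n_rand = len(random_seqs)
    rows = []
    for motif in motifs:
        if motif.threshold is None:
            calibrate_threshold(motif, fdr)
        t_with = len({m.region_index for m in scan_sequences(target_sequences, motif)})
        r_with = len({m.region_index for m in scan_sequences(random_seqs, motif)})
        table = ContingencyTable2x2(t_with, r_with, n_target - t_with, n_rand - r_with)
        rows.append(
            {
                "motif_id": motif.motif_id,
                "name": motif.name,
                "n_target": n_target,
                "target_with_match": t_with,
                "n_random": n_rand,
                "random_with_match": r_with,
                "p_value": fisher_exact_2x2(table, sided="one-greater"),
            }
        )
    df = pd.DataFrame(rows)
    df["adj_p"] = bh_adjust(df["p_value"].to_numpy())
    df = df.sort_values(["p_value", "motif_id"], kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------------------
# JASPAR-style PFM text I/O
# ---------------------------------------------------------------------------

def parse_jaspar(text: str) -> list[tuple[str, str, np.ndarray]]:
    """Parse JASPAR 2014 PFM text (">id name" then four A/C/G/T rows).

    Rows may be bracketed ("A [ 1 2 3 ]") or bare whitespace-separated
    numbers (the simple 4-line count dialect).
    """
    records: list[tuple[str, str, np.ndarray]] = []
    header: str | None = None
    rows: list[list[float]] = []
    order: list[str] = []

    def flush() -> None:
        nonlocal header, rows, order
        if header is None:
            return
        if len(rows) != 4:
            raise ValueError(f"motif {header}: expected 4 matrix rows, got {len(rows)}")
        if order and order != list(BASES):
            rows_by_base = dict(zip(order, rows))
            mat = np.array([rows_by_base[b] for b in BASES])
        else:
            mat = np.array(rows)
        parts = header.split(None, 1)
        motif_id = parts[0]
        name = parts[1] if len(parts) > 1 else ""
        records.append((motif_id, name, mat))
        header, rows, order = None, [], []

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            continue
        stripped = line
        base = ""
        if stripped[0] in BASES and (len(stripped) == 1 or not stripped[1].isdigit()):
            base = stripped[0]
            stripped = stripped[1:]
        stripped = stripped.replace("[", " ").replace("]", " ")
        values = [float(x) for x in stripped.split()]
        rows.append(values)
        if base:
            order.append(base)
    flush()
    return records


def read_jaspar(path: str | Path, pseudocount: float = 0.1,
                background: Sequence[float] | None = None) -> list[MotifModel]:
    with open(path) as fh:
        text = fh.read()
    return [
        build_motif(mat, pseudocount, background, motif_id=mid, name=name)
        for mid, name, mat in parse_jaspar(text)
    ]


def write_jaspar(motifs: Iterable[MotifModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.motif_id} {m.name}".rstrip() + "\n")
            for b, row in zip(BASES, m.counts):
                vals = " ".join(f"{v:g}" for v in row)
                fh.write(f"{b} [ {vals} ]\n")
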