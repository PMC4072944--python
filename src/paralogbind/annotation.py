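"""Interval-to-gene assignment, genomic feature classification, TSS-relative
statistics, per-base track profiling and PWM motif scanning.

Binding intervals are anchored at their midpoint throughout: the midpoint is
assigned to the closest transcription start site (TSS) within a +/-10 kb
window, falling back to the closest gene boundary in the same window, or left
unassigned.  Feature classes (intergenic / intron / exon / UTR / mixed) are
evaluated at the midpoint base with UTR > exon > intron precedence within a
single gene; a midpoint hitting different features of different genes is
"mixed".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ASSIGNMENT_WINDOW = 10_000  # bp, each side of the anchor

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class GeneModel:
    """A stranded gene with exon/UTR structure, 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utrs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.end <= self.start:
            raise ValueError(f"empty gene {self.gene_id}")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"exon outside gene body in {self.gene_id}")

    @property
    def tss(self) -> int:
        """Transcription start site: first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GeneAssignment:
    chrom: str
    start: int
    end: int
    gene_id: str | None
    rule: str  # "tss" | "boundary" | "unassigned"
    distance: int | None


def _midpoint(start: int, end: int) -> int:
    return (start + end) // 2


def assign_interval_to_gene(
    interval: tuple[str, int, int],
    genes: Sequence[GeneModel],
    window: int = ASSIGNMENT_WINDOW,
) -> GeneAssignment:
    """Assign one interval to a gene by closest TSS within ``window`` bp of the
    interval midpoint, falling back to the closest gene start/end in the same
    window; ties break to the lexicographically smaller gene_id.
    """
    chrom, start, end = interval
    mid = _midpoint(start, end)
    best_tss: tuple[int, str] | None = None
    best_boundary: tuple[int, str] | None = None
    for g in genes:
        if g.chrom != chrom:
            continue
        d_tss = abs(mid - g.tss)
        if d_tss <= window:
            cand = (d_tss, g.gene_id)
            if best_tss is None or cand < best_tss:
                best_tss = cand
        d_bound = min(abs(mid - g.start), abs(mid - (g.end - 1)))
        if d_bound <= window:
            cand = (d_bound, g.gene_id)
            if best_boundary is None or cand < best_boundary:
                best_boundary = cand
    if best_tss is not None:
        return GeneAssignment(chrom, start, end, best_tss[1], "tss", best_tss[0])
    if best_boundary is not None:
        return GeneAssignment(
            chrom, start, end, best_boundary[1], "boundary", best_boundary[0]
        )
    return GeneAssignment(chrom, start, end, None, "unassigned", None)


def assign_intervals(
    intervals: pd.DataFrame, genes: Sequence[GeneModel], window: int = ASSIGNMENT_WINDOW
) -> pd.DataFrame:
    """Vector wrapper over :func:`assign_interval_to_gene`."""
    rows = []
    for iv in intervals.itertuples(index=False):
        a = assign_interval_to_gene((iv.chrom, iv.start, iv.end), genes, window)
        rows.append(
            {
                "chrom": a.chrom,
                "start": a.start,
                "end": a.end,
                "gene_id": a.gene_id,
                "rule": a.rule,
                "distance": a.distance,
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene_id", "rule", "distance"]
    )


def _feature_at(g: GeneModel, pos: int) -> str | None:
    """Feature of one gene at a base; UTR > exon > intron inside the body."""
    if not (g.start <= pos < g.end):
        return None
    for s, e in g.utrs:
        if s <= pos < e:
            return "UTR"
    for s, e in g.exons:
        if s <= pos < e:
            return "exon"
    return "intron"


def classify_midpoint_feature(
    interval: tuple[str, int, int], genes: Sequence[GeneModel]
) -> str:
    """Class of the interval midpoint: intergenic / intron / exon / UTR / mixed."""
    chrom, start, end = interval
    mid = _midpoint(start, end)
    hits = {
        f
        for g in genes
        if g.chrom == chrom and (f := _feature_at(g, mid)) is not None
    }
    if not hits:
        return "intergenic"
    if len(hits) == 1:
        return next(iter(hits))
    return "mixed"


def classify_features(intervals: pd.DataFrame, genes: Sequence[GeneModel]) -> pd.Series:
    return pd.Series(
        [
            classify_midpoint_feature((iv.chrom, iv.start, iv.end), genes)
            for iv in intervals.itertuples(index=False)
        ],
        index=intervals.index,
        name="feature",
    )


def tss_position_stats(
    assignments: pd.DataFrame,
    genes: Sequence[GeneModel],
    window: int = ASSIGNMENT_WINDOW,
    n_bins: int = 40,
) -> dict:
    """Strand-aware up/downstream fractions and distance histogram for
    TSS-rule assignments.  Signed distance is negative upstream of the TSS in
    the gene's reading direction; a midpoint exactly on the TSS counts as
    downstream.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    signed = []
    for row in assignments.itertuples(index=False):
        if row.rule != "tss":
            continue
        g = gene_by_id[row.gene_id]
        mid = _midpoint(row.start, row.end)
        d = mid - g.tss if g.strand == "+" else g.tss - mid
        signed.append(d)
    signed = np.asarray(signed, dtype=float)
    n = len(signed)
    if n == 0:
        return {"n": 0, "upstream_fraction": math.nan, "downstream_fraction": math.nan,
                "histogram": None}
    up = float(np.mean(signed < 0))
    hist, edges = np.histogram(signed, bins=n_bins, range=(-window, window))
    return {
        "n": n,
        "upstream_fraction": up,
        "downstream_fraction": 1.0 - up,
        "histogram": pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": hist}
        ),
    }


def profile_signal_around(
    intervals: pd.DataFrame,
    track: Mapping[str, np.ndarray],
    flank: int = 10_000,
    n_bins: int = 41,
) -> pd.DataFrame:
    """Mean per-base track value in bins of position relative to interval
    centres, averaged over intervals; bases beyond chromosome ends are
    excluded from bin means rather than padded.
    """
    if len(intervals) == 0:
        raise ValueError("no intervals to profile")
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    edges = np.linspace(-flank, flank + 1, n_bins + 1)
    for iv in intervals.itertuples(index=False):
        arr = track[iv.chrom]
        centre = _midpoint(iv.start, iv.end)
        lo = max(0, centre - flank)
        hi = min(len(arr), centre + flank + 1)
        rel = np.arange(lo, hi) - centre
        bins = np.clip(np.digitize(rel, edges) - 1, 0, n_bins - 1)
        vals = arr[lo:hi]
        np.add.at(sums, bins, vals)
        np.add.at(counts, bins, 1.0)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"rel_position": centres, "mean_score": mean, "n_bases": counts})


# ---------------------------------------------------------------------------
# PWM scanning


@dataclass
class PWM:
    """Position weight matrix as per-position base probabilities.

    Scores are log2 odds against a 0-order background; per-score p-values are
    computed exactly by dynamic programming over the discretised score
    distribution of background words.
    """

    probs: np.ndarray  # width x 4, rows sum to 1, A C G T order
    background: np.ndarray | None = None  # length 4, sums to 1
    p_threshold: float = 1e-4
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be width x 4")
        if self.width < 4:
            raise ValueError("PWM width must be >= 4")
        if self.background is not None:
            self.background = np.asarray(self.background, dtype=float)
            if not math.isclose(float(self.background.sum()), 1.0, rel_tol=1e-6):
                raise ValueError("background frequencies must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log_odds(self, background: np.ndarray) -> np.ndarray:
        p = self.probs + self.pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        return np.log2(p / background[None, :])


def estimate_background(sequences: Mapping[str, str]) -> np.ndarray:
    """0-order base composition of the scanned sequences (both strands),
    which makes the background strand-symmetric by construction."""
    counts = np.ones(4)  # +1 pseudocount per base
    for seq in sequences.values():
        s = seq.upper()
        for i, b in enumerate(BASES):
            counts[i] += s.count(b)
    counts = counts + counts[::-1]  # A<->T, C<->G symmetrisation
    return counts / counts.sum()


def _score_distribution(
    lom: np.ndarray, background: np.ndarray, n_levels: int = 1000
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Exact discretised null distribution of window scores.

    Each column's log-odds scores are mapped to integer levels at a resolution
    of 1/n_levels of the total score range; the pmf of the sum is built by
    convolution over positions with background base probabilities.
    """
    lo = float(lom.min(axis=1).sum())
    hi = float(lom.max(axis=1).sum())
    scale = n_levels / max(hi - lo, 1e-12)
    levels = np.rint((lom - lom.min(axis=1, keepdims=True)) * scale).astype(int)
    width = lom.shape[0]
    size = int(levels.max(axis=1).sum()) + 1
    pmf = np.zeros(size)
    pmf[0] = 1.0
    top = 0
    for i in range(width):
        new = np.zeros(size)
        for b in range(4):
            lv = levels[i, b]
            new[lv : top + lv + 1] += background[b] * pmf[: top + 1]
        top += int(levels[i].max())
        pmf = new
    sf = np.cumsum(pmf[::-1])[::-1]  # P(level >= k)
    return pmf, sf, lo, scale


def pwm_scan(
    sequences: Mapping[str, str],
    pwm: PWM,
    background: np.ndarray | None = None,
    n_levels: int = 1000,
) -> pd.DataFrame:
    """Scan both strands for PWM matches with exact p <= pwm.p_threshold.

    Windows containing N are skipped.  Returns BED-like rows with the
    log2-odds score and the exact p-value of scoring at least that high under
    the 0-order background.
    """
    bg = background
    if bg is None:
        bg = pwm.background if pwm.background is not None else estimate_background(sequences)
    lom = pwm.log_odds(bg)
    w = pwm.width
    _, sf, lo, scale = _score_distribution(lom, bg, n_levels)
    base_index = {b: i for i, b in enumerate(BASES)}
    rows = []
    for chrom, seq in sequences.items():
        s = seq.upper()
        if len(s) < w:
            continue
        for strand in "+-":
            scan_seq = s if strand == "+" else s.translate(_COMPLEMENT)[::-1]
            idx = np.array([base_index.get(b, -1) for b in scan_seq], dtype=int)
            for i in range(len(s) - w + 1):
                window = idx[i : i + w]
                if (window < 0).any():
                    continue
                score = float(lom[np.arange(w), window].sum())
                level = int(round((score - lo) * scale))
                level = min(max(level, 0), len(sf) - 1)
                p = float(sf[level])
                if p <= pwm.p_threshold:
                    if strand == "+":
                        start = i
                    else:
                        start = len(s) - w - i
                    rows.append(
                        {
                            "chrom": chrom,
                            "start": start,
                            "end": start + w,
                            "strand": strand,
                            "score": score,
                            "p_value": p,
                        }
                    )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "score", "p_value"])
    return df.sort_values(["chrom", "start", "strand"]).reset_index(drop=True)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]
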